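"""Signal-detection summaries of recognition performance.

Criterion ``c = -(z(HR) + z(FAR)) / 2`` and sensitivity
``d' = z(HR) - z(FAR)``, with ``z`` the standard-normal quantile function.
Negative ``c`` is liberal (bias toward calling items old), positive is
conservative.  Perfect hit or false-alarm rates are handled with the
log-linear correction (0.5 added to each cell, 1 to each class total),
applied only when a rate is 0 or 1.

Sessions are summarized per epoch: the scanner design uses six runs of 80
trials; the behavioural design splits 288 trials into thirds of 96.  The
terminal (final-epoch) criterion is the primary endpoint of the
biased-feedback manipulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SDTSummary",
    "criterion",
    "criterion_from_trials",
    "criterion_trajectory",
    "group_contrast",
]


@dataclass(frozen=True)
class SDTSummary:
    epoch_label: str
    n_old: int
    n_new: int
    hits: int
    false_alarms: int
    hit_rate: float
    fa_rate: float
    criterion_c: float
    d_prime: float


def criterion(
    hits: int,
    misses: int,
    false_alarms: int,
    correct_rejections: int,
    epoch_label: str = "",
) -> SDTSummary:
    """SDT summary from the four recognition outcome counts.

    Raises ``ValueError`` if either stimulus class has zero trials (the
    criterion is undefined there).
    """
    counts = (hits, misses, false_alarms, correct_rejections)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n_old = hits + misses
    n_new = false_alarms + correct_rejections
    if n_old == 0 or n_new == 0:
        raise ValueError("both stimulus classes need at least one trial")

    hr = hits / n_old
    far = false_alarms / n_new
    if hr in (0.0, 1.0) or far in (0.0, 1.0):
        # Log-linear edge correction, applied to both classes together.
        hr = (hits + 0.5) / (n_old + 1)
        far = (false_alarms + 0.5) / (n_new + 1)
    zh = stats.norm.ppf(hr)
    zf = stats.norm.ppf(far)
    return SDTSummary(
        epoch_label=epoch_label,
        n_old=n_old,
        n_new=n_new,
        hits=hits,
        false_alarms=false_alarms,
        hit_rate=hr,
        fa_rate=far,
        criterion_c=float(-(zh + zf) / 2.0),
        d_prime=float(zh - zf),
    )


def _counts(trials: pd.DataFrame) -> tuple[int, int, int, int]:
    old_items = trials["item_status"] == "old"
    said_old = trials["response"] == "old"
    hits = int((old_items & said_old).sum())
    misses = int((old_items & ~said_old).sum())
    fas = int((~old_items & said_old).sum())
    crs = int((~old_items & ~said_old).sum())
    return hits, misses, fas, crs


def criterion_from_trials(trials: pd.DataFrame, epoch_label: str = "") -> SDTSummary | None:
    """SDT summary for a block of trials; ``None`` if a class is missing."""
    responded = trials[trials["response"].isin(("old", "new"))]
    try:
        return criterion(*_counts(responded), epoch_label=epoch_label)
    except ValueError:
        return None


def epoch_boundaries(n_trials: int, scheme: str) -> list[tuple[int, int]]:
    """Trial-index slices for an epoching scheme.

    ``runs_of_80`` cuts consecutive 80-trial runs; ``thirds`` splits the
    session into three equal blocks.
    """
    if scheme == "runs_of_80":
        edges = list(range(0, n_trials, 80)) + [n_trials]
        edges = sorted(set(edges))
    elif scheme == "thirds":
        cuts = np.linspace(0, n_trials, 4).round().astype(int)
        edges = list(cuts)
    else:
        raise ValueError(f"unknown epoch scheme {scheme!r}")
    return [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def criterion_trajectory(trials: pd.DataFrame, scheme: str = "runs_of_80") -> list[SDTSummary | None]:
    """Per-epoch SDT summaries, in temporal order.

    Epochs are cut on session trial order (non-responses stay inside their
    epoch but are excluded from the counts).  Epochs missing a whole
    response class yield ``None``.
    """
    trials = trials.reset_index(drop=True)
    out = []
    for i, (a, b) in enumerate(epoch_boundaries(len(trials), scheme), start=1):
        out.append(criterion_from_trials(trials.iloc[a:b], epoch_label=f"epoch{i}"))
    return out


def group_contrast(terminal: pd.DataFrame) -> dict:
    """Condition means and the 2x2 decomposition of the targeted groups.

    ``terminal`` has columns ``participant``, ``condition`` and
    ``terminal_c``.  The four targeted-feedback conditions ``new_high``,
    ``new_low``, ``old_high``, ``old_low`` are decomposed into main
    effects of targeted response (new vs old errors) and targeted
    confidence (high vs low), plus their interaction; the planned
    New-High vs New-Low contrast is reported with Welch's t where both
    cells have >=2 participants.
    """
    by_cond = terminal.groupby("condition")["terminal_c"]
    means = by_cond.mean().to_dict()
    sems = {
        k: float(v) if np.isfinite(v) else None
        for k, v in by_cond.sem().items()
    }
    report: dict = {"means": {k: float(v) for k, v in means.items()}, "sems": sems}

    cells = ["new_high", "new_low", "old_high", "old_low"]
    if all(c in means for c in cells):
        nh, nl, oh, ol = (means[c] for c in cells)
        report["main_effect_response"] = float((nh + nl) / 2 - (oh + ol) / 2)
        report["main_effect_confidence"] = float((nh + oh) / 2 - (nl + ol) / 2)
        report["interaction"] = float((nh - nl) - (oh - ol))
    if "new_high" in means and "new_low" in means:
        a = terminal.loc[terminal["condition"] == "new_high", "terminal_c"]
        b = terminal.loc[terminal["condition"] == "new_low", "terminal_c"]
        report["new_high_vs_new_low"] = float(a.mean() - b.mean())
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            report["new_high_vs_new_low_t"] = float(t)
            report["new_high_vs_new_low_p"] = float(p)
    return report
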
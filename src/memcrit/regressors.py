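"""Model-based parametric regressors for event-related fMRI designs.

Trial-level EV values modulate the trial-onset event and PE values the
feedback event; both are zero-duration sticks convolved with a canonical
double-gamma haemodynamic response function (positive gamma peaking ~5 s
after onset, undershoot gamma at 16 s with ratio 1/6).  Convolution is
performed on a 0.1 s microtime grid and decimated to the repetition time
(TR = 2 s).  Parametric amplitudes are mean-centred before convolution,
the parametric-modulator convention.

The module also quantifies shared vs unique regressor variance: the
Fisher-z-averaged correlation between two codings' convolved regressors
across participants, serial orthogonalization (second regressor reduced
to its unique variance), and a toy GLM recovery experiment in which both
PE codings compete for variance in one ordinary-least-squares model
against a synthetic BOLD signal built from a known generating coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EventSeries",
    "DesignTiming",
    "double_gamma_hrf",
    "convolve_hrf",
    "session_events",
    "coding_correlation",
    "orthogonalize",
    "toy_glm_recovery",
]

MICROTIME_S = 0.1


@dataclass(frozen=True)
class EventSeries:
    """Zero-duration events with parametric amplitudes within one run."""

    onsets: np.ndarray
    amplitudes: np.ndarray
    run_length_s: float
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "amplitudes", amps)
        if onsets.size != amps.size:
            raise ValueError("onsets and amplitudes must have equal length")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if onsets.size and (onsets[-1] >= self.run_length_s or onsets[0] < 0):
            raise ValueError("events must fall inside the run")


@dataclass(frozen=True)
class DesignTiming:
    """Jittered fixation intervals of the scanner design (seconds).

    Inter-trial interval: mean 2, range 1-11; inter-stimulus interval
    between response and feedback: mean 2.85, range 1-6.  Both are drawn
    from shifted exponentials truncated to their ranges.
    """

    iti_mean: float = 2.0
    iti_range: tuple = (1.0, 11.0)
    isi_mean: float = 2.85
    isi_range: tuple = (1.0, 6.0)

    @staticmethod
    def _scale_for_truncated_mean(target: float, width: float) -> float:
        # exponential truncated to [0, width]: mean = s - width/(e^{width/s}-1)
        from scipy.optimize import brentq

        def excess(s):
            return s - width / np.expm1(width / s) - target

        return brentq(excess, target, 50.0)

    def _draw(self, rng, mean, lo, hi, n):
        scale = self._scale_for_truncated_mean(mean - lo, hi - lo)
        x = lo + rng.exponential(scale, size=n)
        while np.any(x > hi):  # redraw tail mass beyond the stated range
            bad = x > hi
            x[bad] = lo + rng.exponential(scale, size=int(bad.sum()))
        return x

    def draw_iti(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self._draw(rng, self.iti_mean, *self.iti_range, n)

    def draw_isi(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self._draw(rng, self.isi_mean, *self.isi_range, n)


def double_gamma_hrf(dt: float = MICROTIME_S, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, peak-normalized to 1."""
    t = np.arange(0, duration_s, dt)
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    return h / h.max()


def convolve_hrf(events: EventSeries, mean_center: bool = True) -> np.ndarray:
    """Convolve stick events with the canonical HRF; sample at the TR."""
    n_micro = int(np.ceil(events.run_length_s / MICROTIME_S))
    sticks = np.zeros(n_micro)
    amps = events.amplitudes
    if mean_center and amps.size:
        amps = amps - amps.mean()
    idx = np.round(events.onsets / MICROTIME_S).astype(int)
    np.add.at(sticks, idx, amps)
    full = np.convolve(sticks, double_gamma_hrf(MICROTIME_S))[:n_micro]
    step = int(round(events.tr_s / MICROTIME_S))
    return full[::step]


def session_events(
    trials: pd.DataFrame,
    timing: DesignTiming = DesignTiming(),
    seed: int = 0,
    feedback_dur_s: float = 1.0,
) -> pd.DataFrame:
    """Lay a trial table out in scan time.

    Returns the input with added ``onset_s`` (trial onset) and
    ``feedback_onset_s`` columns.  Each trial occupies
    rt + ISI + feedback + ITI; non-response trials use the deadline
    duration in place of the RT.
    """
    rng = np.random.default_rng(seed)
    n = len(trials)
    itis = timing.draw_iti(rng, n)
    isis = timing.draw_isi(rng, n)
    rts = trials["rt"].fillna(1.5).to_numpy(dtype=float)
    onsets = np.empty(n)
    fb_onsets = np.empty(n)
    t = 0.0
    for i in range(n):
        onsets[i] = t
        fb_onsets[i] = t + rts[i] + isis[i]
        t = fb_onsets[i] + feedback_dur_s + itis[i]
    out = trials.copy()
    out["onset_s"] = onsets
    out["feedback_onset_s"] = fb_onsets
    out.attrs["run_length_s"] = t + 16.0  # padding for the HRF tail
    return out


def _convolved_regressor(timed: pd.DataFrame, column: str) -> np.ndarray:
    onset_col = "feedback_onset_s" if column.endswith("_pe") else "onset_s"
    ok = timed[column].notna()
    ev = EventSeries(
        onsets=timed.loc[ok, onset_col].to_numpy(),
        amplitudes=timed.loc[ok, column].to_numpy(),
        run_length_s=timed.attrs["run_length_s"],
    )
    return convolve_hrf(ev)


def coding_correlation(
    coded_sessions: list[pd.DataFrame],
    column_a: str = "ms_pe",
    column_b: str = "ero_pe",
    timing: DesignTiming = DesignTiming(),
    seed: int = 0,
) -> dict:
    """Fisher-z-averaged correlation between two convolved codings.

    Each session must already carry the coding columns (see
    ``value_coding.code_trials``).  The Pearson correlation between the
    two convolved regressors is computed within each participant,
    Fisher-z transformed, averaged, and back-transformed; both the mean
    r and R**2 are returned.
    """
    zs = []
    for i, session in enumerate(coded_sessions):
        timed = session_events(session, timing=timing, seed=seed + i)
        xa = _convolved_regressor(timed, column_a)
        xb = _convolved_regressor(timed, column_b)
        if np.std(xa) == 0 or np.std(xb) == 0:
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        zs.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
    if not zs:
        return {"r": float("nan"), "r_squared": float("nan"), "n": 0}
    r_bar = float(np.tanh(np.mean(zs)))
    return {"r": r_bar, "r_squared": r_bar**2, "n": len(zs)}


def orthogonalize(x_first: np.ndarray, x_second: np.ndarray) -> np.ndarray:
    """Serial orthogonalization: residual of the second regressor.

    Returns ``x_second`` minus its projection onto span{1, x_first}; the
    first regressor keeps shared + unique variance, the result carries
    only the second's unique variance.  A zero-variance ``x_first``
    degrades to plain mean-centring.
    """
    x_first = np.asarray(x_first, dtype=float)
    x_second = np.asarray(x_second, dtype=float)
    if x_first.shape != x_second.shape:
        raise ValueError("regressors must have equal length")
    if np.std(x_first) == 0:
        return x_second - x_second.mean()
    design = np.column_stack([np.ones_like(x_first), x_first])
    beta, *_ = np.linalg.lstsq(design, x_second, rcond=None)
    return x_second - design @ beta


def toy_glm_recovery(
    session: pd.DataFrame,
    generating_coding: str = "ms_pe",
    beta: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    timing: DesignTiming = DesignTiming(),
) -> dict:
    """Variance attribution when both PE codings compete in one GLM.

    A synthetic signal ``y = beta * convolved(generating PE) + noise`` is
    regressed on both convolved PE codings jointly (plus intercept);
    reports each coding's coefficient and t-statistic and which coding is
    credited with the unique variance (larger absolute t).
    """
    if generating_coding not in ("ms_pe", "ero_pe"):
        raise ValueError("generating_coding must be 'ms_pe' or 'ero_pe'")
    rng = np.random.default_rng(seed)
    timed = session_events(session, timing=timing, seed=seed)
    x_ms = _convolved_regressor(timed, "ms_pe")
    x_ero = _convolved_regressor(timed, "ero_pe")
    gen = x_ms if generating_coding == "ms_pe" else x_ero
    y = beta * gen + rng.normal(0.0, noise_sd, size=gen.size)

    design = sm.add_constant(np.column_stack([x_ms, x_ero]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return {"rank_deficient": True}
    fit = sm.OLS(y, design).fit()
    coef_ms, coef_ero = float(fit.params[1]), float(fit.params[2])
    t_ms, t_ero = float(fit.tvalues[1]), float(fit.tvalues[2])
    return {
        "rank_deficient": False,
        "coef_ms": coef_ms,
        "coef_ero": coef_ero,
        "t_ms": t_ms,
        "t_ero": t_ero,
        "winner": "ms_pe" if abs(t_ms) >= abs(t_ero) else "ero_pe",
    }
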
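"""Trial-level expected value (EV) and prediction error (PE) codings.

Recognition decisions are framed as value-based choices: each old/new
decision carries an expected probability of positive ("Correct!") feedback,
and the feedback outcome (1 = positive, 0 = negative) generates a
prediction error PE = outcome - EV in [-1, 1].

Three codings map the continuous confidence rating (0 = minimum, 1 =
maximum confidence) onto an EV in [0, 1]:

* Memory strength (MS): EV tracks the latent memory strength implied by
  the response.  New responses span [0, 0.5] (high-confidence new = 0,
  i.e. lowest strength) and old responses span [0.5, 1] (high-confidence
  old = 1).
* Expected response outcome (ERO): EV equals confidence for both
  responses -- the anticipated probability that the response is correct.
* Starred memory strength (MS*): a control coding that removes the
  old/new main-effect offset of the MS coding while preserving the
  within-response confidence slopes: new -> 1 - confidence,
  old -> confidence.

All maps are linear between their endpoint anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CODINGS",
    "ValueCodingResult",
    "ms_ev",
    "ero_ev",
    "ms_star_ev",
    "pe",
    "code_trials",
]

CODINGS = ("MS", "ERO", "MS_star")

Response = Literal["old", "new"]


@dataclass(frozen=True)
class ValueCodingResult:
    """EV and PE for one trial under one coding."""

    coding: str
    ev: float
    pe: float

    def __post_init__(self) -> None:
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if not 0.0 <= self.ev <= 1.0:
            raise ValueError(f"ev {self.ev} outside [0, 1]")
        if not -1.0 <= self.pe <= 1.0:
            raise ValueError(f"pe {self.pe} outside [-1, 1]")


def _check_confidence(confidence) -> np.ndarray:
    q = np.asarray(confidence, dtype=float)
    if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
        raise ValueError("confidence must lie in [0, 1]")
    return q


def _check_response(response) -> np.ndarray:
    r = np.asarray(response, dtype=object)
    bad = ~np.isin(r, ("old", "new"))
    if np.any(bad):
        raise ValueError(f"unknown response label(s): {set(r[bad])}")
    return r


def ms_ev(response, confidence):
    """Memory-strength EV.

    New responses: EV = 0.5 * (1 - confidence), spanning [0, 0.5].
    Old responses: EV = 0.5 + 0.5 * confidence, spanning [0.5, 1].
    """
    r = _check_response(response)
    q = _check_confidence(confidence)
    is_old = r == "old"
    out = np.where(is_old, 0.5 + 0.5 * q, 0.5 * (1.0 - q))
    return float(out) if out.ndim == 0 else out


def ero_ev(confidence):
    """Expected-response-outcome EV: equals confidence, response-independent."""
    q = _check_confidence(confidence)
    return float(q) if q.ndim == 0 else q.copy()


def ms_star_ev(response, confidence):
    """Starred (control) memory-strength EV.

    New responses: EV* = 1 - confidence.  Old responses: EV* = confidence.
    Removes the old/new main-effect offset of the MS coding while keeping
    the within-response slopes.
    """
    r = _check_response(response)
    q = _check_confidence(confidence)
    out = np.where(r == "old", q, 1.0 - q)
    return float(out) if out.ndim == 0 else out


def pe(ev, outcome):
    """Prediction error: outcome - EV, identical for every coding.

    ``outcome`` must be binary (1 = positive feedback, 0 = negative).
    """
    e = np.asarray(ev, dtype=float)
    if np.any((e < 0) | (e > 1)):
        raise ValueError("ev must lie in [0, 1]")
    o = np.asarray(outcome)
    if not np.all(np.isin(o, (0, 1))):
        raise ValueError("outcome must be binary 0/1")
    out = o.astype(float) - e
    return float(out) if out.ndim == 0 else out


def code_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Append EV/PE columns for all three codings to a trial table.

    Expects columns ``response`` ('old'/'new'; NaN/None for non-response),
    ``confidence`` and ``outcome``.  Rows without a response are left as
    NaN in every coding column: EVs and PEs exist only for trials on which
    a decision was made.
    """
    out = trials.copy()
    responded = out["response"].isin(("old", "new")).to_numpy()
    resp = out.loc[responded, "response"].to_numpy()
    conf = out.loc[responded, "confidence"].to_numpy(dtype=float)
    fb = out.loc[responded, "outcome"].to_numpy()

    evs = {
        "ms_ev": ms_ev(resp, conf),
        "ero_ev": ero_ev(conf),
        "ms_star_ev": ms_star_ev(resp, conf),
    }
    for name, ev_vals in evs.items():
        pe_name = name.replace("_ev", "_pe")
        out[name] = np.nan
        out[pe_name] = np.nan
        out.loc[responded, name] = ev_vals
        out.loc[responded, pe_name] = pe(ev_vals, fb)
    return out
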
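"""Trial-table serialization and validation.

The standard trial table is a TSV with one row per recognition trial:
``trial, run, item_status, response, confidence, rt, outcome,
false_feedback`` (plus any extra columns such as the latent strength or
appended value-coding columns).  Non-response trials carry empty
response/confidence/rt fields.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_trials", "write_trials", "validate_trials", "round_sig", "write_json"]

REQUIRED_COLUMNS = (
    "trial",
    "run",
    "item_status",
    "response",
    "confidence",
    "rt",
    "outcome",
    "false_feedback",
)


def read_trials(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "response" in df.columns:
        df["response"] = df["response"].where(df["response"].notna(), None)
    if "false_feedback" in df.columns:
        df["false_feedback"] = df["false_feedback"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix == ".csv" else "\t"
    trials.to_csv(path, sep=sep, index=False, float_format="%.9g")


def validate_trials(trials: pd.DataFrame) -> list[str]:
    """Schema and consistency diagnostics; empty list means clean."""
    violations: list[str] = []
    for col in REQUIRED_COLUMNS:
        if col not in trials.columns:
            violations.append(f"missing column: {col}")
    if violations:
        return violations

    bad_status = ~trials["item_status"].isin(("old", "new"))
    if bad_status.any():
        violations.append(f"{int(bad_status.sum())} rows with invalid item_status")

    responded = trials["response"].isin(("old", "new"))
    bad_resp = ~responded & trials["response"].notna()
    if bad_resp.any():
        violations.append(f"{int(bad_resp.sum())} rows with invalid response label")

    conf = trials.loc[responded, "confidence"]
    out_of_range = (conf < 0) | (conf > 1) | conf.isna()
    if out_of_range.any():
        violations.append(
            f"{int(out_of_range.sum())} responded rows with confidence outside [0, 1]"
        )

    rt = trials.loc[responded, "rt"]
    if ((rt < 0) | rt.isna()).any():
        violations.append("responded rows with negative or missing rt")

    if not trials["outcome"].isin((0, 1)).all():
        violations.append("outcome column contains non-binary values")

    # false feedback must be positive feedback on an error
    ff = trials["false_feedback"].astype(bool)
    if "correct" in trials.columns:
        bad_ff = ff & (trials["correct"].astype(bool) | (trials["outcome"] != 1))
    else:
        correct = trials["response"] == trials["item_status"]
        bad_ff = ff & (correct | (trials["outcome"] != 1))
    if bad_ff.any():
        violations.append(
            f"{int(bad_ff.sum())} false_feedback rows that are not positive feedback on an error"
        )

    nonresp_rate = float((~responded).mean())
    if nonresp_rate > 0.05:
        violations.append(f"non-response rate {nonresp_rate:.3f} exceeds 0.05")
    return violations


def round_sig(x, digits: int = 9):
    """Round floats (recursively through containers) to significant digits."""
    if isinstance(x, dict):
        return {k: round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [round_sig(v, digits) for v in x]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        x = float(x)
        if x == 0 or not math.isfinite(x):
            return x
        return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))
    if isinstance(x, np.ndarray):
        return round_sig(x.tolist(), digits)
    return x


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(round_sig(obj), indent=1, sort_keys=True) + "\n")
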
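"""Biased-feedback delivery schedules.

Two algorithms deliberately deliver *false positive* feedback ("Correct!"
after an incorrect response) to bias the learned recognition criterion:

* :class:`MedianTrackingSchedule` -- the scanner-task schedule.  A running
  median of the confidence ratings given on false alarms is recomputed
  before each trial; false alarms below that median always receive false
  positive feedback, false alarms at or above it receive it with
  probability 0.4, and every other trial receives veridical feedback.
  Under a continuous confidence distribution this converges to false
  feedback on ~70% of false alarms.

* :class:`AdaptiveSchedule` -- the between-groups behavioural schedule.
  A proportional controller targets a fixed total number of false-feedback
  instances (default 30) spread over the whole session (default 288
  trials).  Eligible trials are errors of the targeted response type
  (misses for the "new error" groups, false alarms for the "old error"
  groups) whose confidence falls on the targeted side (low/high) of a
  running median for that error type.  Before each trial the controller
  estimates how many eligible errors remain and delivers false feedback to
  an eligible error with probability
  ``p = clamp((target - delivered) / max(E_remaining, 1), 0, 1)``.

Both schedules are deterministic given a seed and an identical trial
stream.  False feedback is only ever positive feedback on an incorrect
trial of the targeted type.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeedbackDecision",
    "MedianTrackingSchedule",
    "AdaptiveSchedule",
    "VeridicalSchedule",
    "schedule_audit",
]


@dataclass(frozen=True)
class FeedbackDecision:
    """Outcome of one feedback decision: 1/0 feedback plus a false flag."""

    outcome: int
    false_feedback: bool


def _running_median(values: list[float], default: float = 0.5) -> float:
    # Cold start: midpoint of the confidence scale until >=2 observations.
    if len(values) < 2:
        return default
    return statistics.median(values)


class VeridicalSchedule:
    """Truthful feedback on every trial (control condition)."""

    def step(self, response, correct: bool, confidence: float) -> FeedbackDecision:
        if response is None:
            return FeedbackDecision(0, False)
        return FeedbackDecision(int(correct), False)


class MedianTrackingSchedule:
    """Online median-tracking false-feedback schedule for false alarms.

    Parameters
    ----------
    p_below, p_above:
        Probability of false positive feedback for a false alarm whose
        confidence is below / at-or-above the running median of previous
        false-alarm confidences.  Defaults 1.0 and 0.4.
    seed:
        Seed for the Bernoulli draws.
    """

    def __init__(self, p_below: float = 1.0, p_above: float = 0.4, seed: int = 0):
        self.p_below = float(p_below)
        self.p_above = float(p_above)
        self.fa_confidences: list[float] = []
        self._rng = np.random.default_rng(seed)

    def step(self, response, correct: bool, confidence: float) -> FeedbackDecision:
        """Decide feedback for one trial and update the tracked state.

        The median is computed *before* the decision; the new false-alarm
        confidence is appended *after* it.
        """
        if response is None:
            return FeedbackDecision(0, False)
        is_false_alarm = (response == "old") and not correct
        if not is_false_alarm:
            return FeedbackDecision(int(correct), False)

        median = _running_median(self.fa_confidences)
        # Ties (confidence exactly at the median) take the 0.4 arm.
        p = self.p_below if confidence < median else self.p_above
        deliver = bool(self._rng.random() < p)
        self.fa_confidences.append(float(confidence))
        if deliver:
            return FeedbackDecision(1, True)
        return FeedbackDecision(0, False)


@dataclass
class AdaptiveSchedule:
    """Adaptive controller targeting ~``target_total`` false-feedback trials.

    ``targeted_response`` selects which errors are eligible: ``"new_errors"``
    (misses -- incorrect new responses) or ``"old_errors"`` (false alarms --
    incorrect old responses).  ``targeted_confidence`` selects the side of
    the running per-error-type confidence median: ``"low"`` (strictly
    below) or ``"high"`` (at or above).

    The expected number of eligible errors remaining is estimated from the
    running eligible-error rate (eligible errors seen / trials elapsed);
    before any trial has elapsed a prior of ``prior_error_rate / 2`` is
    used (the median split makes roughly half of the targeted errors
    eligible).
    """

    target_total: int = 30
    targeted_response: str = "new_errors"
    targeted_confidence: str = "low"
    trials_total: int = 288
    prior_error_rate: float = 0.3
    seed: int = 0

    delivered: int = field(default=0, init=False)
    trials_elapsed: int = field(default=0, init=False)
    eligible_observed: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if self.targeted_response not in ("new_errors", "old_errors"):
            raise ValueError(f"bad targeted_response {self.targeted_response!r}")
        if self.targeted_confidence not in ("low", "high"):
            raise ValueError(f"bad targeted_confidence {self.targeted_confidence!r}")
        self._error_confidences: list[float] = []
        self._rng = np.random.default_rng(self.seed)

    def _is_targeted_error(self, response, correct: bool) -> bool:
        if response is None or correct:
            return False
        if self.targeted_response == "new_errors":
            return response == "new"
        return response == "old"

    def delivery_probability(self) -> float:
        """Per-trial false-feedback probability for an eligible error."""
        if self.trials_elapsed > 0:
            rate = self.eligible_observed / self.trials_elapsed
        else:
            rate = self.prior_error_rate / 2.0
        remaining = max(self.trials_total - self.trials_elapsed, 0)
        expected_eligible = rate * remaining
        p = (self.target_total - self.delivered) / max(expected_eligible, 1.0)
        return float(np.clip(p, 0.0, 1.0))

    def step(self, response, correct: bool, confidence: float) -> FeedbackDecision:
        p = self.delivery_probability()
        decision = FeedbackDecision(0 if response is None else int(correct), False)
        eligible = False
        if self._is_targeted_error(response, correct):
            median = _running_median(self._error_confidences)
            if self.targeted_confidence == "low":
                eligible = confidence < median
            else:
                eligible = confidence >= median
            self._error_confidences.append(float(confidence))
        if eligible and self._rng.random() < p:
            decision = FeedbackDecision(1, True)
        self.trials_elapsed += 1
        if eligible:
            self.eligible_observed += 1
        if decision.false_feedback:
            self.delivered += 1
        return decision


def schedule_audit(trials: pd.DataFrame) -> dict:
    """Summarize realized false-feedback delivery for a completed session.

    Expects columns ``response``, ``correct``, ``confidence``,
    ``false_feedback`` and optionally ``run``.  Reports the delivered
    count, per-run counts, realized delivery rates for false alarms below
    vs at-or-above the running false-alarm median (replayed in trial
    order), and the confidence distribution of falsely rewarded trials.
    """
    if len(trials) == 0:
        return {
            "n_trials": 0,
            "delivered": 0,
            "per_run": {},
            "below_median_rate": float("nan"),
            "above_median_rate": float("nan"),
            "false_fb_confidence_mean": float("nan"),
        }
    delivered = int(trials["false_feedback"].sum())
    per_run = (
        trials.groupby("run")["false_feedback"].sum().astype(int).to_dict()
        if "run" in trials.columns
        else {}
    )
    # Replay the running false-alarm median to classify each FA's arm.
    fa_seen: list[float] = []
    below = {"n": 0, "fb": 0}
    above = {"n": 0, "fb": 0}
    for row in trials.itertuples(index=False):
        if row.response == "old" and not row.correct:
            arm = below if row.confidence < _running_median(fa_seen) else above
            arm["n"] += 1
            arm["fb"] += int(row.false_feedback)
            fa_seen.append(float(row.confidence))
    fb_conf = trials.loc[trials["false_feedback"].astype(bool), "confidence"]
    return {
        "n_trials": int(len(trials)),
        "delivered": delivered,
        "per_run": per_run,
        "below_median_rate": below["fb"] / below["n"] if below["n"] else float("nan"),
        "above_median_rate": above["fb"] / above["n"] if above["n"] else float("nan"),
        "false_fb_confidence_mean": float(fb_conf.mean()) if len(fb_conf) else float("nan"),
    }
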
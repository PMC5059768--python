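"""Synthetic recognition-memory participants with PE-driven criterion learning.

Each agent is an equal-variance (optionally unequal-variance) signal
detection observer: new items draw memory strength from Normal(0, 1) and
studied items from Normal(d', sigma_old).  The agent responds *old* when
strength exceeds its current decision threshold and reports confidence as
the clamped scaled distance from that threshold.  The criterion is
expressed in SDT units -- c = 0 puts the threshold at the intersection of
the equal-variance distributions (evidence value d'/2) -- so simulated
cohorts are directly comparable to criterion estimates recovered from
their own hit/false-alarm rates.

Feedback (possibly false, via the configured schedule) generates a
prediction error under the agent's coding (MS or ERO), and the criterion
is updated by a reinforcement rule proportional to the PE magnitude:

    c_{t+1} = c_t + alpha * PE * s,   s = +1 after a new response,
                                      s = -1 after an old response,

so positive PEs reinforce the preceding decision tendency (conservative
after new, liberal after old) and negative PEs punish it.  Reinforcement
and punishment have separate rates: ``alpha`` for positive PEs and
``alpha * alpha_neg_ratio`` for negative ones (default ratio 0.25).  The
asymmetry is essential, not cosmetic: with symmetric rates, flipping an
error's feedback from negative to positive swings the criterion by
exactly ``alpha * s`` regardless of the trial's EV, so *which* confidence
level false feedback targets could not matter, contrary to the
PE-magnitude logic the simulator exists to express.

The PE entering the update is centred on a *calibrated critic*: a
per-response baseline, computed from the agent's own generative model as
a function of the current criterion (tabulated once per configuration and
interpolated), chosen so that the asymmetric update has exactly zero mean
drift under veridical feedback at every criterion.  The MS coding carries
a built-in main-effect offset -- its EV for new responses is capped at
0.5 while accuracy is well above that -- so the raw PE is persistently
positive after correct new responses and an uncentred learner drifts
conservative even under fully truthful feedback.  With the critic,
veridical sessions are driftless random walks, while false positive
feedback produces persistent pushes whose confidence-dependent magnitudes
are precisely what the biased-feedback manipulations target.  Set
``critic="none"`` for the raw-PE rule.

Response times come from the diffusion module, sampled from the
first-passage distribution conditional on the item class and the chosen
response; samples beyond the 1.5 s deadline become non-responses.

A free-recall transfer stage emulates the DRM paradigm: ten 15-word
lists each with one unpresented critical lure; candidates are output when
their strength exceeds a monitoring threshold linear in the terminal
recognition criterion, so liberal criteria yield more critical-lure
intrusions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import value_coding
from .ddm import ConditionalRTSampler, DDMParams
from .feedback import AdaptiveSchedule, MedianTrackingSchedule, VeridicalSchedule

__all__ = [
    "AgentConfig",
    "RecallConfig",
    "CONDITIONS",
    "make_schedule",
    "update_criterion",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "simulate_recall",
]

CONDITIONS = ("veridical", "fmri_liberal", "new_high", "new_low", "old_low", "old_high")

#: Session layouts: (n_trials, epoch scheme) per experimental design.
DESIGNS = {"fmri": (480, "runs_of_80"), "behav": (288, "thirds")}


@dataclass(frozen=True)
class AgentConfig:
    """Generative parameters for one simulated participant."""

    d_prime: float = 1.5
    sigma_old: float = 1.0
    c0: float = 0.0
    alpha: float = 0.05
    alpha_neg_ratio: float = 0.25
    coding: str = "MS"
    conf_scale: float = 2.0
    critic: str = "calibrated"
    deadline_s: float = 1.5
    ddm: DDMParams = field(default_factory=DDMParams)
    condition: str = "veridical"
    design: str = "fmri"
    n_trials: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_prime <= 0 or self.sigma_old <= 0 or self.conf_scale <= 0:
            raise ValueError("d_prime, sigma_old, conf_scale must be > 0")
        if self.alpha < 0 or not 0 <= self.alpha_neg_ratio <= 1:
            raise ValueError("alpha must be >= 0 and alpha_neg_ratio in [0, 1]")
        if self.coding not in ("MS", "ERO"):
            raise ValueError(f"coding must be MS or ERO, got {self.coding!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.critic not in ("calibrated", "none"):
            raise ValueError(f"critic must be 'calibrated' or 'none', got {self.critic!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def session_length(self) -> int:
        return self.n_trials if self.n_trials is not None else DESIGNS[self.design][0]


@dataclass(frozen=True)
class RecallConfig:
    """DRM free-recall transfer stage."""

    n_lists: int = 10
    list_length: int = 15
    studied_strength_mean: float = 1.5
    lure_strength_mean: float = 0.75
    new_strength_mean: float = 0.0
    strength_sd: float = 1.0
    transfer_gain: float = 1.0
    threshold_intercept: float = 0.75

    def __post_init__(self) -> None:
        if not (
            self.studied_strength_mean > self.lure_strength_mean > self.new_strength_mean
        ):
            raise ValueError("strength means must satisfy studied > lure > new")


def make_schedule(condition: str, seed: int, trials_total: int = 288):
    """Feedback schedule attached to an experimental condition."""
    if condition == "veridical":
        return VeridicalSchedule()
    if condition == "fmri_liberal":
        return MedianTrackingSchedule(seed=seed)
    targeted_response = "new_errors" if condition.startswith("new") else "old_errors"
    targeted_confidence = "high" if condition.endswith("high") else "low"
    return AdaptiveSchedule(
        targeted_response=targeted_response,
        targeted_confidence=targeted_confidence,
        trials_total=trials_total,
        seed=seed,
    )


def update_criterion(
    c: float, response: str, pe: float, alpha: float, alpha_neg: float | None = None
) -> float:
    """PE-proportional reinforcement of the decision threshold.

    Positive PE after a new response pushes the criterion up
    (conservative); positive PE after an old response pushes it down
    (liberal).  Negative PEs reverse the push, at rate ``alpha_neg``
    (defaults to ``alpha``, the symmetric rule).
    """
    if alpha_neg is None:
        alpha_neg = alpha
    s = 1.0 if response == "new" else -1.0
    rate = alpha if pe >= 0 else alpha_neg
    return c + rate * pe * s


def _trial_ev(coding: str, response: str, confidence: float) -> float:
    if coding == "MS":
        return value_coding.ms_ev(response, confidence)
    return value_coding.ero_ev(confidence)


class VeridicalCritic:
    """Rational critic: expected PE per response, plus the residual drift.

    For each criterion c (decision threshold d'/2 + c) the critic
    tabulates, under the agent's strength distributions, confidence map
    and *veridical* feedback:

    * ``baseline(response, c)`` -- the conditional mean PE
      ``E[PE | response]`` (an advantage baseline; absorbs the coding's
      main-effect calibration offset);
    * ``drift(c)`` -- the remaining expected criterion change per
      responded trial, per unit ``alpha``, of the centred asymmetric
      update.  With asymmetric reinforcement/punishment rates, centring
      alone leaves a small response-dependent drift; subtracting
      ``alpha * drift(c)`` each responded trial makes veridical sessions
      exactly driftless at every criterion (a homeostatic equilibrium
      around truthful feedback) while leaving the response to feedback
      *deviations* -- in particular false positive feedback -- untouched.

    Tabulated on a criterion grid by trapezoidal integration over the
    strength mixture and interpolated at run time.
    """

    C_GRID = np.linspace(-3.0, 3.0, 121)

    def __init__(self, cfg: "AgentConfig"):
        from scipy.stats import norm

        d, so, cs = cfg.d_prime, cfg.sigma_old, cfg.conf_scale
        gamma = cfg.alpha_neg_ratio
        self._b_new = np.empty_like(self.C_GRID)
        self._b_old = np.empty_like(self.C_GRID)
        self._drift = np.empty_like(self.C_GRID)
        for i, c in enumerate(self.C_GRID):
            theta = d / 2.0 + c
            net = 0.0
            for side in ("new", "old"):
                if side == "new":
                    m = np.linspace(theta - 10.0, theta, 1501)
                else:
                    m = np.linspace(theta, theta + 10.0 + d, 1501)
                f_new = 0.5 * norm.pdf(m, 0.0, 1.0)  # item-new component
                f_old = 0.5 * norm.pdf(m, d, so)  # item-old component
                q = np.clip(np.abs(m - theta) / cs, 0.0, 1.0)
                if cfg.coding == "MS":
                    ev = 0.5 * (1.0 - q) if side == "new" else 0.5 + 0.5 * q
                else:
                    ev = q
                # veridical outcome: 1 iff item class matches the response
                f_pos = f_new if side == "new" else f_old  # outcome 1 weight
                f_neg = f_old if side == "new" else f_new  # outcome 0 weight
                p_resp = np.trapezoid(f_pos + f_neg, m)
                mean_pe = (
                    np.trapezoid(f_pos * (1.0 - ev) + f_neg * (-ev), m) / p_resp
                )
                if side == "new":
                    self._b_new[i] = mean_pe
                else:
                    self._b_old[i] = mean_pe
                # residual drift of the centred asymmetric update (per alpha)
                x1 = (1.0 - ev) - mean_pe
                x0 = -ev - mean_pe
                g1 = np.where(x1 >= 0, x1, gamma * x1)
                g0 = np.where(x0 >= 0, x0, gamma * x0)
                s = 1.0 if side == "new" else -1.0
                net += s * np.trapezoid(f_pos * g1 + f_neg * g0, m)
            self._drift[i] = net  # expectation over all responded trials

    def baseline(self, response: str, c: float) -> float:
        table = self._b_new if response == "new" else self._b_old
        return float(np.interp(c, self.C_GRID, table))

    def drift(self, c: float) -> float:
        return float(np.interp(c, self.C_GRID, self._drift))


_CRITIC_CACHE: dict[tuple, VeridicalCritic] = {}


def _get_critic(cfg: AgentConfig) -> VeridicalCritic:
    key = (cfg.d_prime, cfg.sigma_old, cfg.conf_scale, cfg.coding, cfg.alpha_neg_ratio)
    if key not in _CRITIC_CACHE:
        _CRITIC_CACHE[key] = VeridicalCritic(cfg)
    return _CRITIC_CACHE[key]


def simulate_trial(
    cfg: AgentConfig,
    c_t: float,
    item_status: str,
    rng: np.random.Generator,
    rt_sampler: ConditionalRTSampler,
) -> dict:
    """One recognition trial (no feedback/learning; see simulate_session).

    The decision threshold on the evidence axis is ``d'/2 + c_t``; the
    agent responds old above it, and confidence is
    ``clamp(|strength - threshold| / conf_scale, 0, 1)``.
    """
    if item_status == "old":
        m = rng.normal(cfg.d_prime, cfg.sigma_old)
    else:
        m = rng.normal(0.0, 1.0)
    threshold = cfg.d_prime / 2.0 + c_t
    response = "old" if m > threshold else "new"
    confidence = float(np.clip(abs(m - threshold) / cfg.conf_scale, 0.0, 1.0))
    rt = rt_sampler.sample(item_status, response, rng)
    if rt > cfg.deadline_s:  # missed deadline: non-response
        return {
            "item_status": item_status,
            "strength": m,
            "response": None,
            "confidence": np.nan,
            "rt": np.nan,
            "correct": False,
        }
    return {
        "item_status": item_status,
        "strength": m,
        "response": response,
        "confidence": confidence,
        "rt": rt,
        "correct": response == item_status,
    }


def simulate_session(cfg: AgentConfig) -> pd.DataFrame:
    """A full recognition session for one agent.

    Returns one row per trial with the standard columns plus the latent
    memory strength and the criterion value in force on that trial.
    Byte-identical given identical config and seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_trials, rng_items = [np.random.default_rng(s) for s in ss.spawn(2)]
    schedule_seed = int(ss.generate_state(1)[0] % (2**31))

    n = cfg.session_length
    schedule = make_schedule(cfg.condition, schedule_seed, trials_total=n)
    rt_sampler = ConditionalRTSampler(cfg.ddm)

    # equal old/new counts, shuffled within each run-sized block
    n_trials_run, scheme = DESIGNS[cfg.design]
    block = 80 if scheme == "runs_of_80" else n // 3
    statuses: list[str] = []
    for start in range(0, n, block):
        size = min(block, n - start)
        half = size // 2
        blk = np.array(["old"] * half + ["new"] * (size - half))
        rng_items.shuffle(blk)
        statuses.extend(blk)

    c = cfg.c0
    critic = _get_critic(cfg) if cfg.critic == "calibrated" else None
    alpha_neg = cfg.alpha * cfg.alpha_neg_ratio
    rows = []
    for i, status in enumerate(statuses):
        rec = simulate_trial(cfg, c, status, rng_trials, rt_sampler)
        rec.update(trial=i + 1, run=i // block + 1, criterion=c)
        if rec["response"] is None:
            rec.update(outcome=0, false_feedback=False)
        else:
            fb = schedule.step(rec["response"], rec["correct"], rec["confidence"])
            rec.update(outcome=fb.outcome, false_feedback=fb.false_feedback)
            resp = rec["response"]
            ev = _trial_ev(cfg.coding, resp, rec["confidence"])
            pe = value_coding.pe(ev, fb.outcome)
            if critic is not None:
                b = critic.baseline(resp, c)
                comp = cfg.alpha * critic.drift(c)  # homeostatic counter-drift
            else:
                b, comp = 0.0, 0.0
            c = update_criterion(c, resp, pe - b, cfg.alpha, alpha_neg) - comp
        rows.append(rec)

    cols = [
        "trial", "run", "item_status", "strength", "response", "confidence",
        "rt", "correct", "outcome", "false_feedback", "criterion",
    ]
    return pd.DataFrame(rows)[cols]


def simulate_cohort(configs: list[AgentConfig]) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate many agents; returns their sessions and a manifest table."""
    seeds = [c.seed for c in configs]
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds across agents", stacklevel=2)
    sessions = [simulate_session(c) for c in configs]
    manifest = pd.DataFrame(
        {
            "participant": [f"agent{i:03d}" for i in range(len(configs))],
            "condition": [c.condition for c in configs],
            "coding": [c.coding for c in configs],
            "design": [c.design for c in configs],
            "seed": seeds,
            "n_trials": [len(s) for s in sessions],
        }
    )
    return sessions, manifest


def default_cohort_configs(
    conditions: list[str],
    n_agents: int,
    coding: str = "MS",
    design: str = "behav",
    seed: int = 0,
    **overrides,
) -> list[AgentConfig]:
    """Convenience builder: ``n_agents`` per condition with distinct seeds."""
    base = AgentConfig(coding=coding, design=design, **overrides)
    out = []
    k = 0
    for cond in conditions:
        for _ in range(n_agents):
            out.append(replace(base, condition=cond, seed=seed + 1000 * k + 7))
            k += 1
    return out


def simulate_recall(
    terminal_criterion: float,
    cfg: RecallConfig = RecallConfig(),
    seed: int = 0,
) -> dict:
    """DRM free-recall stage driven by the transferred recognition criterion.

    Candidate items on each list are the 15 studied words plus the
    critical lure; an item is verbalized when its strength exceeds
    ``transfer_gain * terminal_criterion + threshold_intercept``.
    Returns the critical-lure count (0..n_lists) and per-list studied
    recall.
    """
    rng = np.random.default_rng(seed)
    threshold = cfg.transfer_gain * terminal_criterion + cfg.threshold_intercept
    lure_count = 0
    studied_recalled = []
    for _ in range(cfg.n_lists):
        studied = rng.normal(cfg.studied_strength_mean, cfg.strength_sd, cfg.list_length)
        lure = rng.normal(cfg.lure_strength_mean, cfg.strength_sd)
        studied_recalled.append(int((studied > threshold).sum()))
        lure_count += int(lure > threshold)
    return {
        "lure_count": lure_count,
        "studied_recalled": studied_recalled,
        "threshold": float(threshold),
    }
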
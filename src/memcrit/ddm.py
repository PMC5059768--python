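"""Drift-diffusion model of the recognition decision.

Evidence accumulates from a relative start point ``z_rel`` (0.5 =
unbiased) between two absorbing boundaries separated by ``a``; the upper
boundary is the *old* response, the lower the *new* response.  Diffusion
coefficient is fixed at 1 (scaling convention).  The item-driven drift has
magnitude ``v`` (positive toward old for studied items, toward new for
unstudied items) and the drift criterion ``dc`` adds a constant to the
drift for both item classes:

    effective drift = +v + dc   (studied / old items)
    effective drift = -v + dc   (unstudied / new items)

so a positive ``dc`` is a liberal memory-level bias.  A response-level
bias instead moves the start point ``z_rel`` toward the old boundary.

Two epoch-varying model variants with equal parameter counts are fit by
maximum likelihood:

* Drift Criterion model: shared ``a, t0, v``, ``z_rel`` fixed at 0.5,
  one ``dc`` per epoch (memory-level learning).
* Response Bias model: shared ``a, t0, v``, ``dc`` fixed at 0, one
  ``z_rel`` per epoch (response-level learning).

First-passage densities use the small-time / large-time series with an
automatic switch at truncation error 1e-7.  Responses faster than 300 ms
are excluded from fitting as guesses, as are non-responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .sdt import epoch_boundaries

__all__ = [
    "DDMParams",
    "DDMFit",
    "fpt_density",
    "absorption_probability",
    "simulate_ddm",
    "ConditionalRTSampler",
    "fit_model",
    "compare_models",
    "RT_EXCLUSION_S",
]

RT_EXCLUSION_S = 0.3  # responses faster than this are treated as guesses
_EPS = 1e-7  # series truncation error bound


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one epoch."""

    a: float = 1.5
    t0: float = 0.3
    v: float = 1.5
    z_rel: float = 0.5
    dc: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.z_rel < 1:
            raise ValueError("z_rel must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    def effective_drift(self, item_status: str) -> float:
        return (self.v if item_status == "old" else -self.v) + self.dc


@dataclass
class DDMFit:
    model: str
    params: dict
    epoch_labels: list
    log_likelihood: float
    n_params: int
    n_trials: int
    aic: float
    bic: float
    converged: bool
    n_excluded_fast: int
    trial_index: np.ndarray = field(repr=False, default=None)

    @property
    def neg_dc(self) -> list[float] | None:
        """dc sign-flipped for plotting against SDT criterion (liberal down)."""
        if self.model != "drift_criterion":
            return None
        return [-d for d in self.params["dc"]]


def _wfpt_lower(t: np.ndarray, v: float, a: float, w: float) -> np.ndarray:
    """Density of first passage through the *lower* boundary at time t.

    Navarro-Fuss style evaluation: normalized time tau = t / a**2; for each
    t the cheaper of the small-time and large-time series is used, with
    term counts chosen so the truncation error is below ``_EPS``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tau = t[pos] / a**2

    # term counts per element
    with np.errstate(divide="ignore", invalid="ignore"):
        kl = np.where(
            np.pi * tau * _EPS < 1,
            np.maximum(
                np.sqrt(np.maximum(-2 * np.log(np.pi * tau * _EPS), 0) / (np.pi**2 * tau)),
                1.0 / (np.pi * np.sqrt(tau)),
            ),
            1.0 / (np.pi * np.sqrt(tau)),
        )
        ks = np.where(
            2 * np.sqrt(2 * np.pi * tau) * _EPS < 1,
            np.maximum(
                2 + np.sqrt(np.maximum(-2 * tau * np.log(2 * np.sqrt(2 * np.pi * tau) * _EPS), 0)),
                np.sqrt(tau) + 1,
            ),
            2.0,
        )

    use_small = ks < kl
    dens = np.empty_like(tau)

    if np.any(use_small):
        ts = tau[use_small]
        K = int(np.ceil(ks[use_small].max()))
        ks_range = np.arange(-((K - 1) // 2), ((K - 1) // 2) + (K - 1) % 2 + 1)
        terms = (w + 2 * ks_range[:, None]) * np.exp(
            -((w + 2 * ks_range[:, None]) ** 2) / (2 * ts[None, :])
        )
        dens[use_small] = terms.sum(axis=0) / np.sqrt(2 * np.pi * ts**3)

    if np.any(~use_small):
        tl = tau[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        ks_range = np.arange(1, K + 1)
        terms = (
            ks_range[:, None]
            * np.exp(-(ks_range[:, None] ** 2) * np.pi**2 * tl[None, :] / 2)
            * np.sin(ks_range[:, None] * np.pi * w)
        )
        dens[~use_small] = np.pi * terms.sum(axis=0)

    dens = dens * np.exp(-v * a * w - v**2 * (tau * a**2) / 2) / a**2
    out[pos] = np.maximum(dens, 0.0)
    return out


def fpt_density(rt, boundary: str, params: DDMParams, item_status: str) -> np.ndarray:
    """First-passage density at observed RT(s) for one boundary.

    ``boundary`` names the response: ``"old"`` (upper) or ``"new"``
    (lower).  RTs at or below ``t0`` get density 0.
    """
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    t = rt - params.t0
    v_eff = params.effective_drift(item_status)
    if boundary == "old":
        dens = _wfpt_lower(t, -v_eff, params.a, 1.0 - params.z_rel)
    elif boundary == "new":
        dens = _wfpt_lower(t, v_eff, params.a, params.z_rel)
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    return dens if dens.size > 1 else dens


def absorption_probability(params: DDMParams, item_status: str, boundary: str = "old") -> float:
    """Closed-form probability of absorption at a boundary.

    For drift v and absolute start z in (0, a):
    P(upper) = (1 - exp(-2 v z)) / (1 - exp(-2 v a)), with the v -> 0
    limit z / a.
    """
    v = params.effective_drift(item_status)
    z_abs = params.z_rel * params.a
    if abs(v) < 1e-12:
        p_upper = params.z_rel
    else:
        p_upper = (1.0 - np.exp(-2 * v * z_abs)) / (1.0 - np.exp(-2 * v * params.a))
    return float(p_upper if boundary == "old" else 1.0 - p_upper)


def simulate_ddm(
    params: DDMParams,
    item_status: str,
    n: int,
    seed: int,
    dt: float = 1e-3,
    t_max: float = 10.0,
) -> pd.DataFrame:
    """Euler-Maruyama forward simulation of n trials.

    Returns a table with ``choice`` ('old'/'new'; NaN if unabsorbed by
    ``t_max``) and ``rt`` (decision time + t0).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if dt >= 0.1 * params.a**2:
        raise ValueError("step size too coarse for this boundary separation")
    rng = np.random.default_rng(seed)
    v = params.effective_drift(item_status)
    x = np.full(n, params.z_rel * params.a)
    rt = np.full(n, np.nan)
    choice = np.full(n, None, dtype=object)
    alive = np.ones(n, dtype=bool)
    sqdt = np.sqrt(dt)
    n_steps = int(np.ceil(t_max / dt))
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x[idx] += v * dt + sqdt * rng.standard_normal(idx.size)
        hit_up = x[idx] >= params.a
        hit_lo = x[idx] <= 0.0
        t_now = step * dt + params.t0
        up_idx = idx[hit_up]
        lo_idx = idx[hit_lo & ~hit_up]
        rt[up_idx] = t_now
        choice[up_idx] = "old"
        rt[lo_idx] = t_now
        choice[lo_idx] = "new"
        alive[up_idx] = False
        alive[lo_idx] = False
    return pd.DataFrame({"choice": choice, "rt": rt})


class ConditionalRTSampler:
    """Inverse-CDF sampler for RT conditional on (item status, response).

    Tabulates the first-passage density on a fine grid once per
    combination and samples by linear interpolation of the conditional
    CDF.  Used by the synthetic-participant generator, where the choice
    is made by the signal-detection stage and only the RT comes from the
    diffusion process.
    """

    def __init__(self, params: DDMParams, t_max: float = 5.0, n_grid: int = 4096):
        self.params = params
        grid = np.linspace(params.t0 + 1e-4, params.t0 + t_max, n_grid)
        self._tables = {}
        for status in ("old", "new"):
            for resp in ("old", "new"):
                dens = fpt_density(grid, resp, params, status)
                cdf = np.cumsum(dens)
                cdf *= (grid[1] - grid[0])
                mass = cdf[-1]
                if mass <= 0:
                    raise ValueError("degenerate conditional RT distribution")
                self._tables[(status, resp)] = (grid, cdf / mass)

    def sample(self, item_status: str, response: str, rng: np.random.Generator, n: int = 1):
        grid, cdf = self._tables[(item_status, response)]
        u = rng.random(n)
        rt = np.interp(u, cdf, grid)
        return float(rt[0]) if n == 1 else rt


# ---------------------------------------------------------------------------
# Fitting


def _prepare(trials: pd.DataFrame, epoch_scheme: str):
    trials = trials.reset_index(drop=True)
    epochs = np.full(len(trials), -1)
    labels = []
    for i, (lo, hi) in enumerate(epoch_boundaries(len(trials), epoch_scheme)):
        epochs[lo:hi] = i
        labels.append(f"epoch{i + 1}")
    t = trials.assign(_epoch=epochs)
    responded = t["response"].isin(("old", "new")) & t["rt"].notna()
    n_fast = int((responded & (t["rt"] < RT_EXCLUSION_S)).sum())
    keep = responded & (t["rt"] >= RT_EXCLUSION_S)
    t = t[keep]
    return t, labels, n_fast


def _neg_loglik(theta, model, data_groups, n_epochs):
    a, t0 = theta[0], theta[1]
    v = theta[2]
    per_epoch = theta[3:]
    ll = 0.0
    for (epoch, status, resp), rts in data_groups.items():
        if model == "drift_criterion":
            p = DDMParams(a=a, t0=t0, v=v, z_rel=0.5, dc=per_epoch[epoch])
        else:
            p = DDMParams(a=a, t0=t0, v=v, z_rel=per_epoch[epoch], dc=0.0)
        dens = fpt_density(rts, resp, p, status)
        ll += np.sum(np.log(np.maximum(dens, 1e-12)))
    return -ll


def fit_model(
    trials: pd.DataFrame,
    model: str = "drift_criterion",
    epoch_scheme: str = "runs_of_80",
    seed: int = 0,
    n_starts: int = 10,
    n_polish: int = 3,
) -> DDMFit:
    """Maximum-likelihood fit of one epoch-varying model variant.

    ``model`` is ``"drift_criterion"`` (dc free per epoch, z fixed 0.5) or
    ``"response_bias"`` (z free per epoch, dc fixed 0); both share
    ``a, t0, v`` across epochs and have equal parameter counts.
    ``n_starts`` Latin-hypercube initial points are screened by
    likelihood; bounded L-BFGS-B polishes the ``n_polish`` best.
    """
    if model not in ("drift_criterion", "response_bias"):
        raise ValueError(f"unknown model {model!r}")
    data, labels, n_fast = _prepare(trials, epoch_scheme)
    if len(data) == 0:
        raise ValueError("no usable trials after exclusions")
    n_epochs = len(labels)

    groups: dict = {}
    for (epoch, status, resp), g in data.groupby(["_epoch", "item_status", "response"]):
        groups[(int(epoch), status, resp)] = g["rt"].to_numpy(dtype=float)

    min_rt = float(data["rt"].min())
    lo = [0.5, 0.05, 0.0] + ([-3.0] * n_epochs if model == "drift_criterion" else [0.05] * n_epochs)
    hi = [4.0, max(min_rt - 1e-3, 0.06), 5.0] + (
        [3.0] * n_epochs if model == "drift_criterion" else [0.95] * n_epochs
    )
    lo, hi = np.array(lo), np.array(hi)

    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    scores = np.array([_neg_loglik(s, model, groups, n_epochs) for s in starts])
    order = np.argsort(scores)[: max(n_polish, 1)]

    best = None
    converged = False
    for i in order:
        res = optimize.minimize(
            _neg_loglik,
            starts[i],
            args=(model, groups, n_epochs),
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 200, "ftol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    theta = best.x
    k = 3 + n_epochs
    ll = -float(best.fun)
    n = len(data)
    per_epoch = list(map(float, theta[3:]))
    params = {
        "a": float(theta[0]),
        "t0": float(theta[1]),
        "v": float(theta[2]),
        "dc": per_epoch if model == "drift_criterion" else [0.0] * n_epochs,
        "z_rel": per_epoch if model == "response_bias" else [0.5] * n_epochs,
    }
    return DDMFit(
        model=model,
        params=params,
        epoch_labels=labels,
        log_likelihood=ll,
        n_params=k,
        n_trials=n,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
        converged=converged,
        n_excluded_fast=n_fast,
        trial_index=data.index.to_numpy(),
    )


def compare_models(fit_dc: DDMFit, fit_bias: DDMFit) -> dict:
    """Likelihood comparison of two fits on the identical trial set."""
    if fit_dc.n_trials != fit_bias.n_trials or not np.array_equal(
        fit_dc.trial_index, fit_bias.trial_index
    ):
        raise ValueError("fits are not on identical trial sets")
    dll = fit_dc.log_likelihood - fit_bias.log_likelihood
    daic = fit_dc.aic - fit_bias.aic
    winner = fit_dc.model if daic < 0 else fit_bias.model
    if daic == 0:
        winner = "tie"
    return {
        "delta_loglik": float(dll),
        "delta_aic": float(daic),
        "delta_bic": float(fit_dc.bic - fit_bias.bic),
        "winner": winner,
    }
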
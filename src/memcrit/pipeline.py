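"""End-to-end orchestration: simulate -> code -> SDT -> DDM -> regressors.

A :class:`RunConfig` (loadable from YAML) fixes the experimental design,
the conditions and cohort sizes, the agents' learning coding, which
analysis stages run, and one master seed from which every per-agent and
per-stage seed is derived deterministically.  ``run_pipeline`` executes
the enabled stages in dependency order, writes trial TSVs plus JSON
summaries under the output directory, and is idempotent given identical
config and seed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import AgentConfig, DESIGNS, default_cohort_configs, simulate_recall
from .ddm import compare_models, fit_model
from .feedback import schedule_audit
from .io import round_sig, write_json, write_trials
from .regressors import coding_correlation
from .sdt import criterion_trajectory, group_contrast
from .value_coding import code_trials

log = logging.getLogger("memcrit")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    design: str = "behav"
    conditions: list = field(default_factory=lambda: ["veridical"])
    n_per_condition: int = 1
    coding: str = "MS"
    alpha: float = 0.05
    n_trials: int | None = None
    run_sdt: bool = True
    run_ddm: bool = False
    run_regressors: bool = False
    run_recall: bool = False
    master_seed: int = 0
    out_dir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _derive_seed(master_seed: int, *tokens) -> int:
    # crc32 keeps token hashing stable across processes (unlike hash())
    ss = np.random.SeedSequence(
        [master_seed, *(zlib.crc32(str(t).encode()) for t in tokens)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns (and writes) the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = DESIGNS[config.design][1]

    configs = default_cohort_configs(
        config.conditions,
        config.n_per_condition,
        coding=config.coding,
        design=config.design,
        alpha=config.alpha,
        n_trials=config.n_trials,
        seed=_derive_seed(config.master_seed, "agents"),
    )

    report: dict = {
        "software_version": __version__,
        "schema_version": 1,
        "config": asdict(config),
        "participants": {},
    }
    sessions = {}
    manifest_rows = []
    for i, acfg in enumerate(configs):
        pid = f"agent{i:03d}"
        try:
            from .agents import simulate_session

            session = code_trials(simulate_session(acfg))
        except Exception:
            log.exception("stage simulate failed for %s", pid)
            report["participants"][pid] = {"error": "simulate"}
            continue
        sessions[pid] = session
        write_trials(session, out / f"{pid}_trials.tsv")
        manifest_rows.append(
            {"participant": pid, "condition": acfg.condition, "coding": acfg.coding,
             "seed": acfg.seed, "file": f"{pid}_trials.tsv"}
        )
        entry: dict = {"condition": acfg.condition, "seed": acfg.seed,
                       "audit": schedule_audit(session)}

        if config.run_sdt:
            traj = criterion_trajectory(session, scheme)
            entry["sdt"] = [
                None if s is None else {"epoch": s.epoch_label, "c": s.criterion_c,
                                        "d_prime": s.d_prime,
                                        "hit_rate": s.hit_rate, "fa_rate": s.fa_rate}
                for s in traj
            ]
            valid = [s for s in traj if s is not None]
            if valid:
                entry["initial_c"] = valid[0].criterion_c
                entry["terminal_c"] = valid[-1].criterion_c

        if config.run_ddm:
            fit_dc = fit_model(session, "drift_criterion", scheme,
                               seed=_derive_seed(config.master_seed, "ddm", pid))
            fit_bias = fit_model(session, "response_bias", scheme,
                                 seed=_derive_seed(config.master_seed, "ddm2", pid))
            entry["ddm"] = {
                "drift_criterion": {"loglik": fit_dc.log_likelihood, "aic": fit_dc.aic,
                                    "params": fit_dc.params, "converged": fit_dc.converged},
                "response_bias": {"loglik": fit_bias.log_likelihood, "aic": fit_bias.aic,
                                  "params": fit_bias.params, "converged": fit_bias.converged},
                "comparison": compare_models(fit_dc, fit_bias),
            }

        if config.run_recall and "terminal_c" in entry:
            entry["recall"] = simulate_recall(
                entry["terminal_c"],
                seed=_derive_seed(config.master_seed, "recall", pid),
            )
        report["participants"][pid] = entry

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)

    if config.run_sdt:
        terminal = pd.DataFrame(
            [
                {"participant": pid, "condition": e["condition"],
                 "terminal_c": e["terminal_c"]}
                for pid, e in report["participants"].items()
                if "terminal_c" in e
            ]
        )
        if len(terminal):
            report["group_contrast"] = group_contrast(terminal)

    if config.run_regressors and sessions:
        report["regressor_correlations"] = {
            "pe": coding_correlation(list(sessions.values()), "ms_pe", "ero_pe",
                                     seed=_derive_seed(config.master_seed, "reg_pe")),
            "ev": coding_correlation(list(sessions.values()), "ms_ev", "ero_ev",
                                     seed=_derive_seed(config.master_seed, "reg_ev")),
        }

    report = round_sig(report)
    write_json(report, out / "report.json")
    log.info("pipeline complete: %d participants -> %s", len(sessions), out)
    return report
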
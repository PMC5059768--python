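#!/usr/bin/env python
"""Shared vs unique regressor variance and GLM variance attribution.

Builds HRF-convolved parametric regressors for the MS and ERO codings on
simulated scanner sessions, reports their Fisher-z-averaged correlation
(PE and EV separately), and runs the toy GLM recovery experiment in which
both PE regressors compete for variance against a synthetic signal with a
known generating coding.  Writes results/regressor_variance.json.
"""

import json

from memcrit.agents import AgentConfig, simulate_session
from memcrit.io import round_sig
from memcrit.regressors import coding_correlation, toy_glm_recovery
from memcrit.value_coding import code_trials

N_AGENTS = 8
N_RECOVERY_SEEDS = 50
OUT = "results/regressor_variance.json"


def main() -> None:
    sessions = [
        code_trials(simulate_session(
            AgentConfig(condition="fmri_liberal", design="fmri", seed=800 + s)))
        for s in range(N_AGENTS)
    ]
    pe_corr = coding_correlation(sessions, "ms_pe", "ero_pe", seed=1)
    ev_corr = coding_correlation(sessions, "ms_ev", "ero_ev", seed=1)

    wins = {"ms_pe": 0, "ero_pe": 0}
    for gen in wins:
        wins[gen] = sum(
            toy_glm_recovery(sessions[s % N_AGENTS], gen, beta=1.0, noise_sd=1.0,
                             seed=s)["winner"] == gen
            for s in range(N_RECOVERY_SEEDS)
        )

    report = {
        "pe_regressor_correlation": pe_corr,
        "ev_regressor_correlation": ev_corr,
        "glm_recovery_wins_of_50": wins,
    }
    with open(OUT, "w") as fh:
        json.dump(round_sig(report), fh, indent=1)

    print(f"{N_AGENTS} simulated scanner sessions, TR = 2 s, double-gamma HRF")
    print(f"convolved MS-PE vs ERO-PE: R^2 = {pe_corr['r_squared']:.2f}")
    print(f"convolved MS-EV vs ERO-EV: R^2 = {ev_corr['r_squared']:.2f}")
    print("(the PE codings share more variance than the EV codings)")
    print(f"GLM attribution wins out of {N_RECOVERY_SEEDS}: {wins}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
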
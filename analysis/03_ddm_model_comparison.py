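#!/usr/bin/env python
"""Memory-level vs response-level learning: diffusion model comparison.

Fits the Drift Criterion model (epoch-varying dc, start point fixed) and
the Response Bias model (epoch-varying start point, dc fixed) -- equal
parameter counts -- to simulated scanner sessions by maximum likelihood,
and reports the per-participant likelihood comparison.  Writes
results/ddm_model_comparison.csv.
"""

import pandas as pd

from memcrit.agents import default_cohort_configs, simulate_session
from memcrit.ddm import compare_models, fit_model

N_AGENTS = 8
OUT = "results/ddm_model_comparison.csv"


def main() -> None:
    configs = default_cohort_configs(["fmri_liberal"], N_AGENTS, coding="MS",
                                     design="fmri", seed=71)
    rows = []
    for i, cfg in enumerate(configs):
        session = simulate_session(cfg)
        fit_dc = fit_model(session, "drift_criterion", "runs_of_80", seed=i)
        fit_z = fit_model(session, "response_bias", "runs_of_80", seed=100 + i)
        cmp = compare_models(fit_dc, fit_z)
        rows.append({
            "participant": f"agent{i:02d}",
            "loglik_dc": fit_dc.log_likelihood,
            "loglik_bias": fit_z.log_likelihood,
            "delta_aic": cmp["delta_aic"],
            "winner": cmp["winner"],
            "terminal_neg_dc": fit_dc.neg_dc[-1],
            "n_excluded_fast": fit_dc.n_excluded_fast,
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT, index=False, float_format="%.9g")

    frac = (df.winner == "drift_criterion").mean()
    print(f"{N_AGENTS} simulated scanner participants, 6-run epoch scheme")
    print(df[["participant", "delta_aic", "winner", "terminal_neg_dc"]]
          .round(2).to_string(index=False))
    print(f"\nDrift Criterion model favoured in {frac:.0%} of participants")
    print("(-dc reported so liberal values are negative, matching the SDT axis)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
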
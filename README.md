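# memcrit

Reinforcement-driven criterion dynamics in recognition memory: a tested,
fully simulated pipeline for studying how trial-by-trial reward prediction
errors regulate the old/new decision criterion.

## The scientific problem

In a recognition test, an observer sees a mix of studied ("old") and
unstudied ("new") items and must decide, item by item, whether each one is
old. Signal detection theory describes the decision with two overlapping
memory-strength distributions and a criterion *c*: respond "old" when
retrieved strength exceeds the criterion. The criterion is not fixed —
trial feedback can push it around, and deliberately *false* positive
feedback ("Correct!" after an error) biases it in predictable directions.

This package implements the computational machinery for a
reinforcement-learning account of those shifts. Each recognition decision
carries an expected value (EV) of a positive outcome, and feedback
generates a prediction error

    PE = outcome − EV,   outcome ∈ {0, 1},  EV ∈ [0, 1],  PE ∈ [−1, 1].

Two rival codings map the continuous confidence rating *q* ∈ [0, 1] onto
EV:

* **Memory strength (MS)** — EV tracks retrieved strength:
  `EV = 0.5·(1 − q)` for new responses (range 0–0.5) and
  `EV = 0.5 + 0.5·q` for old responses (range 0.5–1);
* **Expected response outcome (ERO)** — EV equals confidence,
  `EV = q`, identically for both responses;

plus a starred control coding MS\* (`1 − q` / `q`) that removes the MS
coding's old/new main effect. Positive PEs reinforce the decision just
taken — conservative after a "new" response, liberal after an "old"
response — with strength proportional to the PE magnitude. Because the
codings assign different PE magnitudes to the same trials, they make
opposite predictions when false feedback is targeted at high- versus
low-confidence errors, and those predictions are testable both
behaviourally (criterion trajectories) and at the level of model-based
fMRI regressors.

The package provides, as separately usable modules:

* `memcrit.value_coding` — trial-level EV/PE under the MS, ERO and MS\*
  codings;
* `memcrit.feedback` — both false-feedback schedules: the online
  median-tracking schedule (100% of below-median-confidence false alarms
  rewarded, ~40% above; ~70% overall) and the adaptive controller that
  targets ~30 false-feedback instances per 288-trial session;
* `memcrit.sdt` — criterion `c = −(z(HR) + z(FAR))/2` and `d′` per epoch
  (six 80-trial runs or thirds of 96), trajectories, group contrasts;
* `memcrit.agents` — synthetic participants whose criterion learns from
  PEs, for every experimental condition, plus a DRM free-recall transfer
  stage;
* `memcrit.ddm` — a Wiener diffusion engine (first-passage densities,
  simulation, maximum-likelihood fitting) comparing memory-level
  learning (epoch-varying drift criterion *dc*) against response-level
  learning (epoch-varying start point *z*), with equal parameter counts;
* `memcrit.regressors` — HRF-convolved parametric regressors (EV at trial
  onset, PE at feedback), shared/unique variance quantification, serial
  orthogonalization, and toy GLM recovery;
* `memcrit.pipeline` / `memcrit.cli` — end-to-end orchestration with a
  `memcrit` command-line entry point.

No human data ship with the package: every analysis runs on the synthetic
cohorts, which is what makes each stage testable end to end.

## Worked example

Simulate the five-group behavioural experiment for both codings and
summarize terminal criteria:

```bash
python analysis/02_targeted_feedback_groups.py
```

```
MS-coded cohorts (30/group), mean terminal c:
condition
new_high     0.286
new_low      0.214
veridical   -0.034
old_high    -0.369
old_low     -0.592
New-High vs New-Low planned contrast: +0.072 (t=1.06)

ERO-coded cohorts (30/group), mean terminal c:
condition
new_high     0.377
new_low      0.753
veridical   -0.022
old_high    -0.350
old_low     -0.623
New-High vs New-Low planned contrast: -0.377 (t=-3.93)
```

Reading the numbers: groups falsely rewarded for *new* errors end
conservative (positive terminal *c*), groups falsely rewarded for *old*
errors end liberal (negative), and the veridical control stays neutral.
The codings disagree on the planned contrast: MS learners shift more when
*high*-confidence new errors are rewarded (larger MS-PE), ERO learners
when *low*-confidence new errors are (larger ERO-PE) — the signature that
separates the two accounts.

The other numbered scripts in `analysis/` run the scanner-design liberal
shift (01), the drift-criterion vs response-bias diffusion comparison
(03), regressor shared/unique variance and GLM attribution (04), and the
recognition-to-recall transfer (05); each prints its findings and writes
a small table under `results/`.

A quick library-level example:

```python
from memcrit.agents import AgentConfig, simulate_session
from memcrit.sdt import criterion_trajectory

session = simulate_session(AgentConfig(condition="fmri_liberal", design="fmri", seed=1))
traj = criterion_trajectory(session, "runs_of_80")
print([round(s.criterion_c, 2) for s in traj])   # six per-run criteria
```

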
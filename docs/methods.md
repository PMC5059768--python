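# Methods

This note documents the models implemented in `memcrit`, the defaults and
why they were chosen, the numerical techniques, and what the synthetic
cohorts do and do not establish about real behaviour.

## Value codings

EVs are linear in confidence between their endpoint anchors. The anchors
fully determine each map once linearity is assumed, and linearity is the
simplest map consistent with all of them (including the starred-coding
worked example 0.8 → 0.2): MS uses `0.5·(1−q)` / `0.5+0.5·q` for new/old
responses, ERO is the identity `q`, and MS\* uses `1−q` / `q`. Confidence
exactly 0 or 1 is legal input (the rating procedure allows responses at
either extreme of the scale). Trials without a response produce no coding
values: EV and PE exist only for decisions actually made. The PE is
always `outcome − EV`, with positive feedback (veridical *or* false)
coded 1 and negative feedback 0.

## Feedback schedules

**Median tracking.** The running median of false-alarm confidences is
recomputed before each trial and the new observation appended after the
decision. With fewer than two observed false alarms the provisional
median is 0.5, the midpoint of the scale. A confidence exactly at the
median takes the 40% arm (a side must be chosen; ties have measure zero
for continuous ratings). With any continuous confidence distribution the
long-run delivery rate on false alarms converges to
(1.0 + 0.4)/2 = 70%.

**Adaptive controller.** Eligibility is an error of the targeted
response type whose confidence falls on the targeted side of a running
median *for that error type* — the same mechanism as the scanner
schedule, reused because the original confidence-targeting rule is not
published in the available text. Before each trial the controller
estimates the eligible-error rate as (eligible errors seen)/(trials
elapsed) — with prior `prior_error_rate/2 = 0.15` before any trial, the
division by two reflecting the median split — and delivers false
feedback to an eligible error with probability
`clamp((target − delivered) / max(rate · trials_remaining, 1), 0, 1)`.
Tracking the *eligible* rate rather than the raw error rate keeps the
controller's denominator consistent with the population it can actually
deliver to; with a raw-rate denominator it systematically undershoots the
target by roughly half. With a stationary targeted-error rate near 0.3
the mean delivered count over 200 sessions is ~29.5 against the target
of 30.

## Signal detection

`c = −(z(HR)+z(FAR))/2`, `d′ = z(HR)−z(FAR)`; liberal is negative.
Perfect rates get the log-linear correction (add 0.5 to each cell and 1
to each class total), applied only when a rate is 0 or 1 and then to both
classes jointly so the two rates stay comparable. Epochs are cut on
session trial order — six 80-trial runs for the 480-trial scanner design,
thirds of 96 for the 288-trial behavioural design — and non-responses are
excluded within epochs. The terminal (final-epoch) criterion is the
primary endpoint: false feedback begins at trial one, so the initial
epoch is not a clean baseline and difference scores are avoided.

## Synthetic participants

Each agent draws memory strength from Normal(0, 1) for new items and
Normal(d′, σ_old) for studied items (defaults d′ = 1.5, σ_old = 1; an
unequal-variance option exists but the equal-variance model is the
default). The decision threshold on the evidence axis is `d′/2 + c`, so
the agent's criterion c is in SDT units: c = 0 is the intersection of the
equal-variance distributions and matches the criterion recovered from the
agent's own hit/false-alarm rates. Confidence is the clamped scaled
distance from threshold, `clip(|m − θ|/conf_scale, 0, 1)` with
`conf_scale = 2` so that two evidence units span the scale.

Response times are drawn from the diffusion module's first-passage
distribution conditional on the item class and the response chosen by the
signal-detection stage (inverse-CDF sampling from tabulated densities;
defaults a = 1.5, t₀ = 0.3 s, v = 1.5). Samples beyond the 1.5 s deadline
are recorded as non-responses; under the defaults the non-response rate
is ~2–3%, inside the under-5% band the task design anticipates.

### Learning rule

The criterion updates after every responded, fed-back trial:

    c ← c + rate · (PE − b_r(c)) · s,   s = +1 (new resp.), −1 (old resp.)

with three deliberate features.

1. **Asymmetric rates.** Reinforcement (centred PE ≥ 0) uses `alpha`
   (default 0.05); punishment uses `alpha · alpha_neg_ratio` (default
   ratio 0.25). The asymmetry is load-bearing: with symmetric rates,
   flipping an error's feedback from negative to positive changes the
   session's criterion by exactly `alpha·s` per instance *regardless of
   the trial's EV*, so targeting false feedback at high versus low
   confidence could not produce different group outcomes — contrary to
   the PE-magnitude logic the simulator exists to express. Reinforcement
   dominating punishment restores the confidence dependence.

2. **A calibrated critic.** `b_r(c)` is the expected PE for response r
   under *veridical* feedback, computed from the agent's own generative
   model as a function of the current criterion (tabulated on a grid of
   c by trapezoidal integration over the strength mixture, interpolated
   at run time). The MS coding is miscalibrated by construction — its EV
   for new responses is capped at 0.5 while accuracy is ~0.77 — so raw
   MS-PEs are persistently positive after correct new responses and an
   uncentred learner drifts conservative even under fully truthful
   feedback. The critic absorbs that main-effect offset.

3. **A homeostatic counter-drift.** With asymmetric rates, centring
   alone leaves a small residual drift; the expected centred update per
   responded trial under veridical feedback, `d(c)`, is tabulated
   alongside the baselines and `alpha·d(c)` subtracted every responded
   trial. Veridical sessions are then driftless random walks at every
   criterion, while responses to feedback *deviations* — false positive
   feedback in particular — are untouched.

Setting `critic="none"` recovers the raw rule for comparison. Under the
defaults the simulator reproduces all the qualitative targets: veridical
cohorts end near c₀; the scanner condition shifts liberal in every agent;
MS cohorts order New-High > New-Low > Veridical > Old-High > Old-Low in
mean terminal criterion while ERO cohorts reverse the two New groups; and
terminal criterion anticorrelates with critical-lure recall.

### Recall transfer

The DRM stage presents ten 15-word lists, each with one unpresented
critical lure. Strengths are Gaussian with means 1.5 (studied), 0.75
(lure), 0 (unrelated), sd 1; an item is verbalized when its strength
exceeds `transfer_gain · c_terminal + 0.75`, a single linear mapping from
the recognition criterion to the recall-monitoring threshold. Only the
*sign* of the criterion–lure-count association is asserted; the slope and
intercept are not calibrated against human recall rates.

## Diffusion model

Wiener process, diffusion coefficient fixed at 1, upper boundary = old
response. The drift criterion adds to the item-driven drift
(`+v+dc` studied, `−v+dc` unstudied); response bias moves the relative
start point `z`. First-passage densities use the standard small-time /
large-time series with term counts chosen for truncation error ≤ 1e−7
and an automatic switch to whichever series is cheaper; the density
integrates to the closed-form absorption probability
`(1−e^{−2vz})/(1−e^{−2va})` to 1e−6.

Fitting is per-participant maximum likelihood (bounded L-BFGS-B) in place
of hierarchical Bayesian estimation: deterministic given seeds,
desk-scale, and sufficient for the model-comparison question, which —
because both variants have the same parameter count (shared a, t₀, v plus
one epoch-varying parameter) — reduces to a likelihood comparison (AIC
and BIC are also reported). Ten Latin-hypercube starting points are
screened by likelihood and the best three polished to convergence; ties
break by start order. Trials faster than 300 ms are excluded as guesses,
as are non-responses. Bounds: a ∈ [0.5, 4], t₀ ∈ [0.05, min RT), v ∈
[0, 5], dc ∈ [−3, 3], z ∈ [0.05, 0.95]. In the Drift Criterion model z is
fixed at 0.5 and in the Response Bias model dc at 0 — one of several
layouts satisfying the equal-count constraint, chosen so each model has
exactly one learning locus. A reporting helper exposes −dc so liberal
values plot downward like SDT criterion. Model recovery at the test
problem sizes (three epochs, 150–300 trials/epoch) selects the generating
variant in every direction tested; recovery of epoch-wise dc correlates
r > 0.9 with truth at 300 trials/epoch.

No inter-trial variability parameters (sv, st, sz) are included; the
models compared do not require them and they would break the equal-count
symmetry.

## Regressors

The canonical double-gamma HRF (positive gamma shape 6, undershoot shape
16, ratio 1/6, peak ~5 s) is sampled at 0.1 s microtime; zero-duration
stick events with mean-centred parametric amplitudes (the
parametric-modulator convention) are convolved and decimated to TR = 2 s.
EV modulates the trial-onset event and PE the feedback event. Session
timing draws the inter-trial interval from a shifted truncated
exponential with mean 2 s on [1, 11] s and the response-to-feedback
interval with mean 2.85 s on [1, 6] s, the truncated-distribution scale
solved so the stated means hold after truncation. Temporal-derivative
regressors are omitted: they compensate slice-timing misfit that
synthetic signals do not have.

Between-coding correlations are computed within participant, Fisher-z
averaged, and back-transformed. On default cohorts the convolved PE
codings share R² ≈ 0.6–0.7 and the EV codings R² ≈ 0.3–0.4; the exact
values depend on the simulated confidence distributions, so tests assert
the band and the PE > EV ordering rather than point values. Serial
orthogonalization residualizes the second regressor against span{1,
first}; the toy GLM enters both convolved PE codings jointly with an
intercept and attributes unique variance by |t|.

## Pipeline

A master seed deterministically derives every agent and stage seed
(CRC-based token hashing, stable across processes). All floating-point
outputs are rounded to nine significant digits so reruns diff cleanly;
identical config + seed reproduces trial tables byte for byte. Stage
failures for one participant are logged and do not abort the cohort.

## Problem sizes

Defaults were chosen as the smallest sizes at which the stochastic
assertions are stable with margin: 40 agents/group for the behavioural
cohort orderings, 50 agents for the scanner liberal shift, 20 replicates
at 300 trials/epoch for dc recovery, 25 simulated participants per
direction at 150 trials/epoch for model selection, 10,000 false alarms
and 200 sessions for the schedule statistics, and 50 seeds for GLM
attribution.

## Limitations

The synthetic cohorts emulate the *structure* of the experiments —
designs, schedules, codings, decision model — not fitted human
parameters. Confidence distributions, learning rates, and the
reinforcement asymmetry are plausible-by-construction, so passing tests
establish internal consistency of the account (each coding's learners
produce that coding's predicted group pattern; the diffusion comparison
distinguishes the learning loci) rather than quantitative agreement with
human criterion magnitudes. The agents' RTs are conditionally independent
of their confidence given the response, which real data would not
satisfy. The adaptive schedule's confidence-targeting rule is a
reconstruction, and the recall stage asserts direction only.
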
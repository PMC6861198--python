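# Methods

## The decision model

The package models choices between a gamble and a sure payment in a
wheel-of-fortune task. A gamble pays `x` euros with probability `p`; under
ambiguity a fraction `A` of the wheel is occluded and the reference
probability under the occluder is .5. The subjective value of a wheel is

    EU(x, p, A) = (p − β·A/2) · x^α

with `α` the risk attitude (power-utility curvature: 1 neutral, < 1
averse, > 1 seeking) and `β` the ambiguity attitude (0 neutral, > 0
averse, < 0 seeking). The safe wheel is treated as a degenerate gamble
(`p = 1`, `A = 0`), so a single expression values both options. The
probability weight `p − β·A/2` is clamped to [0, 1]: outside that interval
it is not a probability, and unclamped weights destabilise fitting at
extreme `β`. Choices are stochastic with a logistic rule on the
expected-utility difference,

    Pr(gamble) = 1 / (1 + exp(−(EU_gamble − EU_safe)/μ)),

where the temperature `μ` interpolates between deterministic EU
maximisation (μ → 0) and coin-flipping (μ → ∞). For behavioral reporting
the ambiguity attitude is negated ("recoded") so that higher values mean
more ambiguity seeking; internally the native sign convention is used
everywhere.

## Estimation

Per participant, (α, β, μ) maximise the Bernoulli likelihood of the
gamble/safe choices. The likelihood surface is multimodal for sparse or
near-deterministic data, so a Nelder–Mead simplex search is restarted from
a 4×3×3 grid of starting values (α ∈ {0.2, 0.6, 1.0, 1.4}, β ∈ {−0.6, 0,
0.6}, μ ∈ {0.05, 0.5, 2}) spanning the attitude ranges reported for
adolescent samples, and the best restart wins; the returned objective
never exceeds the objective at any start. Bounds (α ∈ (0, 2.5], β ∈ [−1,
1], μ ∈ [10⁻⁴, 10]) are enforced by smooth reparameterisations — a scaled
logistic for α (a plain log transform could not impose the upper bound),
tanh for β, log with clamping for μ — so the simplex runs unconstrained.
The β bounds keep the perceived probability of a fully occluded wheel
inside [0, 1]. Convergence tolerance is 10⁻⁶ on the objective, at most
2000 iterations per restart. Inside the likelihood, choice probabilities
are floored at 10⁻¹² (equivalently, per-trial deviance capped at
−ln 10⁻¹²) so deterministic responders stay finite; the computation uses
`log(expit(z)) = −logaddexp(0, −z)` and is overflow-safe down to the μ
lower bound. One shared μ covers risk and ambiguity trials.

Missing responses are dropped, never imputed; at least 20 usable trials
are required. Data-quality rules mirror the study protocol: participants
who gamble on ≥ 50% of stochastic-dominance probes (trials whose gamble
amount equals the safe amount, so the sure wheel dominates) are excluded,
as are α estimates more than 3.5 sample SDs above the sample mean and
all-gamble/all-safe (degenerate) responders. The probe denominator counts
probe trials only — over all trials the 50% rule would be untriggerable
for any coherent agent. The outlier mean/SD are computed on fits not
excluded for dominance and not degenerate, since a degenerate fit's α sits
at a transform bound and would corrupt the statistics; zero SD excludes
nobody.

### Identifiability caveat

For a near-deterministic agent (μ ≲ 0.05) the likelihood is flat over
every β consistent with the observed choice pattern: β is set-identified,
not point-identified, and the fitted value can land anywhere in that set
(a brute-force grid search shows an exact plateau). Tests therefore check
that near-deterministic fits fall inside the oracle's near-optimal set
rather than within a fixed distance of the truth. At the noise levels used
for the cohort (μ ≈ 0.1) β is point-identified and recovery is good.

## Task designs

The behavioral design crosses 6 probabilities (.125–.75) and 4 amounts
(€5, €8, €20, €50) for risk, and 4 occlusion levels (25–100%) with the
same amounts for ambiguity (a 0% occlusion is a risk trial), each unique
cell twice: 80 trials. The safe wheel pays €5 — the lowest gamble amount,
taken from the validated predecessor task — which makes the €5 gambles
dominance probes. The scanner design has 92 trials (46 fully ambiguous, 46
risky split 30/8/8 over p = .5/.75/.25) against a sure €3, amounts €31–34
drawn in shuffled blocks of four over the presentation order (so each
amount occurs exactly 23 times), and an event timeline of 0.5 s fixation,
3 s response window, 2–4 s decision–outcome gap in 0.5 s steps, 1.25 s
outcome and a uniform 0–9.35 s ITI. Sequence-efficiency optimisation of
trial order is deliberately not implemented — ordering does not affect the
behavioral pipeline — so jitters are simple uniform draws. A seed changes
order, side/lid assignment pairing and jitter; the gamble cells themselves
are fixed (for the scanner task, the pairing of amounts with probabilities
varies with the seed because the blocks are drawn over the presented
order).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
the published group values: α ~ Normal(0.60 + 0.015·(age − 17), 0.26)
truncated to (0, 2.5]; native β ~ Normal(+0.25, 0.36) truncated to [−1, 1]
(recoded mean −.25); ages uniform on 12–22; μ log-normal with median 0.1
and log-SD 0.5 (no published summary exists for μ; 0.1 gives choice
consistency typical of attentive participants). Choices are Bernoulli
draws from the logistic rule; reaction times are log-normal with
condition-specific means (597.06 ms risk, 641.59 ms ambiguity, log-SD 0.3)
— a decorative covariate, not a response-time process model. Exit ratings
of perceived riskiness are linear in 1 − p (risky wheels, gain 40) and in
A (ambiguous wheels, gain 30), shifted by the agent's attitude deviations
(−15 per unit α, +15 per unit native β), plus Gaussian noise (SD 8),
clipped to the 0–100 slider; the intercepts are set so cohort means land
near the published 52.52 (risk) and 62.75 (ambiguity). All randomness
derives from one integer seed through a `SeedSequence` tree.

What the generator does **not** emulate: learning or heuristic drift over
trials, within-participant attitude instability, sex/IQ covariates,
lapses tied to attention, or any response-time mechanism. Passing tests
show the pipeline recovers what this generative model plants; they are not
evidence about phenomena the generator omits.

## Parameter recovery

The recovery study simulates agents over a 7×9 attitude grid (α 0.2–1.4,
β −0.8–0.8, both step 0.2) at μ = 0.1, 20 replicates of the 80-trial
design per cell, refits each run, and reports bias, RMSE and
true-vs-recovered correlations, overall and on the central sub-grid
(α ∈ [0.3, 1.2], β ∈ [−0.6, 0.6]) where most observed attitudes fall.
Degenerate fits are flagged and counted, never dropped. Frozen test
thresholds: central-sub-grid r ≥ 0.8 for α and ≥ 0.6 for β; and an
end-to-end cohort check (n = 50) requires r(true, recovered) ≥ 0.8 for α
and ≥ 0.6 for recoded β. Problem sizes in the test suite (50-participant
cohorts, 50-replicate consistency studies) are desk-scale choices that
keep the whole study reproducible on a laptop while leaving the
generator's noise settings untouched.

## fMRI regressors and group statistics

For each non-excluded participant, every scanner trial gets the subjective
value of the chosen wheel under their fitted attitudes, and an objective
expected value computed with α = 1, β = 0 (ambiguous wheels at the .5
reference probability). Decision events last 1 s plus the response time;
non-responses become a separate "missing" trial type with no modulator.
Modulators are demeaned per participant *within condition*, because risk
and ambiguity enter the downstream GLM as separate parametric regressors;
demeaning is idempotent and each condition's column sums to zero to within
10⁻⁹. Events are written as tab-separated files with columns `onset`,
`duration`, `trial_type`, `response_time`, `modulation` (seconds, three
decimals). Demeaning is per session, not per run: the pipeline does not
model the run boundary.

The group report computes, per participant, gamble proportions (risk,
ambiguity, and the 50:50-risk subset used as a control variable), mean RTs
per condition, recoded attitudes and exit-rating means; and at the group
level, a paired test on z-scored attitudes, degree-1–3 polynomial age
regressions, Pearson and partial correlations of attitudes with scanner
gambling (controlling age and/or the 50:50 gambling proportion) and with
exit ratings (controlling age), and the RT condition contrast. Partial
correlations use two-stage residualisation semantics; a variable fully
explained by its controls yields a partial correlation of 0, and
zero-variance inputs are reported as undefined with an explicit flag
rather than NaN surprises. No multiple-testing correction is applied.

## Known limitations

* Gains only; no loss domain, probability weighting, or reference
  dependence.
* β is set-identified for near-deterministic responders (see above).
* The exit-rating and RT generators are calibration devices, not
  cognitive models.
* Group statistics on synthetic cohorts inherit the generator's
  assumptions; they validate the pipeline, not developmental claims.
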
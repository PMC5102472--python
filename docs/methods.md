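# Methods

## The task and the decision model

The judgement-bias task probes how subjects resolve perceptual ambiguity
when the stakes differ. On each trial a subject sees a briefly presented
grating tilted up to 1.4° from vertical; the signed lean is coded as
`s ∈ [−1, 1]` (+1 = maximal lean toward the WIN side, 0 = vertical, fully
ambiguous). Pressing the risky REW key wins `R⁺` pence if the stimulus
leant toward WIN and loses `R⁻` pence otherwise; the SAFE key always pays
nothing. Stimuli with `|s| ≤ 0.25` (0.35° from vertical) are empirically at
chance for brief presentations, so choices in that band express valuation
and bias rather than perception.

The model assumes the subject receives a noisy percept `x ~ N(s, σ²)` and,
with a flat prior over the lean, chooses REW when its expected subjective
value is positive. Writing `C_loss = c⁻/c⁺` for the relative subjective
weight of losses to wins, the risky choice is worthwhile when the percept
exceeds

    x* = −σ Φ⁻¹(α) − δ,   α = R⁺ / (R⁺ + C_loss R⁻),

where `δ` is an additive decision bias (negative = toward SAFE) and Φ the
standard normal CDF. Marginalizing the percept gives the per-trial risky
choice probability

    P(REW | s) = (1 − P_lapse) Φ((s + σ Φ⁻¹(α) + δ)/σ) + P_lapse/2,

with a lapse rate `P_lapse` for uninformed coin-flip choices. Only the
ratio `C_loss` is identifiable; `c⁺` is fixed at 1. At equal stakes with
`C_loss = 1` and no lapses this reduces to `P(REW|s) = Φ((s + δ)/σ)`, the
two-parameter model used for the fixed-stakes session.

Model families are expressed as a `ModelSpec` naming the free parameters:
`session1` (σ, δ), `session1_lapse` (σ, δ, P_lapse), `session3_no_lapse`
(σ, δ, C_loss) and `session3_full` (all four).

A consequence of the cumulative-Gaussian form worth noting: two groups that
share a bias δ < 0 but differ in σ show a larger gap in risky choice at
s = +1 than at s = −1 — group differences are expressed most strongly on
the side opposite the shared bias. This is an analytic property of the
model (tested on a parameter grid), not a fitting artifact.

## Task designs emulated by the generator

* **Fixed-stakes session**: 70 trials over the five lean levels
  {−1, −0.25, 0, 0.25, 1}, all at WIN 50p / LOSE 50p. Per-level counts are
  not documented for the original task; the generator uses a balanced 14
  per level (shuffled by seed) because balance maximizes identifiability of
  the psychometric curve.
* **Varying-stakes session**: 250 trials = 125 unique (WIN, LOSE) pairs,
  each presented at leans +x and −x. Cost pairs are integer pence drawn
  uniformly from the four quadrants (WIN and LOSE each from 0–50p or
  60–100p; 51–59p never occurs; the joint (0, 0) pair is resampled),
  allocated 31/31/31/32 pairs per quadrant for deterministic counts.
  A 70% share of trials in the ambiguous band is not attainable exactly
  with mirrored pairs (87.5 pairs); the generator uses 88 ambiguous pairs
  (176 trials, 70.4%) with x uniform on (0, 0.25] and 37 clear pairs with
  x uniform on (0.25, 1]. The within-band distribution of the original
  stimuli is not documented; uniform-within-band is our assumption.

Cohorts are simulated hierarchically: subject-level parameter vectors are
drawn from a diagonal Gaussian population prior in inference space (below),
transformed to natural space, and choices simulated trial-by-trial. All
subjects in a cohort share one stimulus sequence, as in the task. The
default simulation population is σ = 0.35, δ = −0.1, C_loss = 0.8,
P_lapse = 0.05 at the centre (natural space), with inference-space SDs of
0.3 (log σ), 0.1 (δ), 0.3 (log C_loss) and 0.5 (logit P_lapse): ambiguous
stimuli genuinely hard, a mild bias toward SAFE, losses weighted slightly
less than wins, occasional lapses — a plausible human cohort for this task
family. These defaults are fixed; every generative test interprets its
results relative to this population.

## Hierarchical fitting

Parameters are estimated in an unconstrained "inference space"
`h = (log σ, δ, log C_loss, logit P_lapse)` (restricted to the free set;
models that pin P_lapse = 0 never touch the logit coordinate). The
population distribution is Gaussian with mean μ and diagonal covariance Σ
in this space, estimated by Type-II maximum likelihood via approximate EM:

* **E-step** — per subject, a Laplace approximation: the MAP `m_i` of
  `log p(D_i|h) + log p(h|μ, Σ)` (L-BFGS-B with the analytic gradient of
  the Bernoulli likelihood; up to 5 seeded restarts from prior draws on
  failure) and covariance `Φ_i` from the inverse Hessian (central finite
  differences of the gradient; escalating jitter `1e−6·(1+|diag|)` up to
  ×1000 if not positive definite, with the subject flagged).
* **M-step** — moment matching: `μ ← mean(m_i)`,
  `Σ ← diag(mean(m_i m_iᵀ + Φ_i) − μμᵀ)`, floored at 1e−6 (flooring events
  are counted in the result).

Initialization is weakly informative (σ = 0.5, δ = 0, C_loss = 1,
P_lapse = 0.05 transformed; unit variances), centred on the model-agnostic
indifference point. Convergence requires `max|Δμ| < 1e−3` and
`max|Δ log Σ| < 1e−2`, capped at 200 iterations; a final E-step under the
converged prior produces the reported per-subject MAPs. The first E-step
starts each subject at the prior mean; later E-steps warm-start from the
subject's previous MAP, which shares the fixed point and cuts wall time
several-fold. Sessions are fitted independently — nothing in the design
requires them to share information.

**Standard error of the population mean.** The naive `sqrt(Σ/N)` is
anti-conservative whenever subjects are individually poorly identified —
which is the norm for `C_loss` under a 70%-ambiguous design, where the
per-subject posterior is wide and strongly correlated with δ. The package
therefore reports the observed-information SE: each subject contributes
marginal precision `(Σ + D_i)⁻¹`, with `D_i` the data-only posterior
covariance recovered from the Laplace covariance by removing the prior
precision (`D_i⁻¹ = Φ_i⁻¹ − Σ⁻¹`, eigenvalue-floored so unconstrained
directions contribute nothing). This reduces to `sqrt(Σ/N)` when every
subject is well identified and is never smaller than it.

## Model comparison

Fitted priors are scored by the integrated BIC,
`iBIC = −2 log p(D|θ_ML) + M log|D|`, where `M` counts the fitted prior
means (the length of `h`, once per fitted prior; for the separate-group
model `M = 2 × |h|`) and `|D|` is the total number of choices across all
subjects in the comparison. Whether prior variances should count toward
`M`, and whether the separate-group model counts parameters once or per
group, are genuinely open conventions; the package counts means only and
per prior, and reports `M` explicitly so either convention can be
recomputed. The marginal likelihood is estimated by averaging each
subject's likelihood over K samples from the fitted prior (log-sum-exp;
default K = 10,000, K = 2,000 in the test studies), with a per-subject
delta-method Monte-Carlo standard error combined in quadrature — always
reported, so an insufficient K is visible rather than silent.

## Model-agnostic analyses and permutation tests

Choice curves average each subject's risky-choice rate per lean bin and
then across subjects (SEM over subjects). Data with ≤ 10 distinct lean
values use those values exactly; continuous designs use right-closed bins
of width 0.2 on [−1, 1]. Risk aversion at full ambiguity is tested on
per-subject `P(SAFE | s = 0)` with a two-sided one-sample t-test against
0.5 and an exact binomial sign test (ties dropped); a cohort with identical
proportions ≠ 0.5 is reported as t = ±∞ with p = 0.

Group differences in fitted parameters use two-sided permutation tests on
the MAP estimates in inference space (configurable to natural space):
labels shuffled `n_perm` times (default 10,000), add-one p-value
`(1 + #{|stat*| ≥ |obs|})/(n_perm + 1)` — valid, never zero, with attainable
minimum `1/(n_perm+1)`. Statistics: difference of means or of unbiased
variances. The original analyses do not state sidedness or `n_perm`
("e.g. 10,000"); two-sided and 10,000 are our documented defaults.

Posterior-predictive checks simulate each fitted subject's MAP on a session
design (default 500 repetitions per subject) and also report the
closed-form curve at the population-mean parameters.

## Numerical choices

* Per-trial probabilities are clipped to [1e−9, 1 − 1e−9] before logs so
  lapse-free models cannot produce −∞ likelihoods.
* Trials with a zero stake on one side (α exactly 0 or 1) saturate at the
  lapse-bounded extremes and contribute zero gradient to the curve
  parameters; trials with both stakes zero are rejected everywhere
  (generator, reader, likelihood).
* Exact indifference (percept equal to threshold) resolves to SAFE; under
  the continuous percept model this is a measure-zero event.
* The choice simulator and all studies consume `numpy.random.Generator`
  streams seeded explicitly; identical seeds give identical artifacts.

## Validation studies and their sizes

Because the original cohort's data are not deposited, validation is
generative, with study sizes chosen to make each check sharp at desk
scale:

* agent-vs-closed-form agreement on a 75-point grid at 10⁶ draws per point;
* prior recovery over 20 cohorts of 24 subjects on the 250-trial design
  (coverage at 2 observed-information SEs, median |error| vs population SD);
* model-selection direction over 20 replicates each for the lapse
  comparison (24-subject fixed-stakes cohorts) and the pooled-vs-separate
  comparison (24 subjects per group, matching the original group size,
  populations 3 SD apart in δ);
* permutation type-I calibration over 1000 null replicates at n_perm = 199
  (0.05 is exactly attainable on the add-one grid), plus exhaustive
  enumeration at n = 3+3;
* Laplace-vs-grid agreement for one 70-trial subject on a 201×201 grid.

`scripts/acceptance.py` reruns the same battery at slightly smaller
replicate counts (10 recovery/selection replicates, 6 pooled-vs-separate
replicates) and writes the computed quantities as JSON.

## What these simulations do and do not show

Passing tests demonstrate internal validity: the estimator recovers the
populations the generator produces, model selection points the right way
under known ground truth, and the analytic pieces agree with brute-force
oracles. Real data differ in ways the generator does not emulate: sequential
effects (learning, fatigue, criterion drift), reaction-time structure,
non-Gaussian population heterogeneity, and any mismatch between the assumed
flat stimulus prior or linear subjective values and actual behaviour.
Conclusions about a real cohort rest on the model's adequacy for that
cohort, which posterior-predictive simulation (`judgebias simulate`) can
probe but not guarantee.

## Known limitations

* The population covariance is diagonal by design; correlated individual
  differences (e.g. between δ and C_loss) are absorbed into variances.
* The Laplace approximation can misstate skewed posteriors (most visible
  for the lapse logit at small cohorts); EM point estimates inherit the
  usual small-N empirical-Bayes shrinkage bias.
* No reaction-time model is provided; RTs are carried through I/O untouched.
* The Monte-Carlo iBIC is noisy at small K; use the reported MC SE to pick
  K, and prefer differences well beyond that SE.
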
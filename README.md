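# judgebias

Bayesian decision modelling of judgement-bias ("ambiguity") tasks, for
researchers studying how affective state shapes decision-making under
perceptual ambiguity — in humans or, with the fixed-stakes design, in the
animal variants of the paradigm.

## The problem and the model

In a judgement-bias task, a subject classifies a briefly shown stimulus
whose signed lean `s ∈ [−1, 1]` ranges from clearly punishment-predicting
(−1) through fully ambiguous (0) to clearly reward-predicting (+1).
Pressing the risky **REW** key wins `R⁺` pence if the stimulus leant toward
the WIN side and loses `R⁻` pence otherwise; the **SAFE** key always pays
nothing. How a subject resolves the ambiguous middle — "optimistically" or
"pessimistically" — carries information about perception, valuation and
bias that a single choice rate cannot disentangle.

The model assumes a noisy percept `x ~ N(s, σ²)` and a Bayesian chooser
with a flat stimulus prior, giving the per-trial risky-choice probability

    P(REW | s) = (1 − P_lapse) · Φ( (s + σ Φ⁻¹(α) + δ) / σ ) + P_lapse / 2,
    α = R⁺ / (R⁺ + C_loss · R⁻),

with four interpretable parameters: perceptual noise `σ`, decision bias
`δ` (negative = toward SAFE), relative loss weight `C_loss = c⁻/c⁺`, and
lapse rate `P_lapse`. At equal stakes with `C_loss = 1`, `P_lapse = 0`
this reduces to `Φ((s + δ)/σ)`.

On top of the model the package provides:

* **hierarchical fitting** — subject parameters as draws from a diagonal
  Gaussian population prior in `(log σ, δ, log C_loss, logit P_lapse)`
  space, estimated by Type-II maximum likelihood (approximate EM with a
  Laplace E-step), returning the prior, per-subject MAPs and Laplace
  covariances;
* **model comparison** — integrated BIC
  `iBIC = −2 log p(D|θ_ML) + M log|D|` with a Monte-Carlo marginal
  likelihood (K prior samples, log-sum-exp, reported MC standard error),
  including pooled-vs-per-group prior comparisons;
* **model-agnostic analyses** — choice curves by lean bin, risk-aversion
  tests at `s = 0` (t-test and exact sign test), two-sided permutation
  tests on fitted parameters;
* **synthetic data** — seeded generators for the 70-trial fixed-stakes and
  250-trial varying-stakes session designs and for whole cohorts drawn
  from known population priors, so that every stage can be validated by
  parameter recovery.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a two-group cohort on the fixed-stakes design, fit the reduced
(σ, δ) model, and test for group differences:

```sh
judgebias generate --session S1 --subjects 24 --spec session1 \
    --seed 7 --out demo/s1.csv
judgebias fit demo/s1.csv --spec session1 --seed 0 --out demo/s1_fit.json
judgebias permtest demo/s1_fit.json demo/s1.csv --n-perm 2000 --seed 0 \
    --out demo/s1_perm.json
judgebias curves demo/s1.csv --out demo/s1_curves.json
```

which prints:

```
wrote 48 subjects x 70 trials to demo/s1.csv
fit 48 subjects, 14 EM iterations, converged=True
   sigma (pleasant - unpleasant): mean_diff = -0.0903, p = 0.2244
   delta (pleasant - unpleasant): mean_diff = -0.0076, p = 0.5327
pleasant: mean P(SAFE|s=0) = 0.658, t(23) = 4.95, p = 5.308e-05, sign p = 0.0007286
unpleasant: mean P(SAFE|s=0) = 0.649, t(23) = 4.36, p = 0.0002276, sign p = 0.01182
```

Both simulated groups are drawn from the same population, and the
permutation tests on the fitted `log σ` and `δ` correctly find no group
difference (p = 0.22 and 0.53). The population has a mild bias toward SAFE
(δ < 0), so both groups choose SAFE on roughly 65% of fully ambiguous
trials — risk aversion under ambiguity that the t-test and sign test flag
decisively. `demo/s1_fit.json` contains the estimated population prior and
each subject's MAP in both parameter spaces.

The same steps work on real data: any CSV with columns
`subject_id, group, session, trial_index, ambiguity, win_pence, loss_pence,
choice, rt_ms` (choices `REW`/`SAFE`) can be fed to `fit`, `compare`,
`curves` and `permtest`. From Python, the equivalent calls are
`judgebias.sample_cohort`, `judgebias.em_fit`, `judgebias.permutation_test`
and friends.

A full parameter-recovery study — simulate cohorts from a known prior,
refit, report bias/RMSE/coverage — is one command:

```sh
judgebias recover --spec session3_full --replicates 20 --subjects 24 \
    --seed 1 --out demo/recovery.json
```

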
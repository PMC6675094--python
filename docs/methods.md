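# Methods

## Causal systems and the design grid

Two binary causes, focal (F) and alternate (A), occur independently with
prior probabilities `p_f, p_a ∈ {0.1, …, 1.0}` and determine a binary
outcome, `E = F AND A` (conjunctive) or `E = F OR A` (disjunctive).  Zero
priors are excluded: the rated situation is one in which the outcome
occurred, which requires both draws to have been possible.  The 10×10
grid gives 100 parameterizations per structure, enumerated focal-major
ascending; downstream regressions code each prior by its grid index
`g = 10·p ∈ 1..10`, so a slope is the change in (0–1 scaled) rating per
0.1 probability step.  Probability comparisons use an absolute tolerance
of 1e-12, which makes grid membership and the `p = 1` boundary robust to
CSV round-trips while being ten orders of magnitude below the grid
spacing.

## Predictor models

All predictors rate the focal cause in [0, 1].

**Witness/normality (HH).**  A cause is admissible when the witness world
consulted to check its necessity is more *normal* (typical) than the
actual world; normality here is operationalized by the draw
probabilities.  Conjunctively, the focal witness flips focal alone, so
focal is never a cause when `p_f > 0.5`; it scores `x_high` when its
witness is the more normal of the admissible ones and `x_mid` when the
alternate's witness is more normal (`p_a < p_f ≤ 0.5`).  Two cases are
not fixed by the piecewise definition and are resolved here as design
choices: at `p_f = p_a ≤ 0.5` the two witness worlds are equally normal,
so focal is not demoted (`x_high`; configurable to `x_mid`), and at
`p_f ≤ 0.5 < p_a` the alternate is not an admissible cause at all, so
focal again scores `x_high`.  Disjunctively the sole witness world has
both causes absent, and two variants arise: HH1 compares normality
variable by variable and HH2 by total world probability, giving
`x_high` iff both priors < 0.5 (HH1) or `p_f + p_a < 1` (HH2).  Defaults
`x_high = 1`, `x_mid = 1/2`.

The per-variable order in `normality_compare` is deliberately a *strict
dominance* (strong-Pareto) order: a world counts as more normal only if
every cause variable is strictly more typical in it; conflicting
directions, and partial ties short of full equality, are incomparable.
This is the unique choice under which the mechanistic witness path
(`hh_witness` + `normality_compare`) reproduces the HH1 closed form
exactly at the 0.5 boundary of the grid, which the test suite checks on
all 100 settings.

**Counterfactual sampling (Icard).**  People sample a counterfactual
world in proportion to its probability; a focal-absent sample triggers a
necessity check (flip focal, hold the rest of the actual world fixed), a
focal-present sample a sufficiency check (redraw the alternate from its
prior).  With sampling probabilities taken directly from the priors the
expected score is `1 − p_f(1 − p_a)` conjunctively and `p_f`
disjunctively.  `sampling.sample_icard_rating` runs the process literally
with a named per-call RNG (no global state); the per-draw Bernoulli
sufficiency outcome keeps the estimator unbiased, and a `plug_in` flag
substitutes its expectation for variance reduction.  The reported
standard error is the sample standard error of the mean score.

**Causal-strength measures.**  SP, ΔP and Power-PC are computed from
`P(E)`, `P(E|C)`, `P(E|¬C)` obtained by enumerating the four worlds.  At
`p_f = 1` the conditional on ¬C is undefined; `outcome_probabilities`
returns a tagged NaN rather than raising, and the predictors substitute
their (finite) closed-form limits so the full grid is covered.  The
disjunctive Power-PC 0/0 case at `p_a = 1` likewise resolves to the
constant 1, which is also the limit from below.

## Synthetic rating experiments

The generator emulates the two crowd-sourced experiments: `n_subjects`
(999 conjunctive / 1013 disjunctive) × 5 trials, each trial a distinct
setting drawn uniformly without replacement from the grid, response on a
1–9 agreement scale.  The latent scaled rating of subject *i* on a trial
with indices `(g_f, g_a)` is

```
y* = β0 + β_f·φ_f + β_a·φ_a + j_f·1[g_f=10] + j_a·1[g_a=10]
     + b0_i + b1_i·g_f + b2_i·g_a + ε,
```

with `b ~ N(0, diag(σ0², σ1², σ2²))`, `ε ~ N(0, σ²)`, and
`φ_f = m_f·g_f + (1−m_f)·5.5` where the suppression multiplier `m_f`
applies only when the *other* prior equals 1 (symmetrically for `φ_a`).
Flattening a slope toward its grid-mean level (rather than simply
scaling it) removes the effect without shifting the condition's average,
so the jump offsets `j` alone control how far the certain conditions sit
off the linear extrapolation.  The observed rating is
`r = round(1 + 8·clip(y*, 0, 1))`, scaled back as `(r − 1)/8`.

Shipped calibrations (YAML in `causalsel/configs/`):

| parameter | exp1 (conjunctive) | exp2 (disjunctive) | why |
|---|---|---|---|
| β_f, β_a | −0.02, +0.03 | +0.01, −0.005 | reported main-effect slopes |
| j_f, j_a | −0.15, +0.16 | 0, −0.045 | displacement of the certain-condition means from the reported extrapolation intervals; no focal jump was observed disjunctively |
| m_f, m_a | 0, 0 | 0, 0 | each prior's effect vanishes when the other is certain |
| β0 | 0.45 | 0.52 | centers the grand mean near the observed mid-scale band |
| σ0, σ1, σ2, σ | 0.1, 0.02, 0.02, 0.2 | same | puts single-dataset slope standard errors at the reported order (≈0.001–0.002); a calibration choice, not an empirical estimate |

What the generator does **not** emulate: participant dropout (the real
conjunctive experiment lost ~30 of 4995 ratings), order/practice
effects, individual differences beyond Gaussian random effects, and any
response-style heaping on the 1–9 scale.  Passing tests therefore show
that the pipeline detects these effects when present at realistic sizes
and calibrations — not that human data contain them.

## Estimators and tests

**Main effects.**  Four estimators share one contract — consistency for
the generative slopes, verified by recovery tests:

* `mixedlm` (default): REML linear mixed model, random intercept + both
  random slopes per subject.
* `ols_cluster`: pooled OLS with subject-clustered sandwich SEs; the
  workhorse for replicate simulations.
* `censored_ml`: interval-censored marginal ML.  A rating *r* pins the
  latent value to `[(r−1.5)/8, (r−0.5)/8)`, open-ended at the scale ends,
  and the latent variance follows the generator's structure
  `c0 + c_f·g_f² + c_a·g_a²`.  Maximizing the independence working
  likelihood is consistent despite within-subject correlation; SEs come
  from a subject-clustered sandwich with an analytic score.  This is the
  estimator of choice for parameter recovery: the plain linear fits are
  attenuated ~5–15% by the clamp-and-round measurement at the scale
  ends, which the censored likelihood undoes.
* `two_stage`: per-subject OLS averaged across subjects; unbiased but
  noisy with five trials per subject.

Because the certainty jumps and suppression are real nonlinearities, a
plain linear regression on all trials is *not* consistent for the
linear-regime slopes (a jump at `g = 10` loads onto the slope).  The
default `certainty` design therefore adds the two certainty dummies and
the two slope-by-certainty interactions (pooled fits) or restricts to
the `p < 1` regime (two-stage); `design="linear"` gives the naive fit.

**Certainty-jump test.**  OLS of ratings on one prior's index over the
`p < 1` trials, extrapolated to `g = 10`; the 95% interval is for the
*mean of the m observed certain trials* (`se² = se_pred² + σ̂²/m`), so
with no true jump the flag fires at the nominal 5% rate — verified at
500 replicates.  A mean-only interval would be anti-conservative, a
single-observation interval hopelessly wide.

**Conditional effects and Bayes factors.**  Slope of one prior on the
trials where the other prior equals 1 (excluding the tested prior's own
certain trials), with `BF_null = exp((BIC_alt − BIC_null)/2)` — the
unit-information-prior BIC approximation, a reconstruction chosen
because no Bayes-factor method is pinned down for this analysis; the
printed values are not claimed to be reproduced.

**Interaction and order checks.**  The slope-by-certainty interaction is
OLS with a moderator dummy (estimate = certain-stratum slope minus
other-stratum slope); order checks re-estimate slopes with the trial
index as covariate, on first trials only, and with slope-by-trial
interactions.

**Model comparison.**  Empirical condition means (per-setting mean
scaled rating) are correlated with each model's 100-condition profile;
the CI is Fisher-z.  Constant profiles (disjunctive Power-PC) leave r
undefined and are reported not-applicable, never as a number.  Pairs of
models are compared with Williams's test for two dependent correlations
sharing one variable (Steiger formulation, df = n − 3, two-tailed),
validated against a simulated type-I error rate and a percentile
bootstrap of the correlation difference.  No multiplicity correction is
applied anywhere, matching the raw-p reporting convention of the
analyses being mirrored.

## Problem sizes and determinism

The test suite runs the experiments at their full size (999/1013
subjects) where a single dataset suffices, 50 replicates for recovery
sign patterns, 500 for jump-coverage calibration, and 10,000 simulated
nulls for the Williams type-I rate; Monte-Carlo sampling checks use 1e5
draws per grid setting.  All stochastic components take explicit seeds
(numpy `SeedSequence` spawning, one generator per operation), and
simulate → analyze is deterministic given the seed to well below 1e-9 on
every reported statistic.

## Known limitations

* The HH tie rules are package design choices; the underlying account is
  ordinal and does not fix them.
* The censored-ML estimator conditions on the generator's variance
  structure being quadratic in the grid indices; for data with a
  different heteroscedasticity pattern its SEs (not its slopes) may be
  mildly misstated.
* `BF_null` is a BIC approximation and will not match Bayes factors
  computed under other priors.
* The two-stage estimator drops subjects left with fewer than three
  linear-regime trials, or whose settings are collinear in
  (1, g_f, g_a); at experiment scale this is ~5% of subjects and does
  not bias the average, but it is why the estimator reports its own
  effective subject count.
* Empirical quantities that depend on the original participant data
  (item-level correlations, exact condition means) are not reproduced by
  the synthetic build; the shared CSV schema exists to re-run the
  pipeline on such data.
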
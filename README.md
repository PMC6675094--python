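# causalsel

Quantitative models and analyses of **token causal judgment** — how people
grade "X caused Y" for a single outcome when several antecedent events
contributed to it, as a function of how probable those events were a priori.

The package is built for computational cognitive scientists who want to
simulate, analyze, or extend rating experiments on the two most basic
deterministic causal systems:

* **conjunctive** — two independent binary causes, outcome `E = C1 AND C2`;
* **disjunctive** — outcome `E = C1 OR C2`.

Each cause occurs with a prior probability from the grid {0.1, …, 1.0},
giving 100 parameterizations per structure.  One cause is the *focal*
event whose causal status is rated; the other is the *alternate*.

## What's inside

**Predictor models** (`causalsel.predictors`) — closed-form predicted
causal ratings in [0, 1] for five accounts:

| model | conjunctive | disjunctive |
|---|---|---|
| HH (witness/normality) | piecewise {0, x_mid, x_high} | HH1: x_high iff both p < .5; HH2: x_high iff p_f + p_a < 1 |
| Icard (counterfactual sampling) | 1 − p_f·(1 − p_a) | p_f |
| SP = P(E\|C) − P(E) | p_a·(1 − p_f) | (1 − p_f)(1 − p_a) |
| ΔP = P(E\|C) − P(E\|¬C) | p_a | 1 − p_a |
| Power-PC = ΔP / P(¬E\|¬C) | p_a | 1 (constant) |

SP/ΔP/Power-PC are evaluated from their general conditional-probability
definitions by exhaustive world enumeration (`causalsel.scm`) and agree
with the reductions above to 1e-12.  `causalsel.sampling` implements the
sampling account as an actual seeded Monte-Carlo process (necessity vs
sufficiency checks on sampled counterfactual worlds) and the
witness-world/normality machinery from which the HH profiles are rebuilt
mechanistically.

**Synthetic experiments** (`causalsel.simulate`) — a generator emulating
the two large rating experiments (≈1000 subjects × 5 trials each, 1–9
agreement scale, no repeated setting within subject), with subject-level
random intercepts/slopes, linear effects of both priors, and the two
certainty nonlinearities seen empirically: outsized jumps when a prior
reaches 1, and suppression of the other prior's effect at that boundary.
Shipped defaults `exp1_conjunctive` and `exp2_disjunctive` are calibrated
to the reported effects (slopes −0.02/+0.03 and +0.01/−0.005 per 0.1
probability step).

**Statistical pipeline** (`causalsel.stats`, `causalsel.pipeline`) —
mixed-effects main-effect slopes (plus clustered-OLS, two-stage, and an
interval-censored ML estimator that undoes rating-scale attenuation),
certainty-jump extrapolation tests, conditional-effect tests with BIC
Bayes factors, slope-by-certainty interactions, trial-order checks, and
item-level model comparison: Pearson r between each model's 100-condition
profile and the empirical condition means, with Williams's test for
dependent correlations.

## Worked example

Simulate the conjunctive experiment at its shipped defaults and run the
full analysis battery:

```bash
causalsel compare --experiment exp1_conjunctive --seed 11 \
    --estimator censored_ml --out results/demo
```

prints (abridged):

```
causalsel 0.1.0 — conjunctive structure
999 subjects, 4995 ratings

Main effects (scaled rating per 0.1 probability step):
  focal:     b = -0.0185  SE = 0.0017  t = -10.7  p = 1.21e-26
  alternate: b = +0.0288  SE = 0.0018  t = 16.4   p = 2.69e-60

Certainty jumps (observed mean vs 95% extrapolation interval):
  focal: observed 0.30 vs [0.42, 0.48] — OUTSIDE
  alternate: observed 0.71 vs [0.58, 0.64] — OUTSIDE

Conditional effects (other prior certain):
  focal_when_alternate_certain: b = -0.0053  p = 0.25  BF_null = 11.2
  alternate_when_focal_certain: b = +0.0032  p = 0.52  BF_null = 16.0

Item-level model comparison (Pearson r over conditions):
  SP       r = 0.80  [0.72, 0.86]
  Icard    r = 0.79  [0.70, 0.85]
  DeltaP   r = 0.68  [0.56, 0.77]
  PowerPC  r = 0.68  [0.56, 0.77]
  HH       r = 0.51  [0.35, 0.65]
```

Reading this: the focal event is judged *less* causal the more probable
it was (abnormal inflation, negative slope) and *more* causal the more
probable the alternate was (supersession); both certain (p = 1)
conditions sit far outside the linear extrapolation (the certainty
jumps); each prior's effect vanishes when the other prior is certain
(null conditional slopes, Bayes factors favoring the null); and the
sampling-style predictors (Icard, SP) track the condition means best.
The recovered slopes (−0.0185, +0.0288) estimate the generative values
(−0.02, +0.03).

The same battery runs on real data in the shared CSV schema
(`subject, trial, structure, p_focal, p_alternate, rating`):

```bash
causalsel analyze --ratings my_ratings.csv --out report.json
```

Library use mirrors the CLI:

```python
from causalsel import default_config, generate_ratings, fit_main_effects

table = generate_ratings(default_config("exp1_conjunctive", seed=11))
est = fit_main_effects(table, estimator="censored_ml")
print(est.slope_focal, est.ci("focal"))
```

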
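# ippwlab

A Monte-Carlo laboratory for studying **inverse-probability-of-participation
weighting (IPPW)** against **complete-case analysis (CCA)** when a cohort
study loses its outcome to attrition, plus an applied-mode IPPW estimator
for real baseline-complete cohort tables.

## The problem

Longitudinal cohorts lose participants at follow-up. If the probability of
responding depends on observed baseline data (MAR) the complete cases can
remain analysable; if it depends on the unobserved outcome itself (MNAR),
complete-case estimates of an exposure effect are biased. A standard repair
is to fit a logistic *response model* for the participation indicator `r`
on fully observed variables, and weight each respondent by
`w_i = 1 / p̂_i`, the inverse of their estimated participation probability,
in the substantive *association model*. The practical question this package
quantifies: **which variables belong in the response model** — in
particular, whether the exposure `x` should be included — and what each
choice costs in bias, variance, MSE and confidence-interval coverage.

## The simulation design

Each replicate draws a cohort of `n = 1,000`:

    z1..z7 ~ iid N(0,1)
    x = 1 + 0.218(z1 + z2 + z5 + z6) + ε,                    ε  ~ N(0,1)
    y = 1 + 0.5x + 0.17 z1 + 0.23 z3 + 0.17 z5 + 0.23 z7 + ε′, ε′ ~ N(0,1)
    logit(p) = γ0 + γy·y + γx·x + 0.1(z1 + z2 + z3 + z4)
    r ~ Bernoulli(p)

Nine scenarios cross `γx, γy ∈ {0, 0.2, 0.5}`; `γy = 0` is MAR, `γy > 0`
MNAR. The intercept `γ0` is calibrated per scenario (Gauss–Hermite
quadrature + root-finding, no simulation noise) so the mean response rate
is 60%. The association model is the parsimonious epidemiological
regression `y ~ x + z1 + z5` (true effect `β = 0.5`), fitted by OLS on
respondents (CCA) or by weighted least squares with IPPW weights from any
of 18 predefined response-model variable sets (9 including `x`, the same 9
without it). Per (scenario, estimator) cell the engine reports Monte-Carlo
bias, variance, MSE, relative root-MSE and 95% Wald coverage.

## Worked example

```python
from ippwlab import (StudyConfig, get_scenario, response_model,
                     run_study_frame, summarize)

config = StudyConfig(
    B=500,
    scenarios=(get_scenario("MAR 1"), get_scenario("MNAR 6")),
    response_models=(response_model(1), response_model(10)),
    master_seed=7,
)
table = summarize(run_study_frame(config), beta_true=0.5)
table["variance"] *= 1e3; table["mse"] *= 1e3
print(table.round(3).to_string(index=False))
```

prints

```
scenario estimator_label   bias  variance   mse  rrmse  coverage  n_used
   MAR 1             CCA -0.000     1.814 1.814  8.518      93.6     500
   MAR 1   IPPW(model 1)  0.000     1.823 1.823  8.540      93.4     500
   MAR 1  IPPW(model 10)  0.000     1.825 1.825  8.543      93.2     500
  MNAR 6             CCA -0.080     1.914 8.294 18.214      52.4     500
  MNAR 6   IPPW(model 1) -0.077     2.552 8.566 18.511      59.8     500
  MNAR 6  IPPW(model 10) -0.081     1.960 8.480 18.417      52.6     500
```

Under MAR 1 (response independent of `x` and `y`) every estimator is
unbiased and near-nominal. Under the strong MNAR mechanism all estimators
remain biased (no response model can condition on the unobserved `y`), and
the response model that includes the exposure (model 1, `x, z1..z4`)
inflates the variance relative to its twin without it (model 10) — the
design lesson that the exposure should be left out of the response model.

The same estimators run on any cohort table from the shell:

```
ippwlab fixture --kind "MNAR 2" --n 2000 --seed 3 --out cohort.csv
ippwlab apply cohort.csv \
    --response "r ~ z1 + z2 + z3 + z4" \
    --association "y ~ x + z1 + z5" --out estimates.tsv
ippwlab simulate --config study.yaml --out results/
```

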
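# surveysel

Hybrid variable selection for complex-survey epidemiological data.

Large population-based health surveys (NHANES-style designs) pose three
problems at once for anyone trying to find which of dozens of correlated
biomarkers predict a binary outcome such as depression: predictor cells are
missing non-randomly, the sample is a stratified cluster design with
unequal weights rather than a simple random sample, and classical stepwise
or penalized selection handles neither. `surveysel` implements a
three-stage methodology that addresses all three:

1. **Multiple imputation** — missingness diagnostics (per-variable
   indicator tests, Little's MCAR χ² test with EM-estimated moments), then
   proper chained-equation imputation producing *m* completed datasets;
2. **Boosted-tree screening** — from-scratch stochastic gradient-boosted
   regression trees (Bernoulli loss, shrinkage λ, 50% bagging, 60:40
   validation-based stopping) run on the original and every imputed
   dataset; a variable survives when its relative importance exceeds 2% in
   the original data or on average across imputations;
3. **Design-based confirmation** — survey-weighted logistic regression
   (pseudo-MLE with Taylor-linearized between-PSU variance, t inference on
   design df = #PSUs − #strata), Rubin's-rules pooling with Barnard–Rubin
   degrees of freedom, a both-halves univariate screen, collinearity and
   mediation elimination, a confounder + interaction final model, and an
   F-corrected goodness-of-fit test on grouped mean residuals with
   df (g−1, design df − g + 2).

Backward stepwise regression and lasso selection-frequency baselines are
included for validation studies, along with a synthetic-data generator
that produces survey-structured datasets with known truth (correlated
predictors, sparse effects, mediation triples, MCAR/MAR missingness,
stratified two-PSU-per-stratum designs).

The core estimators follow the statsmodels model/results convention:
`SurveyLogit(...).fit()` returns a `SurveyLogitResults` with coefficients,
linearized covariance and a `summary()` table on the odds-ratio scale;
`BernoulliBoost(...).fit()` returns a `BoostResults` with `predict`,
`variable_importance` and `pseudo_r2`; `ChainedImputer(...).fit()` returns
a `MultipleImputation` with the completed copies, `stack()` and
convergence traces.

## Worked example

Twelve correlated predictors, three of which truly affect a ~8%-prevalence
outcome (log-odds 0.8 each), under a 15-stratum / 2-PSU design with 15%
MCAR missingness:

```python
import surveysel as sv

cfg = sv.sparse_truth_config(n=3000, p=12, n_true=3, beta=0.8, seed=42,
                             missingness={"mechanism": "MCAR", "fraction": 0.15})
ds, truth = sv.generate_survey_study(cfg)

report = sv.run_pipeline(ds, sv.PipelineConfig(
    m=5, burn_in=8,
    boost=sv.BoostConfig(shrinkage=0.05, max_iterations=150, patience=10),
    seed=7))

print(report.final_terms)
print(report.final_summary.round(3))
```

prints

```
['x1', 'x2', 'x3']
       odds_ratio  std_err  p_value  ci_low  ci_high
const       0.036    0.004    0.000   0.028    0.045
x1          1.899    0.225    0.000   1.455    2.479
x2          2.097    0.160    0.000   1.776    2.475
x3          1.933    0.165    0.000   1.588    2.354
x4          1.009    0.117    0.937   0.781    1.305
...
```

The three planted predictors are the only terms significant in the pooled
final model, with odds ratios near e^0.8 ≈ 2.2 (slightly attenuated by the
cluster random intercept); the nine noise predictors that survived the
inclusive 2% importance screen are correctly flushed out at the
confirmatory stage. `report` also records Little's test (here
d² = 4294.2 on 4339 df, p = 0.68 — consistent with the MCAR mechanism
used), the full univariate screen table, and the reason each variable was
kept or dropped at every stage.

A worked example needing no fitting at all: the package ships a
transcribed 67-biomarker relative-importance summary from a published
NHANES depression screen; applying the 2% rule reproduces its selection of
exactly 21 biomarkers, which carry more than half of the total importance:

```python
table = sv.load_biomarker_importance()
selected, rationale = sv.select_by_importance(table, sv.SelectionRule(2.0))
len(selected)                    # 21
sv.coverage(table, selected)     # (58.34, 56.27)
```

A `surveysel` command-line interface exposes the same stages
(`simulate`, `diagnose`, `impute`, `boost`, `select`, `pipeline`); run
`surveysel --help`.

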
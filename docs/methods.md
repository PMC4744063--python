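# Methods

`surveysel` implements a three-stage variable-selection procedure for binary
health outcomes measured in complex-survey epidemiological studies with
missing predictor data, together with the synthetic-data machinery needed to
test every stage against known truth. This note records the statistical
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic studies do and do not establish about real data.

## The selection procedure

**Stage 1 — missingness diagnostics and chained imputation.** Before
imputing, two diagnostics ask whether the missingness is ignorable. Each
predictor's missingness indicator (1 = missing) is regressed on the study
outcome with a design-based logistic regression; a significant association
means missingness depends on the outcome. Little's test compares
pattern-wise observed means against EM-estimated grand means under
multivariate normality: with records grouped by missingness pattern *j*
(*n_j* records, *p_j* observed columns),

d² = Σ_j n_j (ȳ_j − μ̂_j)ᵀ Σ̂_j⁻¹ (ȳ_j − μ̂_j),  df = Σ_j p_j − p,

which is asymptotically χ²(df) under MCAR. The diagnostics run on the
*original* data. Running them on imputed data would be circular — the
imputation model already encodes an ignorability assumption — so the
package deliberately diagnoses first, imputes second.

Imputation is by chained equations (fully conditional specification): each
variable with missing cells gets a conditional model on all other model
variables, continuous variables a Bayesian linear regression, binary ones a
logistic regression. Parameter draws are taken from the approximate
posterior (normal-inverse-gamma conjugate draw for linear models; normal
draw around the ridge-stabilized ML fit for logistic ones) before drawing
imputations from the predictive distribution. This makes the imputation
*proper*: the between-imputation variance then reflects parameter
uncertainty, which is what validates Rubin's rules downstream. Visit order
is ascending missing-cell count (stabilizes early cycles); chains are
independent across imputations and, when a grouping variable is set (e.g.
sex), across group levels.

**Stage 2 — boosted-tree importance screening.** A from-scratch MART-style
booster with Bernoulli loss: F₀ is the training log-odds; each iteration
computes pseudo-residuals y − p on the training rows, draws a bag (default
50%, without replacement), grows a small best-first regression tree on the
bag's residuals, replaces each leaf mean with the one-step Newton value
γ = Σr / Σp(1−p), and updates F ← F + λ·tree(x). A 60:40 train/validation
split stops training at the first failure to improve the validation
Bernoulli log-likelihood (an optional patience parameter relaxes this,
default 0), retaining trees through the best iteration. Relative importance
of a variable is its summed squared-error split improvement across retained
trees, averaged per tree and normalized to total 100%.

The booster runs on the original (incomplete) dataset and on each completed
copy. Rows missing a candidate split variable are excluded from that
split's improvement computation and routed to the child that received more
training rows — the simplest defensible handling that lets the incomplete
original participate without surrogates. A variable enters the candidate
set when its importance in the original run strictly exceeds the cutoff
(default 2%) *or* its mean importance across imputations reaches the
cutoff. The asymmetry (strict > vs ≥) is part of the rule. The 2% default
is deliberately inclusive: the stage exists to discard clearly
uninformative variables while keeping a majority of the total importance
for the confirmatory stage.

**Stage 3 — design-based confirmation.** Estimation is weighted
pseudo-maximum likelihood (IRLS, step tolerance 1e-10) with
Taylor-linearized variance: with per-record score contributions
u_i = w_i (y_i − p_i) x_i summed to PSU totals u_{hc},

V = A⁻¹ [Σ_h n_h/(n_h−1) Σ_c (u_{hc} − ū_h)(u_{hc} − ū_h)ᵀ] A⁻¹,

where A is the weighted information and n_h the PSU count of stratum *h*
(with-replacement first-stage approximation, no finite-population
correction). Inference is t-based on the design degrees of freedom,
#PSUs − #strata. Subpopulations (the train/validation halves) are handled
by zeroing out-of-domain score contributions while every PSU stays in the
variance — standard domain estimation. Estimates across the m imputations
are pooled with Rubin's rules (Q̄, W, B, T = W + (1+1/m)B) and the
Barnard–Rubin small-sample degrees of freedom anchored at the design df.

The stage runs: a univariate screen (pooled p ≤ α in *both* halves, with
boundary equality counting as significant — a predictor sitting exactly at
0.05 is kept); collinearity elimination (pairwise weighted correlations
averaged over imputations, |r| ≥ 0.95 flags a pair, the lower-importance
member is dropped, chains resolve transitively by importance rank);
mediation elimination (X is declared fully mediated by M when X is
univariately significant, loses significance in the joint model {X, M}
while M keeps it, and |corr(X, M)| ≥ 0.3; circular verdicts drop neither);
and a final confounder-adjusted model in which candidate
covariate × biomarker interactions are screened one at a time at α and the
retained ones refit jointly. Model fit is checked with a design-adjusted
goodness-of-fit test: records are grouped into g = 10 weighted quantile
groups of predicted probability, the first g−1 group mean residuals are
tested with a linearized Wald statistic, and the F correction gives
F(g−1, d−g+2) — with 15 strata and 31 PSUs (d = 16), df (9, 8).

**Baselines.** Backward stepwise logistic regression (drop the highest-p
term while p > α) and L1-penalized selection frequency (per dataset: a
60:40 split, the penalty minimizing held-out deviance chosen from a
decreasing grid, non-zero coefficients recorded; frequency across the m+1
datasets is the importance measure). The lasso path is solved by
scikit-learn's liblinear coordinate solver at tolerance 1e-7; the stepwise
fits use statsmodels. Both exist to be compared against, not to select.

## Defaults that matter

| parameter | default | rationale |
|---|---|---|
| imputations m | 20 | inside the 5–20 band considered adequate at modest missing fractions |
| burn-in cycles | 10 | chain-mean drift is routinely < 0.2 pooled SDs by then in MCAR studies |
| imputation ridge | 1e-5 | near-collinear biomarker panels make conditional normal equations ill-conditioned |
| shrinkage λ | 0.001 | small-λ regime with validation stopping; larger values trade iterations for speed |
| bag fraction | 0.5 | the standard recommendation for stochastic boosting |
| max terminal nodes | 5 | small trees; interactions up to modest order |
| train fraction (boosting) | 0.6 | 60:40 validation-based stopping |
| min node size | 10 | keeps Newton leaf denominators away from zero (also floored at 1e-8) |
| inclusion cutoff | 2% | inclusive screening retaining > 50% of total importance |
| screen/final α | 0.05, boundary inclusive | a p = 0.05 candidate is retained |
| collinearity r | 0.95 | near-singularity threshold; the motivating pair had r ≈ 0.97 |
| mediation corr | 0.3 | X and M must be substantively associated for mediation to be meaningful |
| GOF groups g | 10 | decile grouping, giving the (9, 8) df pattern under the 15/31 design |

No multiple-testing correction is applied at the univariate screen (raw
p < 0.05); a Bonferroni-style correction can be imposed by passing a
smaller α, but the default mirrors the inclusive screening philosophy.

## The synthetic-data generator

`generate_survey_study` emulates the structure of a large cross-sectional
biomarker study: ~5,000 records, correlated continuous predictors, ~7.7%
outcome prevalence, 15 strata with 2 PSUs each, lognormal unequal weights
(dispersion 0.5 on the log scale), and a normal per-PSU random intercept
(SD 0.2 on the logit scale) inducing within-cluster correlation. Background
pairwise correlations default to Uniform(0.05, 0.30); these are declared
defaults for a plausible biomarker panel, not reconstructions of any real
panel. For wide panels where independent uniform draws are persistently
indefinite, the generator falls back to a one-factor structure whose
pairwise correlations stay inside the same range. The intercept is solved
by 1-d root finding when a target prevalence is given. Missingness is
injected MCAR (independent cell deletion) or MAR (deletion probability a
logistic function of a standardized driver with unit slope, intercept
root-found so the marginal fraction is exact in expectation); outcome and
design columns are never deleted.

When a mediation triple is configured, the driver is made independent of
the other predictors before the mediator is built from it. Without this,
a background-correlated true predictor opens a backdoor path and the
driver retains a conditional association with the outcome given the
mediator — the triple would not actually encode full mediation.

The collinear-predictor validation simulation draws six multivariate-normal
predictors with corr(x1, x2) = 0.8, a simple random design, and equal
(0.3 × 6) or varying (0.5 … 0.05) effects. The effect sizes and the −2.5
intercept (≈ 7.6% prevalence under null effects) are declared defaults.

What passing tests on these studies show — and do not show. The generator
produces Gaussian predictors, a correctly specified logistic outcome, and
clean MCAR/MAR mechanisms. Real biomarker panels are skewed and
heavy-tailed, missingness is rarely exactly MAR, and survey weights can
correlate with outcome model errors. Recovery and calibration results here
establish internal correctness of the machinery, not robustness to those
violations.

## Numerical decisions

* IRLS declares separation when any |β| exceeds 15 rather than iterating to
  divergence; the offending term is named.
* The linearized covariance is symmetrized and checked positive
  semi-definite (eigenvalue floor −1e-10 relative).
* EM for Little's test initializes from complete-case moments
  (available-case if fewer than 10 complete cases), stops at relative
  log-likelihood change < 1e-8 (max 500 iterations), asserts monotone
  log-likelihood at every iteration, and ridge-stabilizes singular
  pattern sub-blocks with a warning. Rows with no observed cells carry no
  information and are excluded from the effective sample size.
* Tree split search: thresholds are midpoints between adjacent distinct
  observed values; ties in improvement resolve to the lowest variable
  index, then the smallest threshold; the leaf to split next is the one
  with the largest best-split improvement, earliest-created leaf first on
  ties. The grower is validated against a naive exhaustive-search oracle
  on random toys (n ≤ 25, p ≤ 3), including discretized predictors that
  force exact ties.
* Rubin pooling at B = 0 takes the proper Barnard–Rubin limit
  ν → ν_obs = ((d+1)/(d+3))·d rather than special-casing the
  complete-data df. As B/W → ∞ the harmonic combination is dominated by
  ν_obs → 0, so pooled df decreases monotonically — the classical
  ν_large = (m−1)(1+1/r)² is an upper envelope, not the limit.
* Single-PSU strata are a hard error for variance estimation; an explicit
  `collapse=True` merges each into a neighbouring stratum with a warning.
* Importance is reported only when at least one split was retained; a run
  that stops at the constant model is recorded as a failure in the
  importance matrix rather than an all-zero column.

## Problem sizes used by the test suite

Monte-Carlo checks run at sizes chosen to make the suite a routine local
run: type-I calibration of Little's test at n = 300, p = 5 over 200
replicates; GOF calibration at n = 2,000 under a 15 × 2 design over 200
replicates (the model there has no cluster random effect, because the
marginal logistic model is otherwise mildly misspecified and the check is
of calibration under correct specification); CI coverage at n = 5,000 over
300 replicates; the collinear-pair contrast at the full n = 5,227 over 50
seeds with shrinkage 0.01 and strict stopping (≈130 trees per fit —
shrinkage 0.001 with ≈1,000 trees gives statistically indistinguishable
pair-importance behaviour at several times the cost); end-to-end recovery
at n = 3,000, p = 30, m = 5 over 20 seeds.

## Known limitations

* The boosted importance split between two equally-informative collinear
  predictors is governed by dataset-level near-symmetry: one member is
  *markedly* downgraded (share ratio ≤ 0.8) in roughly three quarters of
  equal-beta simulations, not in all of them. An independent
  gradient-boosting implementation shows the same rate under identical
  data, so this is a property of the statistic, not of this
  implementation. With unequal effects the rankings are far more stable.
* Variance estimation is first-stage (between-PSU) only, with replacement,
  and offers no replicate-weight methods.
* The imputer has no predictive-mean matching and no categorical
  (> 2 level) models; wide panels lean on the ridge stabilization.
* Mediation labels are associational screening rules, not causal claims.
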
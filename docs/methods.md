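# Methods

## Study design implemented

`palcost` implements a retrospective-cohort cost analysis of early hospital
palliative care in which a predicted length of stay (VMLOS), assigned from
baseline factors, is used twice: to define what "early" engagement means
relative to a patient's expected stay, and as a complexity covariate in the
cost regression. Three gamma/log-link cost models are compared on a common
analytic sample: (i) a fixed-day treatment rule `t1` (engagement within
*d* = 3 days) with baseline covariates; (ii) a predicted-LOS treatment rule
`t2` (engagement within 1/3 of predicted LOS) with the same covariates; and
(iii) `t1` with predicted LOS added as a covariate. All models are estimated
with ATET inverse-probability-of-treatment weights from a logistic
propensity model, and treatment effects are ATETs from recycled predictions
with subject-level bootstrap standard errors.

## Synthetic cohort generator

Real admission-level hospital data of this kind are access-restricted, so
the package ships a generator whose defaults define the study conditions
used throughout the tests.

**Structure.** Each admission draws demographics, 31 Elixhauser and 19
Charlson condition flags, and 7 life-limiting diagnosis flags with
prevalences tuned to a seriously ill tertiary-center case mix. A latent
severity factor (standard normal) raises condition prevalences, LOS and
daily cost, playing the role of patient complexity that condition flags only
partially capture. ln(LOS) is linear in a shared covariate-effect vector
(severity 0.30, ICU day-1 0.35, surgery day-1 0.20, solid tumor 0.12,
hematological tumor 0.18, Charlson 0.05/point, age 0.03/decade over 60) plus
N(0, 0.45) noise, exponentiated and rounded up to whole days (capped at 60).
Total direct cost is a sum of per-day gamma draws (shape 1.5) whose expected
value is `baseline_daily_cost × exp(covariate effects) × 0.92^(day−1)` —
costs accrue disproportionately early, which is what gives early
intervention its larger capacity to change totals. Defaults
(`baseline_daily_cost` $1,900/day, LOS intercept 1.55) give a mean LOS of
about 9 days and mean admission cost near $20k.

**Treatment process.** Palliative-care receipt is logistic in *observed*
baseline covariates (Charlson, solid tumor, ICU/surgery day-1, age > 75, ED
admission; intercept −2.8, giving roughly 16% receipt and 10–12% engagement
within 3 days). The engagement day is right-skewed: with probability
1 − r³ (r = exp(−`pc_timing_skew`), default skew 0.35) engagement is in days
1–3 (truncated-geometric within that window), otherwise it is a truncated
geometric day from day 4 to discharge; late-intent subjects discharged
before day 4 never engage. This split exists so that *early* engagement is
independent of the LOS noise given covariates — a day draw truncated at
discharge would otherwise make early engagement mechanically more likely for
short, cheap stays and confound the default treatment rule with the outcome
noise itself. The cost multiplier `pc_effect` (default 0.7) applies to days
strictly after engagement; both potential outcomes are computed from the
same per-day draws and returned as `GeneratorTruth`, whose `true_atet`
averages their difference over the realised day ≤ 3 treatment group.

**Unobserved selection is off by default.** Severity drives LOS and cost but
not receipt, so the IPTW + GLM pipeline is consistent under the defaults and
parameter-recovery/null-calibration properties are meaningful. Adding a
`severity` entry to `pc_selection_effects` reintroduces unobserved
confounding for robustness studies.

**What the generator does not emulate.** Real ICD coding, billing-line
detail, within-admission cost dynamics beyond geometric decay, readmission
processes beyond an admission counter, and calendar effects. Passing tests
therefore demonstrate correctness of the estimation machinery under a known
data-generating process, not unbiasedness on any particular hospital's data.

## Comorbidity indices

Weights ship as packaged CSVs citing van Walraven et al. (2009) and Charlson
et al. (1987); they are data, not code. The Charlson index is computed
without age points — age enters the models as its own covariate, and adding
age points twice would double-count it.

## VMLOS derivation

Candidates (31 condition flags plus demographics, diagnosis, insurance and
first-day admission type) are screened by bivariate association with ln(LOS)
at a liberal p < 0.20, then pruned by backward elimination in the
multivariable ln(LOS) regression until every predictor clears p < 0.10.
Predictions are discretised at derivation-sample tertiles — a score exactly
at a cutpoint goes to the lower (shorter-stay) category — and each category
carries the arithmetic mean *observed* LOS of its derivation subjects as its
predicted LOS in days. The tertile rule makes category shares equal on the
derivation sample by construction; on the analytic sample (sicker by
eligibility) shares are typically unequal, as expected. Zero retained
predictors degenerate to a single-category mean-LOS model, flagged but not
fatal. The design never touches outcome-derived fields (observed LOS, cost,
engagement day, death), and a leakage test asserts that dropping those
columns does not change the fit.

## Estimation chain and numerical choices

- **Propensity model:** logistic regression by penalized IRLS with a tiny
  ridge (λ = 1e−6) and step halving. The ridge matches the MLE to numerical
  precision on regular data but keeps the fit defined under directional
  quasi-separation (a rare covariate level pure in one class), which occurs
  routinely in bootstrap resamples. Harmful separation is still a diagnostic
  error: a control with fitted propensity ≈ 1 (unbounded ATET weight) or a
  model that classifies the groups perfectly.
- **ATET weights:** treated 1, controls p/(1−p). No weight truncation by
  default; extreme-weight behaviour surfaces as separation errors instead.
- **Cost model:** gamma GLM with log link (statsmodels IRLS,
  tolerance 1e−10), observation weights as variance weights. AIC/BIC are
  computed from the attained log-likelihood (−2ℓ + 2k, −2ℓ + k·ln n,
  counting the dispersion parameter). A design condition number above 1e4
  (on standardised columns) triggers a collinearity warning. A constant
  outcome is fit in closed form (intercept ln c) with degenerate information
  criteria.
- **ATET:** recycled predictions over treated subjects only. For an
  intercept + treatment model this reduces to exp(α+β) − exp(α), and
  unweighted it equals the difference of group sample means (asserted to
  1e−6 relative tolerance).
- **Bootstrap:** resample subjects with replacement; refit propensity,
  weights, GLM and ATET per replicate so weight-estimation uncertainty
  propagates; SE is the replicate standard deviation; the default CI is the
  normal approximation (estimate ± 1.96 SE), with a percentile option.
  Failed replicates (separation, non-convergence, single-class resample) are
  counted; more than 10% failing is an error.
- **Treatment-rule arithmetic:** the t2 ratio is compared with exact
  rational arithmetic (`fractions.Fraction`), so day 3 against a predicted
  9-day stay sits exactly on the 1/3 boundary and is treated (both rules are
  boundary-inclusive).

## Diagnostics and evaluation

- **Park test:** OLS of ln(squared raw residual) on ln(prediction); slope 0
  indicates constant variance, 1 variance ∝ mean, 2 gamma, 3 inverse-
  Gaussian. Zero residuals are dropped with a warning.
- **Grouped calibration (Hosmer–Lemeshow form):** subjects grouped by
  prediction deciles; each group's mean raw residual is standardised by its
  own estimated standard error and the squared discrepancies summed,
  referred to chi-square with one degree of freedom per group. Per-group
  variances are essential here: cost residual variance grows with the mean,
  and a pooled-variance F-test over-rejects badly on gamma data. Thin
  groups (< 2 subjects) reduce the group count with a warning.
- **Pregibon link test:** refit on the linear predictor and its square; the
  squared term's coefficient should be ≈ 0 under an adequate link.
- **Pearson test:** correlation of raw residuals with predictions. Note its
  textbook p-value assumes homoscedasticity and is anti-conservative under
  gamma variance; it is reported as the conventional battery member, not as
  a calibrated test.
- **Accuracy:** RMSE, MAPE = mean|y−μ̂|/y·100, MPE = mean(y−μ̂)/y·100. R² for
  a GLM is not uniquely defined; the package uses the squared Pearson
  correlation of observed and predicted costs on the raw dollar scale, which
  is comparable across models sharing an outcome (0 for constant
  predictions). Out-of-sample metrics come from seed-controlled k-fold
  cross-validation by subject (default k = 10), refitting the propensity
  stage inside each training fold when weights are part of the model
  specification.
- **Comparison:** nine metrics — R², in/out-of-sample RMSE and MAPE,
  |out-of-sample MPE|, AIC, BIC, CI width — tallied per-metric
  (lower-is-better except R²); no formal test is attached to information-
  criterion differences. ATET pairs are compared by t-test with
  independent-SE or paired-replicate SE and a normal reference.
- **Sensitivity grid:** for each fixed-day threshold d within each
  predicted-LOS tertile, the sample is restricted, treatment reassigned and
  the point ATET re-estimated; cells with fewer than 10 treated subjects are
  flagged missing rather than zero.

## Open design choices and their resolutions

- The published category LOS values arise from an unstated discretisation;
  the package uses prediction tertiles with within-category mean observed
  LOS, which reproduces a three-bin baseline-only index with day-valued
  categories.
- "Fixed effects" in this estimation tradition is read as the single-level
  GLM with the full covariate vector, not a random-effects model.
- Whether the bootstrap should refit the propensity stage per replicate is
  ambiguous in common practice; it is refit here so that weight uncertainty
  is inside the SE.
- The out-of-sample procedure is k-fold CV by subject; the fold count and
  seed are explicit configuration.

## Problem sizes used in the test suite

The statistical acceptance properties run at: parameter recovery n = 5,000
with 200 bootstrap replicates; null calibration over 200 cohorts of
n = 1,000 with 60 replicates each; balance at n = 2,674; Park calibration at
n = 10,000; model comparison over 50 cohorts of n = 1,500 with 40
replicates per model; sensitivity grid averaged over 10 cohorts of
n = 3,000. These sizes give Monte-Carlo noise well inside the asserted
tolerances while keeping the full suite to a few minutes; production runs
default to 1,000 bootstrap replicates.

## Known limitations

- Late palliative-care recipients remain in the comparison group by design;
  when the treatment effect is non-null their (small) post-engagement cost
  reduction slightly contaminates the control mean, which is visible as a
  sub-SE bias in parameter-recovery experiments.
- The propensity and cost models are intentionally the conventional
  parametric choices; neither matches the generator exactly (the true
  early-engagement probability is a scaled logistic, the true conditional
  cost mean is not exactly log-linear), so estimates carry small
  finite-sample biases that the acceptance tolerances account for.
- R² on the raw scale rewards fitting the long cost tail; it is reported for
  comparability, not as a goodness-of-fit test.
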
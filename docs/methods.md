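# Methods

This note documents the statistical procedures, default parameters and
design choices behind `diisurv`, and what the synthetic-data tests do and do
not establish about real cohort data.

## Dietary Inflammatory Index

The DII scores a diet's inflammatory potential as a weighted sum of centred
intake percentiles. Per parameter p: `z_p = (x_p − μ_p)/σ_p` against a
global reference mean and SD, then `c_p = 2·Φ(z_p) − 1`, then
`DII = Σ w_p·c_p`. Two choices deserve comment.

**Percentile transform.** The mapping from z-scores to the (−1, 1)
percentile scale uses the doubled normal CDF, the established convention
for this index. Because `2Φ(z) − 1` saturates to ±1 in double precision for
|z| ≳ 8, percentiles are clipped to ±(1 − 1e−12) so the open-interval
invariant holds for arbitrary inputs; the numerical effect is below any
reportable precision. A within-cohort empirical (mid-rank) percentile mode
is available via `score_intakes(..., percentile="empirical")` for
sensitivity analyses; results then depend on the scored cohort.

**Reference table.** The shipped 29-parameter table (`data/dii_reference.csv`)
carries literature-derived global means, SDs and inflammatory weights for
the parameters typically available from a 24-h-recall-based cohort (energy,
macronutrients, fatty-acid classes, fibre, vitamins, minerals, caffeine,
alcohol, tea). It is a placeholder in the sense that any study should
substitute its own table (same four columns) if one is available; all code
paths take the table as an argument.

**eDII.** The energy-adjusted score replaces intakes by densities per
1,000 kcal and scores them against a density-scale reference. If no
external density reference is supplied, one is derived from the scored
cohort (sample mean/SD of each density, weights carried over). Under the
density method total energy itself becomes the constant 1,000 kcal per
1,000 kcal, so the energy parameter is dropped from a derived density
reference; near-constant densities are dropped on the same rule.

Missing parameters are a hard error at the scoring interface (columns) and
produce NaN scores for individual incomplete rows; removing such rows is
the cohort builder's responsibility, which records them as `missing-data`
exclusions.

## Diet-quality indices

**HEI-2020** (`data/hei2020_standards.csv`): 13 components, maxima summing
to 100. Each component's scoring variable — a food-group density per
1,000 kcal, the fatty-acid ratio (MUFA+PUFA)/SFA, or percent of energy for
added sugars (4 kcal/g) and saturated fat (9 kcal/g) — is linearly
interpolated between the score-0 and maximum-score standards and clamped.
Moderation components have standards in reverse order, so one formula
covers both directions. Food-group amounts (cups/oz equivalents) are input
columns; deriving them from nutrients is out of scope.

**MEDS** (`data/meds_components.csv`): nine components, one point each —
five beneficial food groups plus the MUFA/SFA ratio at or above the cohort
median, two detrimental groups below the median, and alcohol inside a
moderate window. Defaults: sex-specific medians when a sex column is
available (overall medians otherwise), and a 5–25 g/day alcohol window for
both sexes. Both choices are assumptions (the scoring literature varies);
they are constructor arguments of `MEDSConfig`.

## Cohort construction

Exclusions are applied row-wise with first-match precedence
`missing-data → prior-disease → landmark`, one logged reason per dropped
participant, so retained + excluded always equals input. The landmark drops
anyone whose event *or censoring* falls within 365.25 days (52.18 weeks) of
entry — the standard guard against reverse causation from disease latent at
baseline; the duration is a parameter.

Covariate reclassification follows the conventions of the cohort the
package emulates: education codes 1 → high, {2, 5, 6} → median,
{3, 4, 7} → low, with prefer-not-to-answer represented by the sentinel −3
and mapped to low (the positive codes are all assigned to substantive
categories, so the sentinel convention avoids a collision); blood pressure
classified as normal (SP<120 and DP<80), elevated (120≤SP≤129 and DP<80),
stage 1 (130≤SP≤139 or 80≤DP≤89, unless stage 2), stage 2 (SP≥140 or
DP≥90) — the "or" logic makes the rule total over the positive quadrant;
age dichotomised at 58 years with the boundary going to "older"; Townsend
deprivation index at −2.3 with the boundary going to "low". Boundary
conventions are arguments.

Quartiles are rank-based: with n = 4q + r the first r groups receive the
extra member (so 121,329 observations split 30,333/30,332/30,332/30,332),
tied values share the quartile of the first member of their value block,
and a fully tied vector collapses to Q1 with a warning.

## Survival inference

*Adjustment tiers.* Tier 1 unadjusted; tier 2 age, sex, ethnicity,
education, deprivation; tier 3 additionally alcohol, smoking, BMI, physical
activity, blood-pressure category, diabetes. Age, deprivation and BMI enter
continuously; categorical covariates are dummy-coded against fixed
reference levels (female, white, high education, rare alcohol/smoking,
activity-target reached, normal blood pressure, no diabetes). Constant
columns raise a named error rather than silently dropping.

*Cox fits* use the Efron tie approximation with a tightened Newton
tolerance (1e−9) so small-sample coefficients agree with brute-force
partial-likelihood maximisation to better than 1e−4. The trend test refits
the model with quartile labels replaced by within-quartile median exposure
and reports the Wald p; it requires strictly increasing quartile medians.
Time is measured in weeks throughout.

*Restricted cubic splines.* The natural-spline basis (linear beyond the
boundary knots, k−2 nonlinear terms scaled by (k_last−k_first)²) is built
in-package; default 4 knots at the 5th/35th/65th/95th exposure percentiles,
3–5 supported. `overall_p` is the Wald test of all spline terms and
`nonlinear_p` of the nonlinear terms only, from the fitted coefficient
covariance.

*Proportional hazards.* The Grambsch–Therneau statistic correlates scaled
Schoenfeld residuals with a time transform (default Kaplan–Meier, also
rank/identity/log). Per-covariate statistics follow the classical
single-degree form; the global test is
`d·u'Vu / Σ(g−ḡ)²` on p degrees of freedom, with u the
transform-weighted sum of unscaled residuals and V the coefficient
covariance. When the global test rejects (p < 0.05), the Weibull AFT model
(log-normal and log-logistic as options) reports time ratios instead.

*Fine-Gray.* The subdistribution-hazard model is implemented as an
IPCW-weighted partial likelihood: subjects with competing events stay in
risk sets after their event with weight `G(t−)/G(T_i−)`, where G is the
Kaplan–Meier estimate of the censoring survival function (left-continuous,
covariate-free — the classical formulation). Ties are handled by Breslow
weighting within the weighted likelihood (the plain Cox route keeps Efron;
the reduction identity is exercised on tie-free data, where the two
coincide). Newton iterations with step-halving converge to a gradient
norm below 1e−6; with no competing events every weight is 1 and the fit
equals Cox regression to optimizer tolerance. Variance is the Lin–Wei
sandwich over per-subject score residuals; the correction for estimating G
is omitted, the usual first-order approximation, which makes the CIs very
slightly conservative in heavy-censoring settings.

*Progression.* Among incident cases the time origin is reset to diagnosis
and the same Cox machinery applies to post-diagnosis outcomes.

*Subgroups.* Stratum-specific fits drop only the stratifier (and its
continuous source for derived splits, e.g. age for the age-group split)
from the adjustment set; heterogeneity is a Wald test of
exposure × stratum product terms in a pooled model with the exposure
continuous. Strata without events are flagged and skipped with a warning.
Biomarker correlations default to Pearson with a Spearman option; the
method is recorded in the output.

## Synthetic cohort generator

The generator reproduces the *structure* the analysis assumes, with
defaults chosen to match the regime of a large UK cohort study of diet and
liver disease:

- **Intakes**: exchangeable-correlation (ρ = 0.2) log-normal draws with
  medians at the reference global means and log-SD 0.35; food-group columns
  for the diet-quality indices drawn log-normally at realistic medians.
- **Covariates**: marginals matching the published baseline table (52%
  female, 95% white, 44/34/23% high/median/low education, 8% current
  smokers, 4% diabetes, …), age ≈ N(57.5, 8²) truncated to 37–73, BMI
  log-normal with median 26.3, TDI ≈ N(−2.3, 3²). Mild gradients along the
  standardised DII (younger, higher-BMI, more deprived, more current
  smokers, less active at higher DII) reproduce the qualitative quartile
  patterns of such cohorts while preserving the configured marginals on
  average.
- **Events**: cause-specific exponential hazards per week — CLD 5.2e−5
  multiplied by `exp(0.0325·DII + 0.04·(BMI−26.3) + 0.5·diabetes +
  0.3·current-smoking)`, cirrhosis 4e−6, liver cancer 2.5e−6, death 8e−5 —
  with administrative censoring uniform on 545–665 weeks. This yields a
  ~3% incident-CLD fraction over a median ~600 weeks, matching the
  published event regime. The first cause to fire is recorded.
- **Progression**: post-diagnosis exponential hazards (cirrhosis 2.5e−4
  per week with log-HR 0.104 per DII unit, i.e. HR ≈ 1.11; liver cancer
  1.2e−4 with no DII effect), censored uniformly at 52–550 residual weeks.
- **Biomarkers**: `a·z_DII + noise` with `a = r/√(1−r²)` so the population
  correlation equals the target (WBC 0.062, neutrophils 0.054, CRP 0.053),
  rescaled to clinical units.
- **Blemishes**: 0.5% of rows get one missing nutrient, 0.4%/1.6% carry
  prior-CLD/prior-malignancy flags, 70% are flagged as typical diet — so
  the exclusion and sensitivity paths are exercised end to end.

Identical config + seed reproduces identical tables byte for byte.

**What the generator does not emulate**: real nutrient intakes are not
jointly log-normal with exchangeable correlation; hazards are not constant
in time; diagnosis arrives through hospital coding with delay and error;
covariates are measured with error and missing not-at-random. Passing
tests therefore demonstrate that the *estimators* are correct and
calibrated under the assumed data-generating process — they do not certify
that effect estimates from any real cohort are unbiased.

## Verification strategy and problem sizes

Deterministic components are checked against independent oracles: scoring
against value-by-value recomputation via `erf` (1e−10), the normal CDF
against numerical integration of the density, Cox coefficients against
grid-search maximisation of a hand-written Efron partial likelihood (1e−4
on well-posed small datasets; completely separated datasets have no finite
maximiser and are excluded), the Fine-Gray solver against a loop-written
IPCW likelihood oracle and against Cox when no competing events exist
(1e−6), and the per-covariate Schoenfeld statistics against an independent
implementation of the same test.

Stochastic components are checked by simulation at desk scale, sizes chosen
to keep the full suite in the tens of minutes on one CPU: effect recovery
and CI coverage over 100 cohorts of n = 20,000 at the true per-unit
log-HR 0.0325 (mean HR within [1.028, 1.038], coverage within [90%, 99%]);
type-I-error uniformity (Kolmogorov–Smirnov) and ≥80% power over 200
replicates at n = 10,000 for the spline nonlinearity test and n = 10,000 /
5,000 for the PH diagnostic; biomarker-correlation recovery at n = 100,000.
The acceptance script reports single large-cohort estimates
(n = 140,000 for Cox/progression, n = 100,000 for Fine-Gray) plus a
50-replicate recovery summary.

## Known limitations

- The shipped DII reference and HEI/MEDS standards are literature-derived
  defaults, not the exact tables of any specific study; results on real
  data depend on substituting study-specific tables.
- The Fine-Gray variance omits the censoring-estimation correction term.
- Breslow ties inside the Fine-Gray likelihood (Efron elsewhere).
- The AFT fallback reports time ratios, which are not numerically
  comparable to hazard ratios; the package never converts between them.
- Quartile boundary and landmark conventions are configurable but the
  defaults encode one specific set of choices, documented above.
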
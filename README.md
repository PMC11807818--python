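# diisurv

Dietary-inflammation scoring and chronic liver disease (CLD) survival
modelling.

Epidemiological cohorts increasingly ask whether a pro-inflammatory diet
raises the risk of chronic liver disease — fatty liver disease, hepatitis,
cirrhosis, liver fibrosis and hepatocellular carcinoma. `diisurv` implements
the full analysis pipeline for that question: it scores diets on the
**Dietary Inflammatory Index** (DII) and its energy-adjusted variant (eDII),
on the **Healthy Eating Index 2020** (HEI-2020) and the **Mediterranean Diet
Score** (MEDS); builds an analysis-ready cohort with a one-year landmark and
standard covariate reclassification; and estimates exposure–outcome
associations with Cox proportional-hazards, Fine-Gray competing-risk,
restricted-cubic-spline and accelerated-failure-time models, plus subgroup,
sensitivity and biomarker-correlation analyses. A seeded synthetic-cohort
generator emulates the structure of a UK-Biobank-style cohort so every stage
is testable without access-restricted data.

It is written for biostatisticians and nutritional epidemiologists who want
a reproducible, scriptable version of this analysis with the statistical
machinery exposed as plain functions.

## The scores and models

**DII.** For each of 29 dietary parameters with literature-derived global
mean μ_p, SD σ_p and inflammatory effect weight w_p (negative =
anti-inflammatory), an individual's mean daily intake x_p is standardised
and mapped to a centred percentile:

    z_p = (x_p − μ_p) / σ_p,   c_p = 2·Φ(z_p) − 1 ∈ (−1, 1),
    DII = Σ_p w_p · c_p

The **eDII** applies the same steps to nutrient densities per 1,000 kcal of
total energy, against a density-scale reference. The shipped reference table
is literature-derived and fully replaceable by CSV.

**Survival models.** For exposure quartiles Q1–Q4 (Q1 reference) or the
continuous score, the package fits Cox proportional-hazards models at three
adjustment tiers (1: unadjusted; 2: + age, sex, ethnicity, education,
Townsend deprivation index; 3: + alcohol, smoking, BMI, physical activity,
blood-pressure category, diabetes), with the Efron tie correction. The
"P for trend" replaces quartile labels by within-quartile median exposure.
Nonlinearity is assessed with a restricted cubic spline (4 knots at the
5th/35th/65th/95th percentiles) and Wald tests of all / nonlinear-only
spline terms. The proportional-hazards assumption is checked with
Grambsch–Therneau scaled-Schoenfeld tests (Kaplan–Meier time transform);
when it fails, a Weibull accelerated-failure-time model is the fallback.
Competing risks (cirrhosis, liver cancer, death competing with incident
CLD) are handled by a **Fine-Gray subdistribution-hazard model**: subjects
with competing events remain in later risk sets with inverse
probability-of-censoring weights G(t−)/G(T_i−) from a Kaplan–Meier fit of
the censoring distribution; the weighted partial likelihood is maximised by
Newton's method and CIs use a robust sandwich variance. Progression among
incident cases resets the time origin to diagnosis.

## Worked example

```python
from diisurv import (SimulationConfig, generate_cohort, build_cohort,
                     fit_cox, fit_fine_gray)

tables = generate_cohort(SimulationConfig(n=50_000, seed=42))
cohort, log = build_cohort(tables["intakes"], tables["covariates"],
                           tables["followup"])
print(f"analysis cohort: {len(cohort)} participants "
      f"({len(log)} excluded: {log.counts()})")
print(f"incident CLD events: {(cohort['event'] == 'cld').sum()}")

quart = fit_cox(cohort, exposure="dii", mode="quartile", tier=3)
for q, e in quart.quartile_hr.items():
    print(f"  {q} vs Q1: HR {e.hr:.3f} "
          f"(95% CI {e.ci_low:.3f}-{e.ci_high:.3f}), p={e.p:.3g}")
print(f"  P for trend: {quart.trend_p:.3g}")

e = fit_cox(cohort, exposure="dii", mode="continuous", tier=3).continuous_hr
print(f"  per DII unit: HR {e.hr:.3f} "
      f"(95% CI {e.ci_low:.3f}-{e.ci_high:.3f}), p={e.p:.3g}")

e = fit_fine_gray(cohort, exposure="dii", mode="continuous",
                  tier=3).continuous_shr
print(f"  Fine-Gray per DII unit: sHR {e.hr:.3f} "
      f"(95% CI {e.ci_low:.3f}-{e.ci_high:.3f}), p={e.p:.3g}")
```

Output:

```
analysis cohort: 48377 participants (1623 excluded: {'prior-disease': 1027,
                                     'landmark': 352, 'missing-data': 244})
incident CLD events: 1478
  Q2 vs Q1: HR 0.944 (95% CI 0.813-1.096), p=0.45
  Q3 vs Q1: HR 1.018 (95% CI 0.879-1.179), p=0.811
  Q4 vs Q1: HR 1.079 (95% CI 0.931-1.250), p=0.312
  P for trend: 0.207
  per DII unit: HR 1.032 (95% CI 0.992-1.073), p=0.119
  Fine-Gray per DII unit: sHR 1.032 (95% CI 0.991-1.074), p=0.125
```

The generator's default continuous effect is a log-hazard of 0.0325 per DII
unit (HR ≈ 1.033): the fitted per-unit HR of 1.032 recovers it, and the
Fine-Gray sHR agrees closely because competing events are rare. Quartile
contrasts are noisier at this sample size — with ~1,500 events the Q4-vs-Q1
CI spans ±15% — which is why calibration claims in the test suite average
over many replicate cohorts rather than reading one fit.

The same pipeline is scriptable from the shell:

```bash
diisurv simulate --seed 42 --n 50000 --out-dir data/
diisurv score-dii --intakes data/intakes.csv --out dii.csv
diisurv build-cohort --intakes data/intakes.csv --covariates data/covariates.csv \
    --followup data/followup.csv --out cohort.csv
diisurv fit-survival --cohort cohort.csv --model 3 --mode quartile
diisurv run-all --seed 42 --n 50000 --out-dir results/
```

`run-all` writes quartile/continuous/trend association tables, progression
and forest-plot CSVs, biomarker correlations and a manifest with a canonical
config hash so any reported number can be regenerated.

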
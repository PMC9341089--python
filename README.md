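# ckdval

**External validation toolkit for non-invasive chronic kidney disease (CKD)
risk prediction models.**

Chronic kidney disease stays asymptomatic into late stages, and most people
with reduced renal function do not know it.  Several questionnaire-level
prediction models estimate the probability of *prevalent* CKD — defined as
an estimated glomerular filtration rate (eGFR) below 60 mL/min/1.73 m² —
from non-invasive predictors only (age band, sex, hypertension, diabetes,
cardiovascular history, anemia, proteinuria, kidney stones), making them
candidates for cheap population screening.  `ckdval` implements six such
published models — Bang's **SCORED** and **modified SCORED**, **Kearns**,
**Kshirsagar**, **Kwon** and **Thakkinstian** — together with the full
machinery needed to validate them externally in a cohort, and a seeded
synthetic-cohort generator emulating the marginal structure of a German
general-population cohort aged 45–75, so every stage is testable without
access to restricted participant data.

Each model is a logistic equation

```
logit P(CKD) = β₀ + Σⱼ βⱼ xⱼ  (+ age-interaction add-ons for Kearns)
```

with binary predictors `xⱼ` derived by model-specific rules (e.g. anemia is
hemoglobin < 12 g/dL for all models except Kwon, which uses < 12/< 13 g/dL
for women/men), plus an integer point-score version with published
thresholds.  The validation report covers:

* **discrimination** — c-statistic (AUC, with Hanley–McNeil, DeLong or
  bootstrap CIs) and Tjur's coefficient (difference of mean predicted risk
  between cases and non-cases);
* **overall performance** — MAPE, Brier score and scaled Brier score;
* **calibration** — risk-decile observed-vs-expected tables and
  intercept-only recalibration;
* **threshold diagnostics** — sensitivity, specificity, PPV/NPV, the
  Youden-optimal threshold and expected/observed case proportions (E/O)
  with bootstrap CIs, per published score threshold.

The outcome side implements the CKD-Epi (2009), MDRD and Full-Age-Spectrum
(FAS) creatinine equations; the eGFR equation is a first-class sensitivity
axis (it changes the outcome, never the predictions).

## Worked example

Risk for a fictitious 75-year-old woman with hypertension, diabetes,
proteinuria and anemia under the SCORED model:

```console
$ ckdval predict --model scored --age 75 --sex f \
    --hypertension --diabetes --proteinuria --anemia
model: SCORED
predicted CKD risk: 68%
point score: 9 (range 0-12; published thresholds 4, 5, 6, 7)
```

The 68% is the inverse logit of −5.40 + 3.23 (age ≥ 70) + 0.29 (female) +
0.45 (hypertension) + 0.44 (diabetes) + 0.83 (proteinuria) + 0.93 (anemia)
= 0.77; the score of 9 (4 age points + 5 items) lies above every published
screening threshold, so this person would be referred for creatinine
testing at any cut-off.

End-to-end on a synthetic cohort:

```console
$ ckdval simulate --n 4185 --seed 1 --out cohort.csv
wrote 4185 participants to cohort.csv (CKD prevalence 9.2%, seed 1)
$ ckdval validate --in cohort.csv --out report.json --tables-dir tables
wrote report for 6 models to report.json
```

`tables/performance.csv` from that run:

```
          model    n  mean_prediction  c_statistic  tjur  mape  brier  scaled_brier
         scored 4185            0.065        0.776 0.066 0.134  0.077         0.084
modified_scored 4185            0.066        0.756 0.059 0.136  0.078         0.071
         kearns 4185            0.201        0.732 0.114 0.237  0.092        -0.099
     kshirsagar 4185            0.147        0.760 0.077 0.199  0.079         0.053
           kwon 4185            0.017        0.759 0.017 0.103  0.087        -0.038
   thakkinstian 3458            0.194        0.718 0.121 0.230  0.091        -0.091
```

Read: all six models discriminate fairly (c ≈ 0.72–0.78) in the synthetic
cohort; the Kearns, Kshirsagar and Thakkinstian models overestimate the
9.2% prevalence on average (mean predictions 0.15–0.20) while Kwon
underestimates it (0.017), which the negative scaled Brier scores and the
calibration tables make visible — the same qualitative pattern motivates
intercept recalibration, whose result is included per model in
`report.json`.  The Thakkinstian row uses the 3,458-record subsample with
kidney-stone information (per-model complete-case filtering).  Note the
cohort is synthetic: these numbers characterize the generator's study
conditions, not any real population.

The library surface mirrors the CLI (`ckdval.builtin_models`,
`derive_predictors`, `predict_risk`, `score`, `egfr_*`, `c_statistic`,
`diagnostic_table`, `generate`, `run_validation`, …); see the module
docstrings and `docs/methods.md` for the underlying definitions and design
choices.

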
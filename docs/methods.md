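# Methods

This note documents the statistical content of `ckdval`: the six risk
models and their derivation rules, the eGFR equations and CKD outcome, the
validation metrics, the synthetic-cohort generator, and the design choices
made where the published sources were ambiguous or silent.

## Risk models

Each model is a logistic regression on binary predictors; `ModelSpec`
stores the intercept, main-effect terms and (for Kearns) age-interaction
add-ons, all in logit units.

| model            | parameters | intercept | age handling |
|------------------|-----------:|----------:|--------------|
| SCORED           | 9 | −5.40 | bands 50–59 / 60–69 / ≥70: 1.55 / 2.31 / 3.23 |
| modified SCORED  | 7 | −5.38 | bands: 1.55 / 2.29 / 3.29 |
| Kearns           | 5 | −3.63 | continuous, centered at 46.72 y (see below) |
| Kshirsagar       | 8 | −3.30 | bands (<50: 0.104): 0.63 / 1.33 / 1.46 |
| Kwon             | 7 | −6.53 | bands: 1.16 / 1.91 / 2.71 |
| Thakkinstian     | 4 | −3.3 (default) | bands: 0.6 / 1.4 / 2.1 |

Age bands are closed-left: [50, 60), [60, 70), [70, ∞).

**Predictor derivation rules.** Hypertension: SBP ≥ 140 mmHg or DBP ≥ 90
mmHg or antihypertensive medication (inclusive "at least" boundaries);
an explicitly ascertained status flag fills gaps when measurements are
missing and, when positive, dominates.  Anemia: hemoglobin < 12 g/dL
(strict) for all models except Kwon, which uses < 12 g/dL for women and
< 13 g/dL for men.  Diabetes: self-report only for the Bang models and
Kshirsagar; self-report or antidiabetic medication for Kwon and
Thakkinstian (the source cites the definitional references without naming
the models; this assignment follows the citation order of the model
columns).  Albuminuria from a measured ratio: ACR ≥ 30, consulted only
when no self-reported proteinuria status is available.  "IHD" in a profile
sets both the combined IHD-or-stroke predictor and the Kearns-specific IHD
predictor.  A record missing any predictor a model requires raises an
explicit incomplete-record signal; the pipeline turns this into per-model
complete-case subsets (so the Thakkinstian model, the only user of
kidney-stone history, is validated on the subsample carrying that item).

**Kearns age terms.** Age enters linearly as 1.075 · (age − 46.72)/10 and
quadratically as −0.01 · (age − 46.72)²/10.  The quadratic's scaling is
ambiguous in the source material (squared centered decades vs. squared
centered years divided by ten); the implemented form is the only one that
reproduces a published worked example (75-year-old woman with
hypertension → 52%), so it is the default, and the centering constant and
both term coefficients are plain `ModelSpec` data that a config file can
override.

**Thakkinstian intercept.** Two candidates exist: −2.8 (printed, estimated
from the validation population's prevalence) and −3.3 (the value that
exactly reproduces all four published worked-example risks; the printed
value is off by +0.5 logit on every one of them).  The default is −3.3;
`builtin_models(thakkinstian_intercept="published")` or a config file
selects −2.8.  Neither choice affects discrimination or score-based
diagnostics (the shift is monotone).

**Table transcription choices.** Two cells of the published coefficient
table cannot be unambiguously recovered from the running text: the
age-< 50 coefficient 0.104 is assigned to the Kshirsagar model (it
directly precedes Kshirsagar's age-band values, and Kearns's age cell is
complete without it), and 0.88 is taken as Kshirsagar's anemia coefficient
(the original Kshirsagar model includes anemia among its eight predictors
and the anemia row as published has one value fewer than the models using
the predictor).  Neither cell is exercised by any reproducible worked
example; both are overridable via the model-config interface.

**Score tables.** The original point tables are cited, not reprinted, in
the validation source, so the defaults are reconstructions constrained to
reproduce the published admissible ranges: 2/3/4 points for the age bands
and 1 point per other item for SCORED (0–12), modified SCORED (0–10) and
Kwon (0–10); 1/2/2 age points plus seven 1-point items for Kshirsagar
(0–9); coefficient-proportional points (age 2/4/6, hypertension 3,
diabetes 3, kidney stones 4) for Thakkinstian (0–16).  Kearns has no
published scoring rule and hence no score table and no threshold
diagnostics.  All tables are serializable to YAML so the originally
published questionnaires can be dropped in verbatim.  Classification at a
threshold is inclusive (score ≥ threshold).

## Renal function and outcome

CKD is eGFR < 60 mL/min/1.73 m² (strict, on the unrounded value).  Three
creatinine equations are implemented with their standard constants:
CKD-Epi 2009 (sex-specific knot 0.7/0.9 mg/dL and exponent −0.329/−0.411,
female factor 1.018), MDRD (default constant 186, appropriate for
creatinine not standardized to isotope-dilution mass spectrometry; 175
selectable) and the adult Full-Age-Spectrum equation (107.3/(Scr/Q) with
Q = 0.70/0.90 and attenuation 0.988^(age−40) beyond age 40).  Race
adjustment factors are off by default (European general-population
setting) and selectable for fidelity to the original equations.  All three
equations have exact closed-form inversions (creatinine from eGFR), used
by the generator and property-tested to round-trip at 1e−9 relative
tolerance.

## Validation metrics

* **c-statistic**: Mann–Whitney form via midranks (ties count ½), verified
  against an exhaustive O(n²) pair-count oracle and scikit-learn.  CI
  methods: Hanley–McNeil analytic SE (default; the classical ROC
  treatment), DeLong structural components, or percentile bootstrap.
* **Tjur coefficient**: difference of class means of the prediction; CI by
  seeded nonparametric bootstrap (1,000 resamples by default) since no
  analytic interval is standard.
* **MAPE** = mean |y − p̂|; **Brier** = mean (y − p̂)².
* **Scaled Brier**: convention A (default) is 1 − Brier/(p̄(1−p̄)) with p̄
  the *outcome* prevalence — the only combination that is 1 for perfect
  predictions, 0 for a prevalence-constant prediction, and interpretable
  like an R².  The literal "mean prediction" denominator and the raw-ratio
  convention B are selectable.  Published scaled-Brier values for these
  models are not reconcilable with either convention and are not used as
  reference values.
* **Calibration**: deciles of predicted risk (binning rule not stated in
  the validation source; deciles are the field standard), reporting
  per-bin count, mean prediction and observed proportion; coincident
  quantile edges are merged with a warning.
* **Intercept recalibration**: the intercept is shifted (Brent root
  finding, tolerance 1e−10) until mean predicted risk equals observed
  prevalence; slopes untouched.
* **Threshold diagnostics**: exact count-based sensitivity, specificity,
  PPV/NPV (undefined cells flagged `None`, never imputed); E/O =
  screen-positives / observed cases with seeded bootstrap CI (method
  unstated in the source); Youden-optimal threshold by exhaustive scan
  over observed score values, ties broken toward the lowest threshold.
  The identities E/O = sens + (1−spec)(1−P)/P and
  PPV = sens·P/(sens·P + (1−spec)(1−P)) hold exactly and are
  property-tested.

## Synthetic cohort generator

The generator emulates the marginal structure of the German validation
cohort (general population aged 45–75): age truncated-normal(59.6, 7.8)
on [45, 75]; 50.5% female; comorbidity marginals hypertension 59.2%,
diabetes 7.9%, IHD/stroke 6.9%, heart failure 3.5%, PVD 2.3%, proteinuria
1.7%, anemia 2.1%, kidney stones 12.0%; CKD prevalence target 9.2%
(CKD-Epi); kidney-stone missingness 18% (matching the published
subsample fraction).  Note the nominal age SD parametrizes the untruncated
normal; truncation to [45, 75] shrinks the realized SD to ≈ 6.7 years.

Only marginals are published, so the dependence structure is a modeling
choice: each flag follows a logistic model in standardized age, sex and a
single shared latent frailty factor (loadings in `CohortConfig`; the
cardiovascular cluster loads most strongly), and the flag's intercept is
solved by root finding so that the mean probability over the realized
covariates equals the target exactly — the drawn marginal then deviates
only by binomial noise √(p(1−p)/n).  Measured quantities are generated
consistently with their flags (hemoglobin below/above 12 g/dL, blood
pressure and medication reproducing the hypertension definition, ACR
≥ 30 iff reported proteinuria), so re-deriving predictors from the emitted
measurements recovers the flags.

Renal function: latent log-eGFR = baseline − 0.0095·(age − 59.6) +
comorbidity effects (−0.015 to −0.22 log units; proteinuria and anemia
largest) − 0.05·frailty + N(0, 0.165) noise (lognormal eGFR noise keeps
creatinine positive and right-skewed); the baseline is set from the
empirical quantile of the structural part so the sample CKD prevalence
hits the 9.2% target.  Creatinine is the exact inverse of the configured
eGFR equation at the latent eGFR, so the observed outcome recomputed from
creatinine equals the latent one to machine precision; the resulting
creatinine marginals (mean ≈ 0.92, SD ≈ 0.21 mg/dL) and eGFR marginals
(mean ≈ 80, SD ≈ 16) fall near the published cohort moments without being
directly calibrated.

Two outcome mechanisms: `from_renal` (default; outcome from creatinine,
mirroring the real design) and `from_model` (outcome Bernoulli in a
planted model's predicted risk, used for parameter-recovery and
calibration experiments; planted-Thakkinstian runs switch off stone
missingness so every record has a defined risk).

**What passing tests do and do not show.** The generator reproduces
published *marginals* plus a plausible dependence structure; it carries no
geographic, socioeconomic or longitudinal structure, no measurement error
model for creatinine assays (e.g. Jaffé vs. enzymatic bias), and its
comorbidity correlations are assumptions, not estimates.  Validation
metrics computed on synthetic cohorts therefore characterize the
machinery and the generator's conditions — they are not estimates of any
real population's values, and the original study's cohort-dependent
results (c-statistics, mean predictions, operating points) are
intentionally out of scope.

## Pipeline

`run_validation` recomputes the outcome from serum creatinine with the
configured equation (records without creatinine are excluded from the
outcome, or a provided outcome column is used for planted cohorts), forms
per-model complete-case subsets, and emits a deterministic JSON report
(fixed seed ⇒ identical bytes) with per-model metric blocks, calibration
tables, recalibrated intercepts and threshold diagnostics, plus CSV
exports.  Models with no complete cases are skipped with an explicit
reason; single-class outcomes flag discrimination metrics as undefined
rather than failing the run.  Human-readable risk output is rounded to
whole percent (the convention of the published worked examples); JSON
keeps full precision.

## Problem sizes and numerical choices

Default bootstrap: 1,000 resamples, seeded.  Oracle-agreement tests use
100 random instances of n ≤ 500 (AUC) and n ≤ 200 (Youden); statistical
acceptance checks (parameter recovery, marginal calibration,
recalibration stability) use cohorts of n = 50,000 with fixed seeds —
large enough that 3-standard-error and 3·√(p(1−p)/n) bounds are
informative, small enough to run in seconds.  Root finders use brackets
[−40, 40] (flag calibration) and [−50, 50] (recalibration) on the logit
scale, far beyond any realistic intercept.  Degenerate inputs are
explicit errors: single-class outcomes, zero observed cases for E/O,
thresholds outside a score range, non-positive creatinine/age.

## Known limitations

* The reconstructed point tables reproduce published score *ranges* and
  thresholds, not necessarily the original per-item points (which the
  source cites but does not reprint); diagnostics at a given threshold may
  therefore differ from the originals.  Tables are config-overridable.
* Worked examples that are not arithmetically consistent with the printed
  coefficients (a minority of the published example cells) are not
  reproduced and are not asserted.
* The FAS equation is implemented for adults only; cystatin-C equations
  and KDIGO staging beyond the eGFR < 60 dichotomy are out of scope.
* Coefficient refitting is out of scope by design: the package validates
  published models and recalibrates intercepts only.
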
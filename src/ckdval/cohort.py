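"""Seeded synthetic cohorts emulating a population-based validation study.

The generator reproduces the marginal structure of a German general-
population cohort aged 45–75 (the setting in which the six CKD risk models
were externally validated): age from a truncated normal, sex, and nine
comorbidity/history flags whose prevalences are calibrated exactly to the
published cohort table, with age-, sex- and frailty-dependent logistic
models inducing realistic co-occurrence.  Renal function is generated as a
latent log-eGFR (baseline minus age decline minus comorbidity effects plus
lognormal noise), translated into a serum creatinine by exact inversion of
the chosen eGFR equation, so that the observed eGFR/CKD outcome recomputed
from creatinine reproduces the latent value to machine precision.

Two outcome mechanisms exist: ``from_renal`` (default; CKD derived from
creatinine via the eGFR equation, mirroring the real validation design) and
``from_model`` (outcome drawn as Bernoulli of a planted model's predicted
risk, enabling clean parameter-recovery and calibration experiments).

Only marginals and a simple dependence structure are emulated; the cohorts
carry no geographic, socioeconomic or longitudinal structure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .models import ModelSpec, PersonProfile, derive_predictors, linear_predictor
from .renal import EgfrParams, egfr as egfr_forward, invert_egfr

__all__ = [
    "CohortConfig",
    "PlantedModelConfig",
    "Cohort",
    "SchemaError",
    "COHORT_COLUMNS",
    "generate",
    "generate_planted",
    "write_cohort",
    "read_cohort",
]

#: Canonical CSV schema, one row per participant.  ``serum_creatinine`` and
#: ``acr`` may be absent (records are then incomplete at the renal /
#: albuminuria stage).
COHORT_COLUMNS = (
    "id", "age", "sex", "sbp", "dbp", "antihypertensive_med",
    "diabetes_selfreport", "antidiabetic_med", "hemoglobin", "ihd", "stroke",
    "heart_failure", "pvd", "proteinuria_selfreport", "kidney_stones",
    "serum_creatinine", "acr",
)
_OPTIONAL_COLUMNS = frozenset({"serum_creatinine", "acr"})
_FLAG_COLUMNS = (
    "antihypertensive_med", "diabetes_selfreport", "antidiabetic_med", "ihd",
    "stroke", "heart_failure", "pvd", "proteinuria_selfreport",
    "kidney_stones",
)

# published cohort marginals the generator targets
_DEFAULT_MARGINALS: dict[str, float] = {
    "female": 0.505,
    "hypertension": 0.592,
    "diabetes": 0.079,
    "ihd_or_stroke": 0.069,
    "heart_failure": 0.035,
    "pvd": 0.023,
    "proteinuria": 0.017,
    "anemia": 0.021,
    "kidney_stones": 0.120,
}

# (age slope per SD of age, female effect, frailty loading) on the logit scale
_DEFAULT_ASSOCIATIONS: dict[str, tuple[float, float, float]] = {
    "hypertension": (0.55, 0.00, 0.45),
    "diabetes": (0.40, -0.10, 0.45),
    "ihd_or_stroke": (0.55, -0.55, 0.60),
    "heart_failure": (0.50, -0.10, 0.60),
    "pvd": (0.45, -0.30, 0.50),
    "proteinuria": (0.25, 0.00, 0.50),
    "anemia": (0.10, 0.90, 0.35),
    "kidney_stones": (0.05, -0.45, 0.15),
}

# multiplicative effects on latent eGFR (log scale)
_DEFAULT_RENAL_EFFECTS: dict[str, float] = {
    "hypertension": -0.040,
    "diabetes": -0.090,
    "ihd_or_stroke": -0.055,
    "heart_failure": -0.130,
    "pvd": -0.070,
    "anemia": -0.160,
    "proteinuria": -0.220,
    "kidney_stones": -0.015,
}


class SchemaError(ValueError):
    """A cohort file does not conform to the canonical CSV schema."""


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; the defaults ARE the emulated study conditions."""

    n: int = 4185
    seed: int = 20220801
    marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS))
    age_mean: float = 59.6
    age_sd: float = 7.8
    age_range: tuple[float, float] = (45.0, 75.0)
    ckd_prevalence: float = 0.092
    egfr_params: EgfrParams = field(default_factory=EgfrParams)
    kidney_stone_missing_rate: float = 0.18
    associations: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ASSOCIATIONS))
    renal_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RENAL_EFFECTS))
    renal_age_slope: float = -0.0095  # per year, log-eGFR
    renal_frailty_effect: float = -0.050
    renal_noise_sd: float = 0.165  # lognormal sd of the eGFR noise

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        bad = {k: p for k, p in self.marginals.items() if not 0.0 < p < 1.0}
        if bad:
            raise ValueError(f"marginal targets must lie in (0,1): {bad}")
        if not 0.0 < self.ckd_prevalence < 1.0:
            raise ValueError("ckd_prevalence must lie in (0,1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age bounds must be ordered")
        if not 0.0 <= self.kidney_stone_missing_rate < 1.0:
            raise ValueError("kidney_stone_missing_rate must lie in [0,1)")

    def digest(self) -> str:
        doc = asdict(self)
        doc["marginals"] = dict(self.marginals)
        doc["associations"] = {k: list(v) for k, v in self.associations.items()}
        doc["renal_effects"] = dict(self.renal_effects)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PlantedModelConfig:
    """A risk model planted as the outcome-generating mechanism."""

    spec: ModelSpec
    intercept_override: Optional[float] = None
    mechanism: str = "from_model"

    def __post_init__(self) -> None:
        if self.mechanism not in ("from_model", "from_renal"):
            raise ValueError("mechanism must be 'from_model' or 'from_renal'")


@dataclass
class Cohort:
    """Participant table plus provenance (synthetic seed/config or file path)."""

    data: pd.DataFrame
    provenance: dict

    @property
    def n(self) -> int:
        return len(self.data)

    def profiles(self) -> list[PersonProfile]:
        """Row-wise conversion to :class:`PersonProfile` (NaN → missing)."""

        def opt(v):
            return None if pd.isna(v) else float(v)

        def optflag(v):
            return None if pd.isna(v) else bool(int(v))

        out = []
        for row in self.data.itertuples(index=False):
            out.append(PersonProfile(
                age=float(row.age),
                sex=str(row.sex),
                systolic_bp=opt(row.sbp),
                diastolic_bp=opt(row.dbp),
                antihypertensive_med=optflag(row.antihypertensive_med),
                diabetes_selfreport=optflag(row.diabetes_selfreport),
                antidiabetic_med=optflag(row.antidiabetic_med),
                hemoglobin=opt(row.hemoglobin),
                ihd_history=optflag(row.ihd),
                stroke_history=optflag(row.stroke),
                heart_failure_history=optflag(row.heart_failure),
                pvd_history=optflag(row.pvd),
                proteinuria_selfreport=optflag(row.proteinuria_selfreport),
                acr=opt(row.acr) if hasattr(row, "acr") else None,
                kidney_stones_history=optflag(row.kidney_stones),
                serum_creatinine=(opt(row.serum_creatinine)
                                  if hasattr(row, "serum_creatinine") else None),
            ))
        return out


def _calibrated_flag(rng: np.random.Generator, target: float,
                     linear: np.ndarray, label: str) -> np.ndarray:
    """Draw a Bernoulli flag whose expected marginal equals ``target``.

    The intercept of ``expit(a + linear)`` is solved so the mean probability
    over the realized covariates matches the target exactly; the drawn
    marginal then deviates only by binomial noise √(p(1−p)/n).
    """

    def gap(a: float) -> float:
        return float(expit(a + linear).mean() - target)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"marginal calibration failed for {label!r}: target {target} "
            f"unreachable with gap({lo})={gap(lo):.3g}, gap({hi})={gap(hi):.3g}")
    a = brentq(gap, lo, hi, xtol=1e-12)
    return rng.random(linear.size) < expit(a + linear)


def generate(config: CohortConfig = CohortConfig()) -> Cohort:
    """Generate a seeded cohort matching the configured marginals."""
    rng = np.random.default_rng(config.seed)
    n = config.n

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                        size=n, random_state=rng)
    female = rng.random(n) < config.marginals["female"]
    frailty = rng.standard_normal(n)
    age_z = (age - config.age_mean) / config.age_sd

    flags: dict[str, np.ndarray] = {}
    for name in ("hypertension", "diabetes", "ihd_or_stroke", "heart_failure",
                 "pvd", "proteinuria", "anemia", "kidney_stones"):
        slope, fem_eff, load = config.associations[name]
        linear = slope * age_z + fem_eff * female + load * frailty
        flags[name] = _calibrated_flag(rng, config.marginals[name], linear, name)

    # split the combined cardiovascular flag into IHD / stroke components
    cvd = flags["ihd_or_stroke"]
    u = rng.random(n)
    ihd = cvd & (u < 0.75)          # IHD alone or with stroke
    stroke = cvd & (u >= 0.65)      # stroke alone or with IHD (10% overlap)

    # blood pressure and medication consistent with the hypertension flag
    ht = flags["hypertension"]
    on_med = ht & (rng.random(n) < 0.55)
    uncontrolled = ht & ~on_med
    sbp = np.where(
        uncontrolled,
        truncnorm.rvs(0.0, 4.0, loc=140.0, scale=12.0, size=n, random_state=rng),
        truncnorm.rvs(-6.0, (139.9 - 125.0) / 10.0, loc=125.0, scale=10.0,
                      size=n, random_state=rng))
    dbp = np.where(
        uncontrolled & (rng.random(n) < 0.5),
        truncnorm.rvs(0.0, 4.0, loc=90.0, scale=8.0, size=n, random_state=rng),
        truncnorm.rvs(-5.0, (89.9 - 78.0) / 8.0, loc=78.0, scale=8.0,
                      size=n, random_state=rng))

    dm = flags["diabetes"]
    antidiabetic = dm & (rng.random(n) < 0.70)

    # hemoglobin consistent with the anemia flag (cohort definition Hb < 12)
    anem = flags["anemia"]
    hb_low = truncnorm.rvs((8.0 - 11.2) / 0.8, (11.99 - 11.2) / 0.8,
                           loc=11.2, scale=0.8, size=n, random_state=rng)
    hb_f = truncnorm.rvs((12.01 - 13.6) / 1.0, (17.5 - 13.6) / 1.0,
                         loc=13.6, scale=1.0, size=n, random_state=rng)
    hb_m = truncnorm.rvs((12.01 - 15.0) / 1.0, (19.0 - 15.0) / 1.0,
                         loc=15.0, scale=1.0, size=n, random_state=rng)
    hemoglobin = np.where(anem, hb_low, np.where(female, hb_f, hb_m))

    # ACR consistent with self-reported proteinuria (ACR >= 30 iff positive)
    prot = flags["proteinuria"]
    acr = np.where(prot,
                   30.0 * np.exp(rng.exponential(0.8, size=n)),
                   30.0 * rng.beta(1.5, 6.0, size=n))

    stones = flags["kidney_stones"].astype(float)
    stones_missing = rng.random(n) < config.kidney_stone_missing_rate
    stones[stones_missing] = np.nan

    # latent renal function on the log scale
    s = config.renal_age_slope * (age - config.age_mean)
    for name, eff in config.renal_effects.items():
        s = s + eff * flags[name]
    s = s + config.renal_frailty_effect * frailty
    s = s + config.renal_noise_sd * rng.standard_normal(n)
    # baseline calibrated so the sample CKD prevalence hits the target
    log_g0 = float(np.log(60.0) - np.quantile(s, config.ckd_prevalence))
    egfr_latent = np.clip(np.exp(log_g0 + s), 8.0, 170.0)

    sex = np.where(female, "female", "male")
    creatinine = invert_egfr(egfr_latent, age, sex, config.egfr_params)
    egfr_obs = egfr_forward(creatinine, age, sex, config.egfr_params)
    ckd = egfr_obs < 60.0

    data = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": age,
        "sex": sex,
        "sbp": sbp,
        "dbp": dbp,
        "antihypertensive_med": on_med.astype(int),
        "diabetes_selfreport": dm.astype(int),
        "antidiabetic_med": antidiabetic.astype(int),
        "hemoglobin": hemoglobin,
        "ihd": ihd.astype(int),
        "stroke": stroke.astype(int),
        "heart_failure": flags["heart_failure"].astype(int),
        "pvd": flags["pvd"].astype(int),
        "proteinuria_selfreport": prot.astype(int),
        "kidney_stones": stones,
        "serum_creatinine": creatinine,
        "acr": acr,
        "egfr": egfr_obs,
        "ckd": ckd.astype(int),
    })
    provenance = {
        "source": "synthetic",
        "mechanism": "from_renal",
        "seed": int(config.seed),
        "n": int(n),
        "egfr_equation": config.egfr_params.equation,
        "config_digest": config.digest(),
    }
    return Cohort(data=data, provenance=provenance)


def generate_planted(config: CohortConfig,
                     planted: PlantedModelConfig) -> Cohort:
    """Generate a cohort whose outcome is drawn from a planted risk model.

    With mechanism ``from_model`` the CKD outcome is Bernoulli(inverse-logit
    of the planted linear predictor); the renal columns are still generated
    but no longer determine the outcome.  When the planted model requires
    the kidney-stones predictor, stone missingness is switched off so every
    record has a defined planted risk.
    """
    if planted.mechanism == "from_renal":
        return generate(config)
    from dataclasses import replace as _replace
    if ("kidney_stones" in planted.spec.requires
            and config.kidney_stone_missing_rate > 0):
        config = _replace(config, kidney_stone_missing_rate=0.0)
    cohort = generate(config)
    spec = planted.spec
    if planted.intercept_override is not None:
        spec = _replace(spec, intercept=planted.intercept_override)
    lps = np.array([linear_predictor(spec, derive_predictors(p, spec))
                    for p in cohort.profiles()])
    risk = expit(lps)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    y = rng.random(cohort.n) < risk
    cohort.data["true_risk"] = risk
    cohort.data["ckd"] = y.astype(int)
    cohort.provenance.update({
        "mechanism": "from_model",
        "planted_model": spec.name,
        "planted_intercept": float(spec.intercept),
    })
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV with a provenance header (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ckdval cohort v1\n")
        fh.write("# provenance: "
                 + json.dumps(cohort.provenance, sort_keys=True) + "\n")
        cohort.data.to_csv(fh, index=False, lineterminator="\n")


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, validating the canonical schema.

    Missing *optional* columns (creatinine, ACR) are tolerated — affected
    pipeline stages later report incomplete records; any other missing or
    renamed schema column raises :class:`SchemaError` listing the offenders.
    """
    provenance: dict = {"source": str(path)}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# provenance:"):
                provenance.update(json.loads(line.split(":", 1)[1]))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh)
    required = [c for c in COHORT_COLUMNS if c not in _OPTIONAL_COLUMNS]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise SchemaError(f"cohort file {path} lacks required column(s): "
                          f"{', '.join(missing)}")
    sex = data["sex"].astype(str).str.lower().map(
        {"f": "female", "female": "female", "w": "female",
         "m": "male", "male": "male"})
    if sex.isna().any():
        bad = sorted(data.loc[sex.isna(), "sex"].astype(str).unique())
        raise SchemaError(f"malformed sex code(s) in {path}: {bad}")
    data = data.assign(sex=sex)
    return Cohort(data=data, provenance=provenance)
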
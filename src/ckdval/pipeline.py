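"""End-to-end validation runs: complete-case filtering, predictor derivation,
outcome construction, per-model metrics and threshold diagnostics.

The orchestration mirrors an external-validation analysis: the binary CKD
outcome is recomputed from serum creatinine with the configured eGFR
equation (the equation is a first-class sensitivity axis — it changes the
outcome but never the models' predictions, which use no laboratory values),
complete-case subsets are formed *per model* from each model's required
predictors (so a model using a sparsely ascertained item, such as kidney
stones, is validated on the subsample carrying that item), and every model
receives a full metrics block plus — for models with a published point
score — threshold diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .cohort import Cohort
from .metrics import (SingleClassError, brier, c_statistic, calibration_table,
                      mape, recalibrate_intercept, scaled_brier, tjur)
from .models import (IncompleteRecordError, builtin_models,
                     builtin_score_tables, derive_predictors, predict_risk,
                     score as score_fn)
from .renal import EgfrParams, egfr as egfr_forward
from .thresholds import diagnostic_table, youden_optimal

__all__ = ["RunConfig", "ValidationReport", "run_validation"]

log = logging.getLogger("ckdval")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one validation run."""

    egfr_params: EgfrParams = field(default_factory=EgfrParams)
    models: Optional[Sequence[str]] = None  # None = all registry models
    thresholds: Optional[Mapping[str, Sequence[int]]] = None
    n_boot: int = 1000
    seed: int = 0
    auc_ci_method: str = "hanley-mcneil"
    calibration_bins: int = 10
    thakkinstian_intercept: str | float = "table3"
    recalibrate: bool = True

    def digest(self) -> str:
        doc = {
            "egfr": [self.egfr_params.equation, self.egfr_params.mdrd_constant,
                     self.egfr_params.race_adjustment],
            "models": list(self.models) if self.models else None,
            "thresholds": ({k: list(v) for k, v in self.thresholds.items()}
                           if self.thresholds else None),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "auc_ci": self.auc_ci_method,
            "bins": self.calibration_bins,
            "thak": self.thakkinstian_intercept,
            "recal": self.recalibrate,
        }
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    """Per-model metric blocks and threshold diagnostics plus provenance."""

    models: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "models": self.models}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          allow_nan=True)

    def performance_frame(self):
        """Table of the headline per-model metrics (one row per model)."""
        import pandas as pd
        rows = []
        for name, block in self.models.items():
            if block.get("skipped"):
                continue
            m = block["metrics"]
            rows.append({
                "model": name,
                "n": block["n_used"],
                "mean_prediction": m["mean_prediction"],
                "sd_prediction": m["sd_prediction"],
                "c_statistic": m["c_statistic"]["value"] if m["c_statistic"] else None,
                "c_ci_low": m["c_statistic"]["ci_low"] if m["c_statistic"] else None,
                "c_ci_high": m["c_statistic"]["ci_high"] if m["c_statistic"] else None,
                "tjur": m["tjur"]["value"] if m["tjur"] else None,
                "mape": m["mape"],
                "brier": m["brier"],
                "scaled_brier": m["scaled_brier"],
            })
        return pd.DataFrame(rows)

    def diagnostics_frame(self):
        """Long table of threshold diagnostics across models."""
        import pandas as pd
        rows = []
        for name, block in self.models.items():
            for r in block.get("thresholds") or []:
                rows.append({"model": name, **r})
        return pd.DataFrame(rows)


def _metric_dict(est) -> dict:
    return {"value": est.value, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "method": est.method}


def _outcome_vector(cohort: Cohort, params: EgfrParams) -> np.ndarray:
    """CKD outcome per record: NaN where not derivable."""
    df = cohort.data
    if (cohort.provenance.get("mechanism") == "from_model"
            and "ckd" in df.columns):
        return df["ckd"].to_numpy(dtype=float)
    if "serum_creatinine" in df.columns and df["serum_creatinine"].notna().any():
        out = np.full(len(df), np.nan)
        m = df["serum_creatinine"].notna().to_numpy()
        g = egfr_forward(df.loc[m, "serum_creatinine"].to_numpy(),
                         df.loc[m, "age"].to_numpy(),
                         df.loc[m, "sex"].to_numpy(), params)
        out[m] = (np.asarray(g) < 60.0).astype(float)
        return out
    if "ckd" in df.columns:
        return df["ckd"].to_numpy(dtype=float)
    raise ValueError("cohort has neither serum creatinine nor a ckd column; "
                     "outcome not derivable")


def run_validation(cohort: Cohort, config: RunConfig = RunConfig()
                   ) -> ValidationReport:
    """Validate the configured models on a cohort and assemble the report."""
    if cohort.n == 0:
        raise ValueError("empty cohort")
    registry = builtin_models(config.thakkinstian_intercept)
    tables = builtin_score_tables()
    names = list(config.models) if config.models else list(registry)
    unknown = [m for m in names if m not in registry]
    if unknown:
        raise KeyError(f"unknown model(s): {unknown}; "
                       f"known: {sorted(registry)}")

    y_all = _outcome_vector(cohort, config.egfr_params)
    profiles = cohort.profiles()

    blocks: dict[str, dict] = {}
    for name in names:
        spec = registry[name]
        table = tables.get(name)
        risks, scores, ys = [], [], []
        n_excluded_pred = 0
        n_excluded_outcome = 0
        for prof, yv in zip(profiles, y_all):
            if np.isnan(yv):
                n_excluded_outcome += 1
                continue
            try:
                d = derive_predictors(prof, spec)
            except IncompleteRecordError:
                n_excluded_pred += 1
                continue
            risks.append(predict_risk(spec, d))
            if table is not None:
                scores.append(score_fn(table, d))
            ys.append(yv)
        n_used = len(ys)
        log.info("model %s: %d complete cases (%d excluded: %d missing "
                 "predictors, %d missing outcome)", name, n_used,
                 cohort.n - n_used, n_excluded_pred, n_excluded_outcome)
        if n_used == 0:
            log.warning("model %s skipped: no complete cases", name)
            blocks[name] = {"skipped": True,
                            "skip_reason": "no complete cases",
                            "n_used": 0,
                            "n_excluded": cohort.n}
            continue

        pred = np.asarray(risks)
        y = np.asarray(ys)
        block: dict = {
            "skipped": False,
            "n_used": n_used,
            "n_excluded": cohort.n - n_used,
            "n_excluded_missing_predictors": n_excluded_pred,
            "n_excluded_missing_outcome": n_excluded_outcome,
        }
        metrics: dict = {
            "mean_prediction": float(pred.mean()),
            "sd_prediction": float(pred.std(ddof=1)) if n_used > 1 else 0.0,
            "mape": mape(pred, y),
            "brier": brier(pred, y),
        }
        single_class = y.min() == y.max()
        if single_class:
            metrics.update({
                "c_statistic": None, "tjur": None, "scaled_brier": None,
                "discrimination_undefined": True,
            })
            block["warnings"] = ["single-class outcome: discrimination "
                                 "metrics undefined"]
        else:
            metrics["c_statistic"] = _metric_dict(c_statistic(
                pred, y, ci_method=config.auc_ci_method,
                n_boot=config.n_boot, seed=config.seed))
            metrics["tjur"] = _metric_dict(tjur(
                pred, y, n_boot=config.n_boot, seed=config.seed))
            metrics["scaled_brier"] = scaled_brier(pred, y)
            metrics["discrimination_undefined"] = False
        if n_used < 30:
            block.setdefault("warnings", []).append(
                "fewer than 30 complete cases: bootstrap CIs unstable")
        if n_used >= config.calibration_bins:
            cal = calibration_table(pred, y, n_bins=config.calibration_bins)
            block["calibration"] = cal.to_dict(orient="records")
        else:
            block["calibration"] = None
        if config.recalibrate and not single_class:
            derived = []
            for prof, yv in zip(profiles, y_all):
                if np.isnan(yv):
                    continue
                try:
                    derived.append(derive_predictors(prof, spec))
                except IncompleteRecordError:
                    continue
            recal = recalibrate_intercept(spec, derived, y)
            metrics["recalibrated_intercept"] = recal.intercept
            metrics["intercept_shift"] = recal.intercept - spec.intercept
        block["metrics"] = metrics

        if table is not None and not single_class:
            sc = np.asarray(scores, dtype=float)
            thr = (list(config.thresholds[name])
                   if config.thresholds and name in config.thresholds
                   else list(table.published_thresholds))
            diag = diagnostic_table(sc, y, thr, model_name=name,
                                    egfr_equation=config.egfr_params.equation,
                                    n_boot=config.n_boot, seed=config.seed)
            block["thresholds"] = diag.to_frame().to_dict(orient="records")
            block["youden_optimal_threshold"] = youden_optimal(sc, y)
        else:
            block["thresholds"] = None
            block["youden_optimal_threshold"] = None
            if table is None:
                block["threshold_skip_reason"] = ("no published scoring rule "
                                                  "for this model")
        blocks[name] = block

    provenance = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "egfr_equation": config.egfr_params.equation,
        "cohort": cohort.provenance,
        "n_records": cohort.n,
    }
    return ValidationReport(models=blocks, provenance=provenance)
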
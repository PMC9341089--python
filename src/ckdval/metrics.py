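"""Discrimination, calibration and overall-performance measures.

Metrics for validating predicted probabilities against a binary outcome:

* c-statistic (AUC) with Hanley–McNeil, DeLong or bootstrap confidence
  intervals,
* Tjur's coefficient of discrimination (difference of class means of the
  predicted probability), bootstrap CI,
* MAPE (mean absolute prediction error against the 0/1 outcome),
* Brier score and the scaled Brier score,
* decile-based calibration tables (plot-ready observed-vs-expected data),
* intercept-only recalibration of a logistic model to a validation cohort.

The scaled Brier score is exposed under two conventions: convention "A"
(default) is 1 − Brier/denominator, the R²-like form with value 1 for
perfect predictions and 0 for a constant prediction equal to the baseline;
convention "B" is the raw ratio Brier/denominator.  The denominator is
p̄(1 − p̄) with p̄ either the outcome prevalence (default: the only choice
under which convention A has the 0 baseline) or the mean prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm, rankdata

from .models import DerivedPredictors, ModelSpec, linear_predictor

__all__ = [
    "MetricEstimate",
    "SingleClassError",
    "c_statistic",
    "tjur",
    "mape",
    "brier",
    "scaled_brier",
    "calibration_table",
    "recalibrate_intercept",
]


class SingleClassError(ValueError):
    """Discrimination is undefined when only one outcome class is present."""


@dataclass(frozen=True)
class MetricEstimate:
    value: float
    ci_low: float
    ci_high: float
    method: str
    n_cases: int
    n_noncases: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


def _validate(pred, y, require_both_classes: bool = True):
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape or pred.ndim != 1:
        raise ValueError("pred and y must be 1-d arrays of equal length")
    if pred.size == 0:
        raise ValueError("empty input")
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be 0/1")
    n1 = int(y.sum())
    n0 = y.size - n1
    if require_both_classes and (n1 == 0 or n0 == 0):
        raise SingleClassError(
            "both outcome classes must be present (discrimination undefined)")
    return pred, y.astype(bool), n1, n0


def _auc_point(pred: np.ndarray, y: np.ndarray) -> float:
    # Mann-Whitney form via midranks; ties count 1/2 by construction.
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(pred)
    return (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(pred: np.ndarray, y: np.ndarray) -> float:
    # Structural components from midranks (Sun & Xu formulation).
    x, ycls = pred[y], pred[~y]
    m, n = x.size, ycls.size
    rx = rankdata(np.concatenate([x, ycls]))[:m]
    ry = rankdata(np.concatenate([x, ycls]))[m:]
    v10 = (rx - rankdata(x)) / n
    v01 = 1.0 - (ry - rankdata(ycls)) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(np.sqrt(max(var, 0.0)))


def _bootstrap_ci(stat_fn, pred, y, n_boot, seed, alpha):
    if n_boot <= 0:
        return -np.inf, np.inf
    rng = np.random.default_rng(seed)
    n = pred.size
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue  # resample lost a class; drop it
        vals.append(stat_fn(pred[idx], yb))
    if len(vals) < max(10, n_boot // 10):
        warnings.warn("bootstrap unstable: most resamples were single-class",
                      stacklevel=3)
    if not vals:
        return -np.inf, np.inf
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def c_statistic(pred, y, ci_method: str = "hanley-mcneil",
                n_boot: int = 1000, seed: Optional[int] = 0,
                alpha: float = 0.05) -> MetricEstimate:
    """Area under the ROC curve with a 95% (by default) confidence interval.

    Equals the proportion of case/non-case pairs in which the case carries
    the higher prediction, ties counted one half.  ``ci_method`` is one of
    ``"hanley-mcneil"`` (classical analytic SE, default), ``"delong"`` or
    ``"bootstrap"``.
    """
    pred, yb, n1, n0 = _validate(pred, y)
    auc = _auc_point(pred, yb)
    if ci_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, n1, n0)
        z = norm.ppf(1 - alpha / 2)
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "delong":
        se = _delong_se(pred, yb)
        z = norm.ppf(1 - alpha / 2)
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(_auc_point, pred, yb, n_boot, seed, alpha)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = max(0.0, min(lo, auc)), min(1.0, max(hi, auc))
    return MetricEstimate(float(auc), lo, hi, f"auc/{ci_method}", n1, n0)


def _tjur_point(pred: np.ndarray, yb: np.ndarray) -> float:
    return float(pred[yb].mean() - pred[~yb].mean())


def tjur(pred, y, n_boot: int = 1000, seed: Optional[int] = 0,
         alpha: float = 0.05) -> MetricEstimate:
    """Tjur coefficient: mean(pred | case) − mean(pred | non-case), in [−1, 1]."""
    pred, yb, n1, n0 = _validate(pred, y)
    point = _tjur_point(pred, yb)
    lo, hi = _bootstrap_ci(_tjur_point, pred, yb, n_boot, seed, alpha)
    lo, hi = min(lo, point), max(hi, point)
    return MetricEstimate(point, lo, hi, "tjur/bootstrap", n1, n0)


def mape(pred, y) -> float:
    """Mean absolute deviation between prediction and the 0/1 outcome."""
    pred, yb, _, _ = _validate(pred, y, require_both_classes=False)
    return float(np.abs(yb.astype(float) - pred).mean())


def brier(pred, y) -> float:
    """Mean squared deviation between prediction and the 0/1 outcome."""
    pred, yb, _, _ = _validate(pred, y, require_both_classes=False)
    return float(((yb.astype(float) - pred) ** 2).mean())


def scaled_brier(pred, y, convention: str = "A",
                 denominator: str = "outcome_mean") -> float:
    """Scaled Brier score.

    ``convention="A"`` (default): 1 − Brier/(p̄(1 − p̄)), interpretable like
    an R²; ``"B"``: the raw ratio Brier/(p̄(1 − p̄)).  ``denominator``
    chooses p̄ as the outcome prevalence (``"outcome_mean"``, default) or
    the mean prediction (``"prediction_mean"``).
    """
    pred, yb, _, _ = _validate(pred, y, require_both_classes=False)
    if denominator == "outcome_mean":
        p = float(yb.mean())
    elif denominator == "prediction_mean":
        p = float(pred.mean())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    denom = p * (1.0 - p)
    if denom <= 0.0:
        raise ValueError("degenerate denominator: mean is 0 or 1")
    ratio = brier(pred, yb.astype(float)) / denom
    if convention == "A":
        return 1.0 - ratio
    if convention == "B":
        return ratio
    raise ValueError(f"unknown convention {convention!r}")


def calibration_table(pred, y, n_bins: int = 10) -> pd.DataFrame:
    """Observed vs. expected event proportions in risk-decile bins.

    Bins predictions by quantiles of predicted risk (default deciles) and
    reports, per bin, the count, mean predicted probability and observed
    event proportion — the data behind a calibration plot.  When the
    predictions have too few distinct values for the requested number of
    bins, coincident bin edges are merged with a warning.
    """
    pred, yb, _, _ = _validate(pred, y, require_both_classes=False)
    if pred.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} observations")
    edges = np.quantile(pred, np.linspace(0, 1, n_bins + 1))
    uniq = np.unique(edges)
    if uniq.size < edges.size:
        warnings.warn(
            f"merged {edges.size - uniq.size} calibration bins with "
            "coincident quantile edges (few distinct predictions)",
            stacklevel=2)
    edges = uniq
    if edges.size < 2:  # constant predictions: one bin holding everything
        idx = np.zeros(pred.size, dtype=int)
        n_eff = 1
    else:
        idx = np.clip(np.searchsorted(edges, pred, side="right") - 1,
                      0, edges.size - 2)
        n_eff = edges.size - 1
    rows = []
    for b in range(n_eff):
        m = idx == b
        if not m.any():
            continue
        rows.append({
            "bin": b,
            "n": int(m.sum()),
            "mean_predicted": float(pred[m].mean()),
            "observed_proportion": float(yb[m].mean()),
        })
    table = pd.DataFrame(rows)
    table.attrs["binning"] = f"quantile/{n_bins}"
    return table


def recalibrate_intercept(spec: ModelSpec,
                          derived: Sequence[DerivedPredictors],
                          y, tol: float = 1e-10) -> ModelSpec:
    """Shift the intercept so mean predicted risk equals observed prevalence.

    All slope coefficients are untouched (intercept-only recalibration, the
    standard first remedy for a model that is mis-calibrated in the large).
    Solved numerically; raises on non-convergence with diagnostics.
    """
    _, yb, n1, n0 = _validate(np.zeros(len(y)), y)
    if len(derived) != yb.size:
        raise ValueError("derived and y must have equal length")
    offsets = np.array([linear_predictor(spec, d) - spec.intercept
                        for d in derived])
    prevalence = yb.mean()

    def gap(delta: float) -> float:
        return float(expit(spec.intercept + delta + offsets).mean() - prevalence)

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - requires prevalence 0/1
        raise RuntimeError(
            f"intercept recalibration failed to bracket a root: "
            f"prevalence={prevalence:.4f}, gap({lo})={gap(lo):.3g}, "
            f"gap({hi})={gap(hi):.3g}")
    delta = brentq(gap, lo, hi, xtol=tol)
    new_spec = replace(spec, intercept=spec.intercept + delta)
    if abs(gap(delta)) > 1e-8:  # pragma: no cover
        raise RuntimeError(f"recalibration did not converge: residual {gap(delta)}")
    return new_spec
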
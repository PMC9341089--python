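"""Threshold diagnostics for the score versions of the risk models.

For a vector of integer scores (or, more generally, any real-valued risk
marker) against the binary CKD outcome, this module computes exact
count-based sensitivity, specificity and predictive values per threshold,
the Youden-optimal threshold, and the expected/observed case proportion
(E/O) with bootstrap confidence intervals.  A threshold classifies
screen-positive inclusively: score ≥ threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricEstimate, SingleClassError

__all__ = [
    "ThresholdRow",
    "DiagnosticTable",
    "diagnostic_table",
    "youden_optimal",
    "eo_proportion",
]


@dataclass(frozen=True)
class ThresholdRow:
    """One 2×2 table at a threshold with its derived diagnostics.

    ``ppv`` is ``None`` (flagged, not imputed) when no record is
    screen-positive; likewise ``npv`` when none is screen-negative.
    ``eo`` is the ratio of expected cases (screen-positives) to observed
    cases; > 1 indicates risk overestimation at that threshold.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    eo: float
    eo_ci: tuple[float, float]


@dataclass(frozen=True)
class DiagnosticTable:
    model_name: str
    egfr_equation: str
    prevalence: float
    rows: tuple[ThresholdRow, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "model": self.model_name,
                "threshold": r.threshold,
                "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "ppv": r.ppv, "npv": r.npv,
                "eo": r.eo, "eo_ci_low": r.eo_ci[0], "eo_ci_high": r.eo_ci[1],
            })
        return pd.DataFrame(recs)


def _validate_scores(scores, y):
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if scores.shape != y.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and y must be non-empty 1-d arrays of equal length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be 0/1")
    yb = y.astype(bool)
    if yb.all() or not yb.any():
        raise SingleClassError("both outcome classes must be present")
    return scores, yb


def _counts(scores: np.ndarray, yb: np.ndarray, threshold: float
            ) -> tuple[int, int, int, int]:
    pos = scores >= threshold
    tp = int(np.count_nonzero(pos & yb))
    fp = int(np.count_nonzero(pos & ~yb))
    fn = int(np.count_nonzero(~pos & yb))
    tn = int(np.count_nonzero(~pos & ~yb))
    return tp, fp, tn, fn


def diagnostic_table(scores, y, thresholds: Sequence[float],
                     model_name: str = "", egfr_equation: str = "",
                     n_boot: int = 1000, seed: Optional[int] = 0
                     ) -> DiagnosticTable:
    """Exact per-threshold sensitivity/specificity/PPV/NPV and E/O + CI."""
    scores, yb = _validate_scores(scores, y)
    n1 = int(yb.sum())
    rows = []
    for t in thresholds:
        tp, fp, tn, fn = _counts(scores, yb, t)
        eo_est = eo_proportion(scores, yb, t, n_boot=n_boot, seed=seed)
        rows.append(ThresholdRow(
            threshold=t, tp=tp, fp=fp, tn=tn, fn=fn,
            sensitivity=tp / n1,
            specificity=tn / (yb.size - n1),
            ppv=tp / (tp + fp) if tp + fp > 0 else None,
            npv=tn / (tn + fn) if tn + fn > 0 else None,
            eo=eo_est.value,
            eo_ci=(eo_est.ci_low, eo_est.ci_high),
        ))
    return DiagnosticTable(
        model_name=model_name, egfr_equation=egfr_equation,
        prevalence=n1 / yb.size, rows=tuple(rows))


def youden_optimal(scores, y):
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidates are the distinct observed score values; ties are broken
    toward the lowest threshold.  Returns an ``int`` when all scores are
    integral.
    """
    scores, yb = _validate_scores(scores, y)
    n1 = int(yb.sum())
    n0 = yb.size - n1
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):  # ascending, so first max wins the tie-break
        tp, fp, tn, fn = _counts(scores, yb, t)
        j = tp / n1 + tn / n0 - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    if float(best_t).is_integer():
        return int(best_t)
    return float(best_t)


def eo_proportion(scores, y, threshold: float, n_boot: int = 1000,
                  seed: Optional[int] = 0, alpha: float = 0.05
                  ) -> MetricEstimate:
    """Expected/observed case proportion at a threshold, with bootstrap CI.

    E = number screen-positive (score ≥ threshold), O = number of observed
    cases.  Identity: E/O = sens + (1 − spec)(1 − P)/P with P the prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float).astype(bool)
    if scores.shape != y.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and y must be non-empty 1-d arrays of equal length")
    n1 = int(y.sum())
    if n1 == 0:
        raise ValueError("E/O undefined with zero observed cases")
    point = float(np.count_nonzero(scores >= threshold) / n1)
    rng = np.random.default_rng(seed)
    n = scores.size
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        o = int(y[idx].sum())
        if o == 0:
            continue
        vals.append(np.count_nonzero(scores[idx] >= threshold) / o)
    if vals:
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(float(lo), point), max(float(hi), point)
    else:
        lo, hi = point, point
    return MetricEstimate(point, lo, hi, "eo/bootstrap", n1, n - n1)
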
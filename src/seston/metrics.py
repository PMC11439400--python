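"""Evaluation statistics for the two-stage turbidity estimator.

Covers the classification side (confusion matrices, exact and within-k
class accuracy) and the regression side (R², RMSE, RRMSE) plus the two
turbidity-banded coverage statements that summarize practical accuracy:
the fraction of low-turbidity predictions (below 2.5 FNU) within an
absolute half-width of truth, and the fraction of higher-turbidity
predictions within a relative half-width. RRMSE (equivalently, relative
standard deviation) is 100·RMSE/mean(observed): a scale-free error
measure suited to a quantity whose practical tolerance scales with its
magnitude.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

logger = logging.getLogger(__name__)


def confusion(true_classes, predicted_classes, n_classes: int = 11):
    """Count and row-normalized confusion matrices (true x predicted)."""
    t = np.asarray(true_classes, dtype=int)
    p = np.asarray(predicted_classes, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != p.shape:
        raise ValueError("true and predicted lengths differ")
    if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError(f"class index out of range [0, {n_classes})")
    counts = _sk_confusion(t, p, labels=np.arange(n_classes))
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, 0.0)
    return counts, normalized


def within_k_accuracy(confusion_counts, k: int) -> float:
    """Fraction of predictions with |true − predicted| ≤ k class indices."""
    m = np.asarray(confusion_counts)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if k < 0:
        raise ValueError("k must be >= 0")
    n = m.shape[0]
    i, j = np.indices((n, n))
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(m[np.abs(i - j) <= k].sum() / total)


def regression_metrics(y_true, y_pred) -> dict:
    """R², RMSE (FNU) and RRMSE (%) of continuous predictions.

    ``rrmse = 100 * rmse / mean(y_true)``; undefined (NaN, with a
    warning) when the observed mean is zero. The adjusted R² uses
    df_model = 11, the confidence-regression's model degrees of
    freedom.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    resid = yt - yp
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    n = yt.size
    df_model = 11
    adj_r2 = (
        1.0 - (1.0 - r2) * (n - 1) / (n - df_model - 1) if n > df_model + 1 else float("nan")
    )
    mean_y = float(yt.mean())
    if mean_y == 0.0:
        logger.warning("mean of observed values is zero; RRMSE undefined")
        rrmse = float("nan")
    else:
        rrmse = 100.0 * rmse / mean_y
    return {"r2": r2, "adj_r2": adj_r2, "rmse": rmse, "rrmse": rrmse}


def banded_coverage(
    y_true,
    y_pred,
    split: float = 2.5,
    abs_halfwidth: float = 0.7,
    rel_halfwidth: float = 0.33,
) -> tuple[float, float]:
    """Coverage of absolute/relative error bands below and above a split.

    Low band: among pairs with ``y_true < split``, the fraction with
    ``|y_pred − y_true| ≤ abs_halfwidth``. High band: among pairs with
    ``y_true ≥ split``, the fraction with
    ``|y_pred − y_true| ≤ rel_halfwidth · y_true``. An empty band is
    reported as NaN.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    err = np.abs(yp - yt)
    low = yt < split
    high = ~low
    low_cov = float(np.mean(err[low] <= abs_halfwidth)) if low.any() else float("nan")
    high_cov = (
        float(np.mean(err[high] <= rel_halfwidth * yt[high])) if high.any() else float("nan")
    )
    return low_cov, high_cov


@dataclass
class EvaluationReport:
    """Full performance report of one evaluation run."""

    confusion_counts: np.ndarray
    confusion_normalized: np.ndarray
    top1_accuracy: float
    within1_accuracy: float
    r2: float
    adj_r2: float
    rmse: float
    rrmse: float
    band_low_halfwidth: float = 0.7
    band_low_coverage: float = float("nan")
    band_high_relwidth: float = 0.33
    band_high_coverage: float = float("nan")
    n: int = 0

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "top1_accuracy": self.top1_accuracy,
            "within1_accuracy": self.within1_accuracy,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "rrmse": self.rrmse,
            "band_low_halfwidth": self.band_low_halfwidth,
            "band_low_coverage": self.band_low_coverage,
            "band_high_relwidth": self.band_high_relwidth,
            "band_high_coverage": self.band_high_coverage,
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        def fmt(x):
            return "n/a" if (isinstance(x, float) and math.isnan(x)) else f"{x:.3f}"

        return "\n".join(
            [
                f"Evaluation over {self.n} images",
                f"  top-1 class accuracy      {fmt(self.top1_accuracy)}",
                f"  within-1-class accuracy   {fmt(self.within1_accuracy)}",
                f"  R2 {fmt(self.r2)}   adj R2 {fmt(self.adj_r2)}",
                f"  RMSE {fmt(self.rmse)} FNU   RRMSE {fmt(self.rrmse)}%",
                f"  coverage < 2.5 FNU within +/-{self.band_low_halfwidth} FNU: "
                f"{fmt(self.band_low_coverage)}",
                f"  coverage >= 2.5 FNU within +/-{self.band_high_relwidth * 100:.0f}%: "
                f"{fmt(self.band_high_coverage)}",
            ]
        )

    def plot_confusion(self, ax=None, normalized: bool = True):
        """Heatmap of the confusion matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        m = self.confusion_normalized if normalized else self.confusion_counts
        im = ax.imshow(m, cmap="Blues")
        ax.set_xlabel("predicted class")
        ax.set_ylabel("true class")
        ax.figure.colorbar(im, ax=ax)
        return ax


def evaluate_predictions(
    true_classes,
    predicted_classes,
    y_true,
    y_pred,
    n_classes: int = 11,
) -> EvaluationReport:
    """Assemble the full report from class and continuous predictions."""
    counts, normalized = confusion(true_classes, predicted_classes, n_classes)
    reg = regression_metrics(y_true, y_pred)
    low_cov, high_cov = banded_coverage(y_true, y_pred)
    return EvaluationReport(
        confusion_counts=counts,
        confusion_normalized=normalized,
        top1_accuracy=within_k_accuracy(counts, 0),
        within1_accuracy=within_k_accuracy(counts, 1),
        r2=reg["r2"],
        adj_r2=reg["adj_r2"],
        rmse=reg["rmse"],
        rrmse=reg["rrmse"],
        band_low_coverage=low_cov,
        band_high_coverage=high_cov,
        n=len(np.asarray(true_classes)),
    )
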
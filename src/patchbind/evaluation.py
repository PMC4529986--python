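"""Binary-classification metrics for binding-residue prediction.

Predicted binding scores lie in [-1, 1]; a residue is called binding when its
score reaches the decision threshold theta (default 0).  From the confusion
counts the usual suite is derived: sensitivity (TPR), FPR, accuracy,
precision, specificity, F-score and MCC, plus the ROC curve and its
trapezoidal AUC from a full threshold sweep.  Zero-denominator conventions:
precision is 0 when nothing is predicted positive, and MCC is 0 when any
marginal is empty.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "roc_curve_points",
    "roc_auc",
    "metrics_from_counts",
]


@dataclass
class MetricsReport:
    """Confusion counts and the derived metric suite."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    fpr: float
    accuracy: float
    precision: float
    specificity: float
    f_score: float
    mcc: float
    auc: float = float("nan")
    roc_points: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_points"] = [[float(a), float(b)] for a, b in self.roc_points]
        return d


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray
                     ) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    return tp, tn, fp, fn


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Metric suite from raw confusion counts."""
    n = tp + tn + fp + fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n if n else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens, fpr=fpr,
                         accuracy=acc, precision=prec, specificity=spec,
                         f_score=f, mcc=mcc)


def compute_metrics(scores: np.ndarray, y_true: np.ndarray,
                    theta: float = 0.0) -> MetricsReport:
    """Thresholded metrics plus ROC/AUC for a score vector.

    AUC is omitted (NaN) when only one class is present in ``y_true``.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(bool)
    y_pred = scores >= theta
    report = metrics_from_counts(*confusion_counts(y_true, y_pred))
    if 0 < y_true.sum() < y_true.size:
        points, auc = roc_auc(scores, y_true)
        report.roc_points = points
        report.auc = auc
    return report


def roc_curve_points(scores: np.ndarray, y_true: np.ndarray
                     ) -> list[tuple[float, float]]:
    """(FPR, TPR) points from a sweep over the unique scores, ties grouped.

    Starts at (0, 0) — the threshold above every score — and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(bool)
    pos = int(y_true.sum())
    neg = int(y_true.size - pos)
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires both classes in the truth labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y_true[order]
    tps = np.cumsum(t)
    fps = np.cumsum(~t)
    # keep only the last index of each tie group
    last_of_group = np.r_[np.diff(s) != 0, True]
    tpr = tps[last_of_group] / pos
    fpr = fps[last_of_group] / neg
    pts = [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def roc_auc(scores: np.ndarray, y_true: np.ndarray
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC."""
    pts = roc_curve_points(scores, y_true)
    arr = np.asarray(pts)
    auc = float(np.trapezoid(arr[:, 1], arr[:, 0]))
    return pts, auc
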
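"""ROC curves, AUC and distance-to-corner probability-threshold optimization.

Probabilistic classifiers are usually cut at 0.5, but the cutoff that best
separates the classes can sit well away from 0.5, especially after pooling
several models.  Here the operating threshold is chosen as the ROC point
with minimum Euclidean distance

    d = sqrt((1 - TPR)^2 + FPR^2)

to the perfect-classification corner (FPR=0, TPR=1); class calls are then
``active iff p >= threshold`` (inclusive, so the lowest-probability cutoff
reproduces the (1,1) ROC endpoint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class RocCurve:
    """Ordered (FPR, TPR, threshold) triples with trapezoidal AUC.

    One point per unique predicted probability plus the (0,0) endpoint, whose
    generating threshold is a sentinel strictly above the maximum
    probability.  Tied probabilities form a single threshold step.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int | None = None   # class counts enable exact tie handling
    n_neg: int | None = None

    def __post_init__(self):
        self.fpr = np.asarray(self.fpr, dtype=np.float64)
        self.tpr = np.asarray(self.tpr, dtype=np.float64)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC points must be monotone non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0
                and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must span (0,0) to (1,1)")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr,
                      "tpr": self.tpr}).to_csv(path, index=False)


@dataclass
class ThresholdResult:
    """Optimal cutoff with its distance-to-corner and operating point."""

    threshold: float
    distance: float
    tpr_at_opt: float
    fpr_at_opt: float
    degenerate: bool = False  # all probabilities equal: only trivial cutoffs

    def __post_init__(self):
        expected = float(np.hypot(1.0 - self.tpr_at_opt, self.fpr_at_opt))
        if abs(expected - self.distance) > 1e-9:
            raise ValueError("distance inconsistent with operating point")


def _validate(labels, probs) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=np.float64)
    if labels.shape != probs.shape or labels.ndim != 1:
        raise ValueError("labels and probabilities must be equal-length 1-D")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities outside [0, 1]")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present (AUC undefined)")
    return labels, probs


def roc(labels, probs) -> RocCurve:
    """Build the ROC curve of active-class probabilities vs binary labels.

    Points are placed at every unique probability (ties merged into one
    step); AUC is the trapezoidal area.  The (0,0) endpoint's sentinel
    threshold is strictly above the maximum probability.
    """
    labels, probs = _validate(labels, probs)
    fpr, tpr, thr = _sk_roc_curve(labels, probs, drop_intermediate=False)
    # scikit-learn's first threshold is +inf; keep a finite sentinel above max
    thr = thr.copy()
    thr[0] = np.nextafter(probs.max(), np.inf)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(_trapezoid_auc(fpr, tpr)),
                    n_pos=int((labels == 1).sum()),
                    n_neg=int((labels == 0).sum()))


def optimal_threshold(curve: RocCurve) -> ThresholdResult:
    """Pick the ROC point minimizing the distance to the (0,1) corner.

    Ties are broken toward higher TPR (screening favours catching actives),
    then toward the lower threshold.  When the curve carries class counts,
    squared distances are compared in exact integer arithmetic
    (``(fn*N)^2 + (fp*P)^2``), so geometrically tied operating points are
    recognized as ties regardless of float rounding.
    """
    if curve.n_pos and curve.n_neg:
        P, N = curve.n_pos, curve.n_neg
        fn = np.rint((1.0 - curve.tpr) * P).astype(np.int64)
        fp = np.rint(curve.fpr * N).astype(np.int64)
        keys = [((int(a) * N) ** 2 + (int(b) * P) ** 2, -int(P - a), t)
                for a, b, t in zip(fn, fp, curve.thresholds)]
        best = min(range(len(keys)), key=keys.__getitem__)
        distance = math.sqrt(keys[best][0]) / (P * N)
    else:
        d = np.hypot(1.0 - curve.tpr, curve.fpr)
        order = np.lexsort((curve.thresholds, -curve.tpr, d))
        best = int(order[0])
        distance = float(d[best])
    degenerate = len(curve.thresholds) <= 2
    return ThresholdResult(threshold=float(curve.thresholds[best]),
                           distance=distance,
                           tpr_at_opt=float(curve.tpr[best]),
                           fpr_at_opt=float(curve.fpr[best]),
                           degenerate=degenerate)


def optimize_threshold(labels, probs) -> tuple[RocCurve, ThresholdResult]:
    """Convenience: ROC construction plus threshold optimization."""
    curve = roc(labels, probs)
    return curve, optimal_threshold(curve)


def apply_threshold(probs, t: float) -> np.ndarray:
    """Binary class calls: active (1) iff probability >= t (inclusive).

    ``t`` may exceed 1 only as the sentinel "call nothing active" cutoff.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if t < 0:
        raise ValueError(f"threshold {t} < 0")
    return (probs >= t).astype(int)
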
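"""Bitwise classification metrics for fingerprint prediction.

All metrics micro-average over the flattened (sample, bit) pairs: a
positive pair means the substructure bit is set.  ROC and precision-recall
curves group tied scores into a single threshold step and integrate AUC by
the trapezoidal rule (delegated to scikit-learn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve


class DegenerateCurveError(ValueError):
    """Targets contain a single class; ROC/PR are undefined."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class CurvePoints:
    thresholds: np.ndarray
    x: np.ndarray   # FPR (ROC) or recall (PR)
    y: np.ndarray   # TPR (ROC) or precision (PR)
    auc: float


def binarize(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """bit = 1 iff score >= threshold."""
    return (np.asarray(scores) >= threshold).astype(np.int64)


def confusion_counts(pred: np.ndarray, targets: np.ndarray) -> ConfusionCounts:
    p = np.asarray(pred).ravel().astype(bool)
    t = np.asarray(targets).ravel().astype(bool)
    if p.shape != t.shape:
        raise ValueError("prediction/target shape mismatch")
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()), tn=int((~p & ~t).sum()),
    )


def accuracy_f1(counts: ConfusionCounts) -> tuple[float, float]:
    """Accuracy and F1 from a confusion table; F1 is 0 when 2tp+fp+fn = 0."""
    acc = (counts.tp + counts.tn) / counts.total if counts.total else 0.0
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / denom if denom else 0.0
    return acc, f1


def roc_pr_curves(scores: np.ndarray,
                  targets: np.ndarray) -> tuple[CurvePoints, CurvePoints]:
    """Micro-averaged ROC and PR curves over flattened (sample, bit) pairs."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    t = np.asarray(targets).ravel().astype(np.int64)
    if t.min() == t.max():
        raise DegenerateCurveError("targets contain a single class")
    fpr, tpr, roc_thr = roc_curve(t, s)
    roc = CurvePoints(thresholds=roc_thr, x=fpr, y=tpr,
                      auc=float(_trapezoid_auc(fpr, tpr)))
    prec, rec, pr_thr = precision_recall_curve(t, s)
    # sklearn anchors the curve at (recall 0, precision 1); extend the last
    # measured precision flat instead, so a constant classifier integrates
    # to the prevalence rather than an artifact of the anchor point
    prec = prec.copy()
    if len(prec) > 1:
        prec[-1] = prec[-2]
    pr = CurvePoints(thresholds=pr_thr, x=rec, y=prec,
                     auc=float(_trapezoid_auc(rec[::-1], prec[::-1])))
    return roc, pr


def micro_roc_auc(scores: np.ndarray, targets: np.ndarray) -> float:
    roc, _ = roc_pr_curves(scores, targets)
    return roc.auc
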
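"""Multiclass evaluation metrics: confusion matrix, per-class precision /
recall / F1, macro F1, one-vs-rest ROC curves with trapezoid AUC, macro AUC.

Per-class quantities come from the one-vs-rest confusion counts TP/FP/TN/FN;
macro averages are unweighted means over the classes.  Degenerate 0/0 ratios
(a class never predicted, or absent from the truth) are reported as 0 by
convention, except AUC for a single-class truth vector, which is undefined
and reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn.metrics

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "per_class_f1",
    "macro_f1",
    "roc_auc",
    "macro_auc",
    "compute_metrics",
]


def confusion_matrix(true, pred, n_classes: int = 4) -> np.ndarray:
    """Count matrix with entry [i, j] = samples of true class i predicted j."""
    true, pred = np.asarray(true, int), np.asarray(pred, int)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have equal length")
    for name, arr in (("true", true), ("pred", pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    return sklearn.metrics.confusion_matrix(true, pred, labels=range(n_classes))


def _ovr_counts(cm: np.ndarray, m: int) -> tuple[int, int, int, int]:
    tp = cm[m, m]
    fn = cm[m].sum() - tp
    fp = cm[:, m].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return int(tp), int(fp), int(tn), int(fn)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def per_class_f1(cm: np.ndarray, m: int) -> tuple[float, float, float]:
    """(precision, recall, F1) of class m from a confusion matrix.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    0/0 -> 0.
    """
    tp, fp, _tn, fn = _ovr_counts(np.asarray(cm), m)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return precision, recall, f1


def macro_f1(per_class: "np.ndarray | list[float]") -> float:
    """Unweighted mean of per-class F1 values."""
    per_class = np.asarray(per_class, dtype=float)
    if per_class.size == 0:
        raise ValueError("empty F1 list")
    return float(per_class.mean())


def roc_auc(scores: np.ndarray, true, m: int) -> tuple[np.ndarray, float]:
    """One-vs-rest ROC curve and trapezoid AUC for class m.

    ``scores`` holds one probability row per sample; the curve sweeps a
    threshold over ``scores[:, m]`` with TPR = TP/(TP+FN) on the y axis and
    FPR = FP/(FP+TN) on the x axis.  Returns (points [k x 2] as (FPR, TPR),
    AUC).  A single-class truth vector has no defined AUC -> NaN.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = (np.asarray(true, int) == m)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    s = scores[:, m]
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tp = np.concatenate([[0], np.cumsum(y_sorted)])
    fp = np.concatenate([[0], np.cumsum(~y_sorted)])
    # keep only the last point of each tied-score run
    distinct = np.concatenate([np.diff(s[order]) != 0, [True]])
    keep = np.concatenate([[True], distinct])
    tp, fp = tp[keep], fp[keep]
    if n_pos == 0 or n_neg == 0:
        pts = np.column_stack([np.zeros_like(tp, float), np.zeros_like(tp, float)])
        return pts, float("nan")
    tpr, fpr = tp / n_pos, fp / n_neg
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def macro_auc(aucs) -> float:
    """Unweighted mean of per-class AUC values."""
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size == 0:
        raise ValueError("empty AUC list")
    return float(aucs.mean())


@dataclass
class MetricsReport:
    """Full four-class evaluation: accuracy, per-class P/R/F1 and AUC, macro
    F1 and AUC, confusion matrix.  Rates are fractions in [0, 1]."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    auc: np.ndarray
    macro_auc: float
    confusion: np.ndarray

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_f1": self.macro_f1,
            "auc": self.auc.tolist(),
            "macro_auc": self.macro_auc,
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(true, pred, scores: np.ndarray | None = None,
                    n_classes: int = 4) -> MetricsReport:
    """Assemble the full report from labels, predictions and score rows."""
    cm = confusion_matrix(true, pred, n_classes)
    prf = np.array([per_class_f1(cm, m) for m in range(n_classes)])
    if scores is not None:
        aucs = np.array([roc_auc(scores, true, m)[1] for m in range(n_classes)])
    else:
        aucs = np.full(n_classes, np.nan)
    valid = aucs[~np.isnan(aucs)]
    return MetricsReport(
        accuracy=float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0,
        precision=prf[:, 0],
        recall=prf[:, 1],
        f1=prf[:, 2],
        macro_f1=macro_f1(prf[:, 2]),
        auc=aucs,
        macro_auc=macro_auc(valid) if valid.size else float("nan"),
        confusion=cm,
    )
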
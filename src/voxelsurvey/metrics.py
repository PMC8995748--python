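"""Confusion-matrix metrics and ROC/AUC for binary {-1, +1} classification.

The positive class is +1 (healthy control) throughout, matching the label
convention disease = -1 / control = +1.  The combined F score uses the
weighted form

    F_alpha = (alpha^2 + 1) * P * R / (alpha^2 * (P + R))

which reduces to the harmonic mean 2PR/(P+R) at alpha = 1.  Metrics with a
zero denominator are reported as flagged ``None`` values (listed in
``MetricsReport.undefined``), never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

POSITIVE = +1  # healthy control
NEGATIVE = -1  # disease


@dataclass(frozen=True)
class ConfusionCounts:
    """The four binary-classification counts; P = TP+FN, N = FP+TN."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN with +1 as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.shape}, y_pred has {y_pred.shape}"
        )
    bad = set(np.unique(y_true)) | set(np.unique(y_pred))
    if bad - {POSITIVE, NEGATIVE}:
        raise ValueError(f"labels must be in {{-1, +1}}, found {sorted(bad)}")
    return ConfusionCounts(
        tp=int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE))),
        tn=int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE))),
        fp=int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE))),
        fn=int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE))),
    )


def f_measure(precision: float, recall: float, alpha: float = 1.0) -> float | None:
    """Weighted F score; ``None`` when the denominator vanishes."""
    denom = alpha**2 * (precision + recall)
    if denom == 0:
        return None
    return (alpha**2 + 1) * precision * recall / denom


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / precision / recall / F for one evaluation.

    Undefined ratios (zero denominators) are ``None`` and their names are
    listed in ``undefined``.
    """

    accuracy: float | None
    precision: float | None
    recall: float | None
    f_measure: float | None
    alpha: float = 1.0
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "alpha": self.alpha,
            "undefined": list(self.undefined),
        }


def metrics(counts: ConfusionCounts, alpha: float = 1.0) -> MetricsReport:
    """Accuracy, precision, recall and F from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    undefined = []
    accuracy = (counts.tp + counts.tn) / counts.total

    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, _ = None, undefined.append("precision")
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, _ = None, undefined.append("recall")

    if precision is None or recall is None:
        f = None
        undefined.append("f_measure")
    else:
        f = f_measure(precision, recall, alpha)
        if f is None:
            undefined.append("f_measure")
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f,
        alpha=alpha,
        undefined=tuple(undefined),
    )


def evaluate_predictions(y_true, y_pred, alpha: float = 1.0) -> MetricsReport:
    """Convenience wrapper: confusion counts then metrics."""
    return metrics(confusion_counts(y_true, y_pred), alpha=alpha)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve from a threshold sweep plus its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, y_true) -> RocCurve:
    """ROC curve and AUC from continuous decision scores.

    Higher scores mean "more positive" (+1).  The AUC equals the
    probability that a random positive outscores a random negative (ties
    counted half).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise ValueError("scores and y_true must have equal length")
    classes = set(np.unique(y_true))
    if classes != {POSITIVE, NEGATIVE}:
        raise ValueError(f"both classes required for ROC, found labels {sorted(classes)}")
    fpr, tpr, thr = _sk_roc_curve(y_true, scores, pos_label=POSITIVE)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))
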
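"""Imbalance-aware evaluation for the three-class fall-detection problem.

Because BKG blocks outnumber ALERT and FALL blocks by two orders of
magnitude, plain accuracy is nearly meaningless here; the headline figure
is the macro F1-score, the harmonic mean of macro-precision and
macro-recall,

    F1_m = 2 * precision_m * recall_m / (precision_m + recall_m),

where precision_m and recall_m average the per-class ratios
TP_c/(TP_c+FP_c) and TP_c/(TP_c+FN_c) over the three classes with equal
weight.  Specificity averages TN_c/(TN_c+FP_c) the same way.  Macro-recall
is the conventional *sensitivity* of the detector.  Per-class ROC curves
are built one-vs-rest by sweeping a confidence threshold over the softmax
output of the corresponding class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .synthdata import CLASSES

_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class, ordered
    (BKG, ALERT, FALL)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(CLASSES), len(CLASSES)):
            raise ValueError(f"confusion matrix must be {len(CLASSES)}x{len(CLASSES)}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, c: int) -> int:
        return int(self.counts[c, c])

    def fp(self, c: int) -> int:
        return int(self.counts[:, c].sum() - self.counts[c, c])

    def fn(self, c: int) -> int:
        return int(self.counts[c, :].sum() - self.counts[c, c])

    def tn(self, c: int) -> int:
        return self.total - self.tp(c) - self.fp(c) - self.fn(c)


def _as_indices(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        idx = labels.astype(int)
        if np.any((idx < 0) | (idx >= len(CLASSES))):
            raise ValueError("integer labels must be in 0..2")
        return idx
    try:
        return np.array([_CLASS_INDEX[str(l)] for l in labels])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into a 3x3 matrix."""
    t = _as_indices(true_labels)
    p = _as_indices(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    counts = np.zeros((len(CLASSES), len(CLASSES)), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def _macro_average(ratios_num, ratios_den, metric_name: str) -> float:
    """Equal-weight average of per-class ratios; empty denominators
    contribute 0 with a warning."""
    vals = []
    for c, (num, den) in enumerate(zip(ratios_num, ratios_den)):
        if den == 0:
            warnings.warn(
                f"{metric_name}: class {CLASSES[c]} has empty denominator; counted as 0",
                RuntimeWarning,
                stacklevel=3,
            )
            vals.append(0.0)
        else:
            vals.append(num / den)
    return float(np.mean(vals))


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(precision_m, recall_m, f1_m) with equal class weighting.

    f1_m is the harmonic mean of the two macro averages (not the mean of
    per-class F1 scores).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    prec = _macro_average(
        [cm.tp(c) for c in range(3)], [cm.tp(c) + cm.fp(c) for c in range(3)], "macro precision"
    )
    rec = _macro_average(
        [cm.tp(c) for c in range(3)], [cm.tp(c) + cm.fn(c) for c in range(3)], "macro recall"
    )
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return prec, rec, f1


def specificity(cm: ConfusionMatrix) -> float:
    """Macro-averaged true-negative rate, TN_c/(TN_c + FP_c)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return _macro_average(
        [cm.tn(c) for c in range(3)], [cm.tn(c) + cm.fp(c) for c in range(3)], "specificity"
    )


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm.counts) / cm.total)


def roc_and_auc(
    class_scores: Sequence[float], true_labels: Sequence, target_class: str
) -> tuple[np.ndarray, float]:
    """One-vs-rest ROC by threshold sweep; AUC by the trapezoid rule.

    ``class_scores`` are the softmax outputs for ``target_class``.  The
    returned points are (fpr, tpr) pairs including the (0,0) and (1,1)
    endpoints.  Raises if the truth contains a single class (AUC undefined).
    """
    scores = np.asarray(class_scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1]")
    pos = _as_indices(true_labels) == _CLASS_INDEX[target_class]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC undefined: truth contains only one class for target {target_class!r}"
        )
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep one operating point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fps[distinct] / n_neg, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class EvalReport:
    """Full evaluation bundle for one model on one block set."""

    confusion: ConfusionMatrix
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    specificity: float
    roc: dict = field(default_factory=dict)  # class -> {"points": ndarray, "auc": float}

    @property
    def sensitivity(self) -> float:
        return self.macro_recall

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "class_order": list(CLASSES),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "specificity": self.specificity,
            "auc": {c: self.roc[c]["auc"] for c in self.roc},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(true_labels, predicted_labels, probabilities=None) -> EvalReport:
    """Build an EvalReport; ROC/AUC are included when softmax probabilities
    (n, 3) are supplied and both classes are present for the target."""
    cm = confusion(true_labels, predicted_labels)
    prec, rec, f1 = macro_metrics(cm)
    roc = {}
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        for i, c in enumerate(CLASSES):
            try:
                points, auc = roc_and_auc(probabilities[:, i], true_labels, c)
            except ValueError:
                continue  # class absent from the truth: AUC undefined
            roc[c] = {"points": points, "auc": auc}
    return EvalReport(
        confusion=cm,
        accuracy=accuracy(cm),
        macro_precision=prec,
        macro_recall=rec,
        macro_f1=f1,
        specificity=specificity(cm),
        roc=roc,
    )
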
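"""Confusion-matrix evaluation metrics for the prediction reports.

Binary reports treat label 0 as "normal" and the larger label as
"disease"; accuracy, sensitivity (recall on the disease class),
specificity, precision, recall and F-measure are computed directly from
the integer confusion counts.  Multi-class reports macro-average the
per-class one-vs-rest metrics; the reported F-measure is always the
harmonic mean of the reported precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["ClassificationReport", "confusion_matrix", "classification_report"]


@dataclass(frozen=True)
class ClassificationReport:
    classes: tuple[int, ...]
    confusion: np.ndarray  # (c, c) int, rows = true, cols = predicted
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f_measure: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }

    def summary(self) -> str:
        lines = ["Prediction report", "-----------------"]
        lines += [f"{k:<12} {v:.4f}" for k, v in self.as_dict().items()]
        return "\n".join(lines)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: tuple[int, ...]
) -> np.ndarray:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[int(t)], index[int(p)]] += 1
    return cm


def _harmonic(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def classification_report(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ClassificationReport:
    """Metrics from the integer confusion matrix (macro-averaged if c > 2)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = tuple(
        int(c) for c in np.unique(np.concatenate([y_true, y_pred]))
    )
    if len(classes) < 2:
        classes = tuple(sorted(set(classes) | {0, 1}))
    cm = confusion_matrix(y_true, y_pred, classes)
    total = int(cm.sum())
    accuracy = float(np.trace(cm)) / total if total else 0.0

    sens, spec, prec, rec = [], [], [], []
    for i in range(len(classes)):
        tp = int(cm[i, i])
        fn = int(cm[i].sum()) - tp
        fp = int(cm[:, i].sum()) - tp
        tn = total - tp - fn - fp
        rec_i = tp / (tp + fn) if tp + fn else 0.0
        sens.append(rec_i)
        rec.append(rec_i)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        prec.append(tp / (tp + fp) if tp + fp else 0.0)

    if len(classes) == 2:
        # positive class = the disease label (index 1)
        sensitivity, specificity = sens[1], spec[1]
        precision, recall = prec[1], rec[1]
    else:
        sensitivity = float(np.mean(sens))
        specificity = float(np.mean(spec))
        precision = float(np.mean(prec))
        recall = float(np.mean(rec))

    return ClassificationReport(
        classes=classes,
        confusion=cm,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        recall=recall,
        f_measure=_harmonic(precision, recall),
    )
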
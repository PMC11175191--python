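"""Confusion-matrix evaluation: the four standard rates, Cohen's kappa, ROC.

Binary convention: class 1 ("lie") is the positive class. Rates are stored as
fractions in [0, 1]; CLI output multiplies by 100 for percentage display.
A rate whose denominator is zero is reported as NaN with a warning, never
silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class Metrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    kappa: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy * scale,
            "precision": self.precision * scale,
            "sensitivity": self.sensitivity * scale,
            "specificity": self.specificity * scale,
            "kappa": self.kappa,  # kappa is conventionally left unscaled
        }


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray
                     ) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """Accuracy/precision/sensitivity/specificity plus Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    (accuracy) and p_e the chance agreement implied by the marginals.
    """
    n = tp + tn + fp + fn
    accuracy = _ratio(tp + tn, n, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    specificity = _ratio(tn, tn + fp, "specificity")
    if n == 0:
        kappa = float("nan")
    else:
        p_o = (tp + tn) / n
        p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
        kappa = _ratio(p_o - p_e, 1.0 - p_e, "kappa")
    return Metrics(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                   precision=precision, sensitivity=sensitivity,
                   specificity=specificity, kappa=kappa)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    return metrics_from_counts(*confusion_counts(y_true, y_pred))


def roc_auc(y_true: np.ndarray, scores: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve points and trapezoid area; ties handled by rank averaging.

    ``scores`` are class-1 probabilities. Returns (fpr, tpr, auc).
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC is undefined for single-class y_true")
    fpr, tpr, _ = roc_curve(y_true, scores)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area
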
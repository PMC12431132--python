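"""Confusion-matrix metrics and threshold curves for binary vigilance labels.

The positive class is drowsy (1) throughout: sensitivity is the true
positive rate on drowsy segments, specificity the true negative rate on
alert segments.  Metrics are percentages kept at full precision and
rounded only for display (2 decimals, half-up, as in the reported
tables); ratios with a zero denominator are reported as not-applicable
(``None``) rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts with drowsy (1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_array(self) -> np.ndarray:
        """Rows = true (alert, drowsy); columns = predicted (alert, drowsy)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion(y_true, y_pred) -> ConfusionMatrix2x2:
    """Tally a 2x2 confusion matrix from binary label sequences."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0 = alert, 1 = drowsy)")
    return ConfusionMatrix2x2(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Display rounding that matches printed tables (0.005 -> 0.01)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """The five confusion-matrix metrics (percent) plus optional AUCs."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    pr_auc: float | None = None
    roc_auc: float | None = None

    def rounded(self, decimals: int = 2) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1",
                     "pr_auc", "roc_auc"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, decimals)
        return out

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1, "pr_auc": self.pr_auc, "roc_auc": self.roc_auc,
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix2x2) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    if prec is None or sens is None or prec + sens == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
    )


def curves(scores, labels) -> dict:
    """PR and ROC point sets with their AUCs from continuous scores.

    ROC AUC by trapezoid over the threshold sweep; PR AUC by step-wise
    interpolation (average precision).
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel()
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr},
        "pr": {"precision": prec, "recall": rec, "thresholds": pr_thr},
        "roc_auc": float(roc_auc_score(labels, scores)),
        "pr_auc": float(average_precision_score(labels, scores)),
    }


def evaluate_predictions(y_true, y_pred, scores=None) -> MetricsReport:
    """Full report from labels (and scores, when available, for the AUCs)."""
    report = compute_metrics(confusion(y_true, y_pred))
    if scores is not None and np.unique(np.asarray(y_true)).size == 2:
        c = curves(scores, y_true)
        report = MetricsReport(**{**report.as_dict(),
                                  "pr_auc": c["pr_auc"], "roc_auc": c["roc_auc"]})
    return report
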
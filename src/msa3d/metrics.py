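"""Evaluation metrics: confusion-matrix scores and ROC AUC.

ACC/SEN/SPE/F1 follow the usual closed forms at a 0.5 decision threshold;
AUC is threshold-free, computed from positive-class probabilities with
scikit-learn's trapezoidal ROC integration (ties handled rank-wise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["MetricsReport", "confusion_counts", "report_from_counts", "evaluate"]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spe: float
    auc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
                "AUC": self.auc, "F1": self.f1,
                "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}


def confusion_counts(labels: np.ndarray, predictions: np.ndarray):
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return tp, fp, tn, fn


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def report_from_counts(tp: int, fp: int, tn: int, fn: int,
                       auc: float = float("nan")) -> MetricsReport:
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=_safe_div(tp + tn, tp + tn + fp + fn),
        sen=_safe_div(tp, tp + fn),
        spe=_safe_div(tn, tn + fp),
        auc=auc,
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
    )


def evaluate(labels, positive_probs, threshold: float = 0.5) -> MetricsReport:
    """Score binary predictions given positive-class probabilities."""
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(positive_probs, dtype=np.float64)
    preds = (probs >= threshold).astype(int)
    tp, fp, tn, fn = confusion_counts(labels, preds)
    auc = float(roc_auc_score(labels, probs)) if len(set(labels)) > 1 else float("nan")
    return report_from_counts(tp, fp, tn, fn, auc)
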
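"""Confusion-matrix statistics and ROC/AUC for binary DIAD classification.

ACC = (TP+TN)/(TP+FN+TN+FP), SE = TP/(TP+FN), SP = TN/(TN+FP),
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

With the 148:450 class imbalance of the endpoint, ACC alone flatters
majority-class models, so MCC is carried everywhere alongside it. A zero
factor in the MCC denominator (a degenerate row or column) yields MCC = 0
with ``mcc_degenerate`` set — the common convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix_from_predictions",
    "confusion_metrics",
    "infer_confusion_from_rates",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    acc: float
    se: float
    sp: float
    mcc: float
    auc: float | None = None
    roc: np.ndarray | None = None  # (m, 2) columns FPR, TPR
    cm: ConfusionMatrix | None = None
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        """Benchmark-table row with proportions printed as percentages."""
        return {
            "ACC": round(100 * self.acc, 2),
            "SE": round(100 * self.se, 2) if not math.isnan(self.se) else float("nan"),
            "SP": round(100 * self.sp, 2) if not math.isnan(self.sp) else float("nan"),
            "MCC": round(self.mcc, 2),
            "AUC": round(self.auc, 2) if self.auc is not None else float("nan"),
        }


def confusion_matrix_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred misaligned")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """ACC/SE/SP/MCC from integer counts (no ROC — that needs scores)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags = []
    acc = (cm.tp + cm.tn) / cm.total
    se = cm.tp / cm.n_pos if cm.n_pos else float("nan")
    sp = cm.tn / cm.n_neg if cm.n_neg else float("nan")
    if cm.n_pos == 0:
        flags.append("se_undefined")
    if cm.n_neg == 0:
        flags.append("sp_undefined")
    denom = ((cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if denom == 0:
        mcc = 0.0
        flags.append("mcc_degenerate")
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return MetricsReport(acc=acc, se=se, sp=sp, mcc=mcc, cm=cm, flags=flags)


def infer_confusion_from_rates(se: float, sp: float, n_pos: int, n_neg: int) -> ConfusionMatrix:
    """Recover the integer confusion matrix implied by printed SE/SP.

    TP = round(SE*n_pos), TN = round(SP*n_neg); the complements fill FN/FP.
    Used to audit published benchmark rows for internal consistency.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = int(round(se * n_pos))
    tn = int(round(sp * n_neg))
    if not (0 <= tp <= n_pos and 0 <= tn <= n_neg):
        raise ValueError("rates round outside [0, n]")
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) and trapezoidal AUC from continuous scores."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
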
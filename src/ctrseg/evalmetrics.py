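"""Segmentation and detection evaluation metrics.

Segmentation quality is summarised by the Jaccard index (intersection over
union of binary masks).  Detection quality is summarised from the confusion
matrix of cardiomegaly-vs-normal calls: sensitivity, specificity, their
geometric mean (G-Mean), accuracy, and ROC AUC.  Cardiomegaly is the
positive class throughout.

Two AUC variants are provided.  ``auc_binary`` scores a hard binary
predictor: its ROC has a single interior operating point and the
trapezoidal area reduces to (sensitivity + specificity) / 2.  This is the
default report column.  ``auc_scores`` is the usual rank-based AUC for a
continuous score (here, the CTR itself) with midrank tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
import math

import numpy as np
from sklearn.metrics import roc_auc_score

CARDIOMEGALY = "cardiomegaly"
NORMAL = "normal"
_VALID_LABELS = {CARDIOMEGALY, NORMAL}


def _round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention), e.g. 70.205 -> 70.21."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Confusion counts and summary rates (rates as percentages)."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    g_mean: float
    accuracy: float
    auc: float

    def rounded(self) -> dict:
        """Report-style dict with percentages rounded to 2 decimals."""
        return {
            "TP": self.tp,
            "FN": self.fn,
            "TN": self.tn,
            "FP": self.fp,
            "sens": _round_half_away(self.sensitivity),
            "spec": _round_half_away(self.specificity),
            "gmean": _round_half_away(self.g_mean),
            "acc": _round_half_away(self.accuracy),
            "auc": _round_half_away(self.auc),
        }


def jaccard(y: np.ndarray, yhat: np.ndarray) -> float:
    """Jaccard index |y ∩ yhat| / |y ∪ yhat| of two binary masks.

    Both masks empty is defined as perfect agreement (1.0).
    """
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    yb = y > 0.5
    pb = yhat > 0.5
    union = np.logical_or(yb, pb).sum()
    if union == 0:
        return 1.0
    inter = np.logical_and(yb, pb).sum()
    return float(inter / union)


def confusion(true_labels, pred_labels) -> dict:
    """Count TP/FN/TN/FP over label sequences; cardiomegaly is positive."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label sequences differ in length")
    for lab in true_labels + pred_labels:
        if lab not in _VALID_LABELS:
            raise ValueError(f"unknown label {lab!r}")
    tp = fn = tn = fp = 0
    for t, p in zip(true_labels, pred_labels):
        if t == CARDIOMEGALY:
            if p == CARDIOMEGALY:
                tp += 1
            else:
                fn += 1
        else:
            if p == NORMAL:
                tn += 1
            else:
                fp += 1
    return {"tp": tp, "fn": fn, "tn": tn, "fp": fp}


def summary_metrics(counts: dict) -> EvalReport:
    """Sens/Spec/G-Mean/Acc/AUC (percentages) from confusion counts.

    With no positives (or no negatives) the affected rate is undefined and
    reported as NaN; accuracy is always defined for a non-empty sample.
    """
    tp, fn, tn, fp = counts["tp"], counts["fn"], counts["tn"], counts["fp"]
    total = tp + fn + tn + fp
    if total <= 0:
        raise ValueError("empty confusion table")
    pos = tp + fn
    neg = tn + fp
    sens = 100.0 * tp / pos if pos else float("nan")
    spec = 100.0 * tn / neg if neg else float("nan")
    if math.isnan(sens) or math.isnan(spec):
        gmean = auc = float("nan")
    else:
        gmean = math.sqrt(sens * spec)
        auc = (sens + spec) / 2.0
    acc = 100.0 * (tp + tn) / total
    return EvalReport(tp, fn, tn, fp, sens, spec, gmean, acc, auc)


def rates_to_summary(sens_pct: float, spec_pct: float,
                     n_pos: int, n_neg: int) -> EvalReport:
    """Reconstruct the full report from printed Sens/Spec and class sizes.

    Counts are recovered by rounding sens*n_pos and spec*n_neg to the
    nearest integer; the remaining metrics follow from the formulas.
    """
    tp = int(round(sens_pct / 100.0 * n_pos))
    tn = int(round(spec_pct / 100.0 * n_neg))
    return summary_metrics(
        {"tp": tp, "fn": n_pos - tp, "tn": tn, "fp": n_neg - tn}
    )


def auc_binary(true_labels, pred_labels) -> float:
    """ROC AUC (%) of a hard binary predictor: (Sens + Spec) / 2."""
    c = confusion(true_labels, pred_labels)
    if c["tp"] + c["fn"] == 0 or c["tn"] + c["fp"] == 0:
        raise ValueError("AUC undefined: only one class present")
    rep = summary_metrics(c)
    return (rep.sensitivity + rep.specificity) / 2.0


def auc_scores(true_labels, scores) -> float:
    """Rank-based ROC AUC (%) of continuous scores, midrank tie handling."""
    y = np.array([1 if t == CARDIOMEGALY else 0 for t in true_labels])
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("AUC undefined: only one class present")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite scores")
    return 100.0 * float(roc_auc_score(y, s))
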
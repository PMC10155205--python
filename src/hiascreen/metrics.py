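"""Regression and binary-classification metrics.

RMSE, range-normalised RMSE (reported in percent of the observed range),
coefficient of determination, confusion-matrix statistics, cross-entropy
(log) loss, and ROC curves with trapezoidal AUC in class-0/class-1/micro/
macro variants. Undefined ratios (e.g. precision with no predicted
positives) raise :class:`UndefinedMetricError` rather than silently
returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG_LOSS_EPS = 1e-15


class UndefinedMetricError(ArithmeticError):
    """A metric's denominator is zero; the value is genuinely undefined."""


# ---------------------------------------------------------------------------
# Regression


def _check_aligned(obs, pred):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty input")
    return obs, pred


def rmse(obs, pred) -> float:
    """Root-mean-square error."""
    obs, pred = _check_aligned(obs, pred)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def nrmse(obs, pred) -> float:
    """RMSE normalised by the observed range, as a percentage.

    With observations spanning the full 0–100 HIA scale, NRMSE equals RMSE
    numerically.
    """
    obs, pred = _check_aligned(obs, pred)
    span = obs.max() - obs.min()
    if span == 0:
        raise UndefinedMetricError("observed values are constant; zero range")
    return 100.0 * rmse(obs, pred) / span


def r2(obs, pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    obs, pred = _check_aligned(obs, pred)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("observed values are constant; SS_tot = 0")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Classification

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, predicted_classes) -> ConfusionMatrix:
    """Confusion matrix with class 1 as the positive class."""
    y, yhat = _check_aligned(labels, predicted_classes)
    vals = set(np.unique(y)) | set(np.unique(yhat))
    if not vals <= {0.0, 1.0}:
        raise ValueError(f"labels/predictions must be binary 0/1, got {sorted(vals)}")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.n


def precision(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("no predicted positives; precision undefined")
    return cm.tp / (cm.tp + cm.fp)


def recall(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no actual positives; recall undefined")
    return cm.tp / (cm.tp + cm.fn)


def f1(precision_value: float, recall_value: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision_value + recall_value == 0:
        raise UndefinedMetricError("precision + recall = 0; F1 undefined")
    return 2.0 * precision_value * recall_value / (precision_value + recall_value)


def false_positive_rate(cm: ConfusionMatrix) -> float:
    if cm.fp + cm.tn == 0:
        raise UndefinedMetricError("no actual negatives; FPR undefined")
    return cm.fp / (cm.fp + cm.tn)


def log_loss(labels, probabilities) -> float:
    """Mean cross-entropy -[y ln p + (1-y) ln(1-p)], p clipped to 1e-15."""
    y, p = _check_aligned(labels, probabilities)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, LOG_LOSS_EPS, 1.0 - LOG_LOSS_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    variant: str  # class0 | class1 | micro | macro


def _roc_points(y: np.ndarray, p: np.ndarray):
    """Threshold sweep over unique scores, rule score >= t -> positive."""
    order = np.argsort(-p, kind="stable")
    y = y[order]
    p = p[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    thresholds = [np.inf]
    tps = [0]
    fps = [0]
    tp = fp = 0
    i = 0
    n = len(y)
    while i < n:
        t = p[i]
        while i < n and p[i] == t:
            if y[i] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        thresholds.append(t)
        tps.append(tp)
        fps.append(fp)
    return (
        np.asarray(thresholds, dtype=float),
        np.asarray(fps, dtype=float) / n_neg,
        np.asarray(tps, dtype=float) / n_pos,
    )


def _trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def roc_auc(labels, probabilities, variant: str = "class1"):
    """ROC curve and trapezoidal AUC.

    ``class1`` treats the given probabilities as scores for class 1;
    ``class0`` complements labels and probabilities; ``macro`` averages the
    two AUCs (its curve is the class-1 curve by convention); ``micro`` pools
    the per-class indicator/score pairs of both classes before the sweep.
    """
    y, p = _check_aligned(labels, probabilities)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")

    if variant == "class1":
        thr, fpr, tpr = _roc_points(y, p)
    elif variant == "class0":
        thr, fpr, tpr = _roc_points(1 - y, 1 - p)
    elif variant == "micro":
        pooled_y = np.concatenate([y, 1 - y])
        pooled_p = np.concatenate([p, 1 - p])
        thr, fpr, tpr = _roc_points(pooled_y, pooled_p)
    elif variant == "macro":
        _, auc1 = roc_auc(y, p, "class1")
        _, auc0 = roc_auc(y, p, "class0")
        thr, fpr, tpr = _roc_points(y, p)
        curve = RocCurve(thr, fpr, tpr, "macro")
        return curve, 0.5 * (auc0 + auc1)
    else:
        raise ValueError(f"unknown ROC variant {variant!r}")

    curve = RocCurve(thr, fpr, tpr, variant)
    return curve, _trapezoid_auc(fpr, tpr)


def classification_report(labels, probabilities, threshold: float = 0.5) -> dict:
    """Table-style metric bundle at a decision threshold (p >= t -> class 1)."""
    y, p = _check_aligned(labels, probabilities)
    cm = confusion(y, (p >= threshold).astype(int))
    prec = precision(cm)
    rec = recall(cm)
    _, auc = roc_auc(y, p, "class1")
    return {
        "threshold": threshold,
        "log_loss": log_loss(y, p),
        "auc": auc,
        "f1": f1(prec, rec),
        "accuracy": accuracy(cm),
        "precision": prec,
        "recall": rec,
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
    }


def regression_report(obs, pred) -> dict:
    return {"rmse": rmse(obs, pred), "nrmse": nrmse(obs, pred), "r2": r2(obs, pred)}
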
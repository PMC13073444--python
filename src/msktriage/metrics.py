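"""Evaluation: confusion matrices, summary metrics, bootstrap intervals.

All metrics derive from the 3x3 confusion matrix (rows = true class,
columns = predicted class, order GREEN/YELLOW/RED). Undefined ratios
(0/0, e.g. precision of a never-predicted class) are defined as 0, both
in point estimates and inside bootstrap resamples — a resample is never
discarded.

Uncertainty comes from the non-parametric percentile bootstrap:
resample (truth, prediction) pairs with replacement, recompute the
metric, and report the empirical 2.5th/97.5th percentiles. The paired
variant resamples the same indices for two prediction sets so the
difference distribution respects their correlation; the reported
``p_like`` (fraction of resamples where the difference is <= 0) is a
descriptive quantity, not a significance test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .labels import CLASS_NAMES, N_CLASSES

__all__ = [
    "confusion_matrix",
    "per_class_prf",
    "accuracy",
    "macro_precision",
    "macro_recall",
    "macro_f1",
    "weighted_f1",
    "bootstrap_ci",
    "paired_bootstrap",
    "EvaluationReport",
    "evaluate_predictions",
    "metric_accuracy",
    "metric_macro_f1",
    "metric_weighted_f1",
]

MetricFn = Callable[[np.ndarray, np.ndarray], float]


def _as_label_array(y: Sequence) -> np.ndarray:
    arr = np.asarray([int(v) for v in y], dtype=int)
    if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
        raise ValueError("labels must be in {0, 1, 2}")
    return arr


def confusion_matrix(y_true: Sequence, y_pred: Sequence) -> np.ndarray:
    """3x3 count matrix; cm[i, j] = #(true i, predicted j)."""
    yt, yp = _as_label_array(y_true), _as_label_array(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred differ in length")
    return _sk_confusion_matrix(yt, yp, labels=list(range(N_CLASSES)))


def _safe_div(num: float, den: float) -> float:
    return float(num) / float(den) if den else 0.0


def per_class_prf(cm: np.ndarray, c: int) -> tuple[float, float, float]:
    """(precision, recall, F1) for class ``c``; 0/0 ratios are 0."""
    cm = np.asarray(cm)
    tp = cm[c, c]
    precision = _safe_div(tp, cm[:, c].sum())
    recall = _safe_div(tp, cm[c, :].sum())
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return precision, recall, f1


def _check_total(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    return cm


def accuracy(cm: np.ndarray) -> float:
    cm = _check_total(cm)
    return float(np.trace(cm)) / float(cm.sum())


def macro_precision(cm: np.ndarray) -> float:
    cm = _check_total(cm)
    return float(np.mean([per_class_prf(cm, c)[0] for c in range(N_CLASSES)]))


def macro_recall(cm: np.ndarray) -> float:
    cm = _check_total(cm)
    return float(np.mean([per_class_prf(cm, c)[1] for c in range(N_CLASSES)]))


def macro_f1(cm: np.ndarray) -> float:
    """Unweighted mean of per-class F1 (the model-selection criterion)."""
    cm = _check_total(cm)
    return float(np.mean([per_class_prf(cm, c)[2] for c in range(N_CLASSES)]))


def weighted_f1(cm: np.ndarray) -> float:
    """Support-weighted mean of per-class F1."""
    cm = _check_total(cm)
    support = cm.sum(axis=1)
    f1s = np.array([per_class_prf(cm, c)[2] for c in range(N_CLASSES)])
    return float((f1s * support).sum() / support.sum())


# convenience metric functions with the (y_true, y_pred) signature used
# by the bootstrap machinery
def metric_accuracy(y_true, y_pred) -> float:
    return accuracy(confusion_matrix(y_true, y_pred))


def metric_macro_f1(y_true, y_pred) -> float:
    return macro_f1(confusion_matrix(y_true, y_pred))


def metric_weighted_f1(y_true, y_pred) -> float:
    return weighted_f1(confusion_matrix(y_true, y_pred))


def bootstrap_ci(
    y_true: Sequence,
    y_pred: Sequence,
    metric: MetricFn,
    n_resamples: int = 1000,
    seed: int = 42,
) -> tuple[float, float, float]:
    """(point, low, high): percentile bootstrap 95% interval of a metric."""
    yt = np.asarray(list(y_true))
    yp = np.asarray(list(y_pred))
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("need non-empty, equal-length sequences")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    point = float(metric(yt, yp))
    rng = np.random.default_rng(seed)
    n = yt.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    stats = np.array([metric(yt[ix], yp[ix]) for ix in idx], dtype=float)
    low, high = np.percentile(stats, [2.5, 97.5])
    return point, float(low), float(high)


def paired_bootstrap(
    y_true: Sequence,
    pred_a: Sequence,
    pred_b: Sequence,
    metric: MetricFn,
    n_resamples: int = 1000,
    seed: int = 42,
) -> tuple[float, float, float, float]:
    """Paired comparison of two prediction sets on the same truth.

    Returns (delta, low, high, p_like) where delta = metric(a) -
    metric(b) on the full sample, (low, high) the percentile interval of
    the resampled difference, and p_like the fraction of resamples with
    difference <= 0 (descriptive only).
    """
    yt = np.asarray(list(y_true))
    pa = np.asarray(list(pred_a))
    pb = np.asarray(list(pred_b))
    if not (yt.shape == pa.shape == pb.shape) or yt.size == 0:
        raise ValueError("need non-empty, aligned sequences")
    delta = float(metric(yt, pa)) - float(metric(yt, pb))
    rng = np.random.default_rng(seed)
    n = yt.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    deltas = np.array(
        [metric(yt[ix], pa[ix]) - metric(yt[ix], pb[ix]) for ix in idx],
        dtype=float,
    )
    low, high = np.percentile(deltas, [2.5, 97.5])
    p_like = float(np.mean(deltas <= 0))
    return delta, float(low), float(high), p_like


@dataclass
class EvaluationReport:
    """Full metric summary of one prediction set."""

    matrix: np.ndarray
    accuracy: float
    per_class: list[dict]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_f1: float
    ci: dict = field(default_factory=dict)
    n_resamples: int = 0
    seed: int = 42

    def to_dict(self) -> dict:
        return {
            "n": int(np.asarray(self.matrix).sum()),
            "confusion_matrix": np.asarray(self.matrix).astype(int).tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "ci": self.ci,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def format_table(self) -> str:
        """Human-readable table, rates to two decimals."""
        lines = [f"{'Class':<8}{'Precision':>10}{'Recall':>8}{'F1':>6}{'Support':>9}"]
        support = np.asarray(self.matrix).sum(axis=1)
        for c, row in enumerate(self.per_class):
            lines.append(
                f"{CLASS_NAMES[c]:<8}{row['precision']:>10.2f}"
                f"{row['recall']:>8.2f}{row['f1']:>6.2f}{support[c]:>9d}"
            )
        lines.append(
            f"{'Macro':<8}{self.macro_precision:>10.2f}"
            f"{self.macro_recall:>8.2f}{self.macro_f1:>6.2f}{'-':>9}"
        )
        lines.append(f"Accuracy: {100 * self.accuracy:.1f}%")
        return "\n".join(lines)


def evaluate_predictions(
    y_true: Sequence,
    y_pred: Sequence,
    n_resamples: int = 0,
    seed: int = 42,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport`; CIs when n_resamples > 0.

    Bootstrap intervals are computed for accuracy and macro-F1 (the two
    headline metrics).
    """
    cm = confusion_matrix(y_true, y_pred)
    per_class = []
    for c in range(N_CLASSES):
        p, r, f = per_class_prf(cm, c)
        per_class.append(
            {"class": CLASS_NAMES[c], "precision": p, "recall": r, "f1": f}
        )
    ci: dict = {}
    if n_resamples > 0:
        for name, fn in (
            ("accuracy", metric_accuracy),
            ("macro_f1", metric_macro_f1),
        ):
            _, low, high = bootstrap_ci(y_true, y_pred, fn, n_resamples, seed)
            ci[name] = {"low": low, "high": high}
    return EvaluationReport(
        matrix=cm,
        accuracy=accuracy(cm),
        per_class=per_class,
        macro_precision=macro_precision(cm),
        macro_recall=macro_recall(cm),
        macro_f1=macro_f1(cm),
        weighted_f1=weighted_f1(cm),
        ci=ci,
        n_resamples=n_resamples,
        seed=seed,
    )
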
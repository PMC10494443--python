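"""Confusion matrices and sleep-staging performance metrics.

Accuracy, class-wise F1, overall (macro) F1 and Cohen's kappa, computed
from a 5x5 confusion matrix in the fixed stage order
(Wake, N1, N2, N3, REM).  "Overall F1" is the unweighted macro average
of the class-wise F1-scores — the convention used throughout the sleep
staging literature when comparing scorers.  A class with a zero F1
denominator (no true and no predicted epochs) scores 0, not NaN, so
macro averages stay defined on small folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STAGES, STAGE_INDEX


class UndefinedMetricsError(ValueError):
    """Metrics requested for an empty confusion matrix."""


@dataclass
class ConfusionMatrix:
    """Rows = true stage, columns = predicted stage."""

    counts: np.ndarray
    classes: tuple = STAGES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


@dataclass
class MetricsReport:
    accuracy: float
    per_class_f1: np.ndarray
    macro_f1: float
    kappa: float
    support: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "per_class_f1": {c: float(f) for c, f in zip(STAGES, self.per_class_f1)},
            "support": {c: int(s) for c, s in zip(STAGES, self.support)},
        }


def _to_indices(labels, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.array([idx[l] for l in arr], dtype=np.int64)


def confusion(y_true, y_pred, classes: tuple = STAGES) -> ConfusionMatrix:
    """Count matrix over (true, predicted) stage pairs.

    Accepts stage codes or integer class indices; inputs must have equal
    length.
    """
    t = _to_indices(y_true, classes)
    p = _to_indices(y_pred, classes)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, classes)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class F1, macro-F1 and Cohen's kappa from counts."""
    n = cm.total
    if n == 0:
        raise UndefinedMetricsError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    f1 = np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    accuracy = tp.sum() / n
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / (n * n)
    kappa = 1.0 if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)
    return MetricsReport(
        accuracy=float(accuracy),
        per_class_f1=f1,
        macro_f1=float(f1.mean()),
        kappa=float(kappa),
        support=cm.counts.sum(axis=1),
    )


def score(y_true, y_pred) -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(y_true, y_pred))


def per_class_f1(y_true_idx: np.ndarray, y_pred_idx: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Class-wise F1 from integer label arrays (drives the adaptive loss)."""
    cm = confusion(y_true_idx, y_pred_idx, classes=tuple(range(n_classes)))
    return metrics(cm).per_class_f1


def plot_confusion(cm: ConfusionMatrix, path=None, normalize: bool = True):
    """Render the confusion matrix as a heat map (row-normalized by default)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = cm.counts.astype(float)
    if normalize:
        row = counts.sum(axis=1, keepdims=True)
        counts = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(counts, cmap="Blues", vmin=0)
    ax.set_xticks(range(len(cm.classes)), cm.classes)
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("Predicted stage")
    ax.set_ylabel("True stage")
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, f"{counts[i, j]:.2f}" if normalize else f"{int(counts[i, j])}",
                    ha="center", va="center", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
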
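"""Classification metrics and the per-group sample-size calculation.

The confusion matrix follows the rows = true class, columns = predicted
class convention; "class-wise accuracy" is row-normalized recall. The
sample-size calculator implements the standard proportion estimate with
finite-population correction,

    n' = N Z^2 P(1-P) / (d^2 (N-1) + Z^2 P(1-P)),

reducing to Z^2 P(1-P) / d^2 as N -> infinity, rounded up to an integer
(sample sizes are conservative by convention).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes) ints, rows = true

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ParameterError("confusion matrix must be square")
        if (c < 0).any():
            raise ParameterError("confusion matrix counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")

    def plot(self, path: str | Path) -> None:
        """Render a heat map of row-normalized recall to a PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(rows > 0, self.counts / rows, 0.0)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
        ax.set_xlabel("predicted class")
        ax.set_ylabel("true class")
        fig.colorbar(im, ax=ax)
        for i in range(self.n_classes):
            for j in range(self.n_classes):
                if self.counts[i, j]:
                    ax.text(j, i, str(self.counts[i, j]), ha="center",
                            va="center", fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def confusion_matrix(true_labels, predicted_labels, n_classes: int = 9) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ParameterError("label sequences must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ParameterError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row sums; empty rows yield NaN, not zero."""
    rows = cm.counts.sum(axis=1)
    out = np.full(cm.n_classes, np.nan)
    nz = rows > 0
    out[nz] = np.diag(cm.counts)[nz] / rows[nz]
    return out


def per_class_precision(cm: ConfusionMatrix) -> np.ndarray:
    cols = cm.counts.sum(axis=0)
    out = np.full(cm.n_classes, np.nan)
    nz = cols > 0
    out[nz] = np.diag(cm.counts)[nz] / cols[nz]
    return out


def overall_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, macro precision, macro recall); macro means skip
    undefined (empty) classes."""
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    accuracy = float(np.trace(cm.counts) / cm.total)
    precision = float(np.nanmean(per_class_precision(cm)))
    recall = float(np.nanmean(per_class_recall(cm)))
    return accuracy, precision, recall


def metrics_report(cm: ConfusionMatrix) -> dict:
    accuracy, precision, recall = overall_metrics(cm)
    return {
        "accuracy": accuracy,
        "macro_precision": precision,
        "macro_recall": recall,
        "per_class_recall": [
            None if math.isnan(v) else float(v) for v in per_class_recall(cm)
        ],
        "per_class_precision": [
            None if math.isnan(v) else float(v) for v in per_class_precision(cm)
        ],
        "total": cm.total,
    }


def save_report(cm: ConfusionMatrix, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics_report(cm), indent=2))


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs of the proportion sample-size formula; N may be math.inf."""

    P: float  # expected proportion
    d: float  # desired precision
    Z: float = 1.96  # standard-normal quantile (95% confidence)
    N: float = math.inf  # population size

    def validate(self) -> None:
        if not 0 < self.P < 1:
            raise ParameterError("P must lie in (0, 1)")
        if not 0 < self.d < 1:
            raise ParameterError("d must lie in (0, 1)")
        if self.Z <= 0:
            raise ParameterError("Z must be positive")
        if self.N != math.inf and (self.N < 1 or self.N != int(self.N)):
            raise ParameterError("N must be a positive integer or infinite")


def compute_sample_size(p: SampleSizeParams) -> int:
    """Required samples per group, rounded up to the next integer."""
    p.validate()
    core = p.Z**2 * p.P * (1 - p.P)
    if p.N == math.inf:
        n = core / p.d**2
    else:
        n = p.N * core / (p.d**2 * (p.N - 1) + core)
    return math.ceil(n - 1e-12)
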
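"""Evaluation suite for multi-class classifiers: accuracy, macro-F1,
confusion matrix and per-class classification report.

All functions are pure and operate on integer label vectors, so they can be
checked against brute-force oracles. Conventions:

* the confusion matrix entry ``C[i, j]`` counts samples of true class ``i``
  predicted as class ``j`` (rows = truth, columns = prediction);
* precision/recall/F1 use the zero-division convention: an undefined ratio
  (empty denominator) is reported as 0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassReport",
    "confusion_matrix",
    "accuracy",
    "macro_f1",
    "classification_report",
    "render_outputs",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count matrix; ``counts[i, j]`` = true class i predicted as j."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if len(self.class_names) != counts.shape[0]:
            raise ValueError("class_names length must match matrix size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Per-class sample counts (row sums)."""
        return self.counts.sum(axis=1)

    def accuracy(self) -> float:
        """trace / total — identical to :func:`accuracy` on the raw labels."""
        if self.total == 0:
            raise ValueError("confusion matrix is empty")
        return float(np.trace(self.counts)) / self.total


@dataclass(frozen=True)
class ClassReport:
    """Per-class precision/recall/F1/support plus macro and weighted averages."""

    class_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float = field(init=False)
    macro_recall: float = field(init=False)
    macro_f1: float = field(init=False)
    weighted_precision: float = field(init=False)
    weighted_recall: float = field(init=False)
    weighted_f1: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "f1", "support"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = self.support.sum()
        w = self.support / n if n else np.zeros_like(self.support, dtype=float)
        object.__setattr__(self, "macro_precision", float(self.precision.mean()))
        object.__setattr__(self, "macro_recall", float(self.recall.mean()))
        object.__setattr__(self, "macro_f1", float(self.f1.mean()))
        object.__setattr__(self, "weighted_precision", float(self.precision @ w))
        object.__setattr__(self, "weighted_recall", float(self.recall @ w))
        object.__setattr__(self, "weighted_f1", float(self.f1 @ w))

    def to_dict(self) -> dict:
        per_class = {
            name: {
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
                "support": int(s),
            }
            for name, p, r, f, s in zip(
                self.class_names, self.precision, self.recall, self.f1, self.support
            )
        }
        return {
            "classes": per_class,
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassReport":
        names = tuple(d["classes"])
        rows = [d["classes"][n] for n in names]
        return cls(
            class_names=names,
            precision=np.array([r["precision"] for r in rows]),
            recall=np.array([r["recall"] for r in rows]),
            f1=np.array([r["f1"] for r in rows]),
            support=np.array([r["support"] for r in rows]),
            accuracy=float(d["accuracy"]),
        )


def _check_labels(y: np.ndarray, n_classes: int, name: str) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    bad = np.nonzero((y < 0) | (y >= n_classes))[0]
    if bad.size:
        raise ValueError(
            f"{name}[{bad[0]}] = {y[bad[0]]} outside valid classes 0..{n_classes - 1}"
        )
    return y.astype(np.int64)


def confusion_matrix(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    n_classes: int,
    class_names: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tabulate ``C[i, j] = #{k : y_true[k] = i and y_pred[k] = j}``."""
    y_true = _check_labels(np.asarray(y_true), n_classes, "y_true")
    y_pred = _check_labels(np.asarray(y_pred), n_classes, "y_pred")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred have different lengths")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred have different lengths")
    if len(y_true) == 0:
        raise ValueError("accuracy undefined on empty input")
    return float(np.mean(y_true == y_pred))


def classification_report(cm: ConfusionMatrix) -> ClassReport:
    """Per-class precision P_i = C_ii / column_i, recall R_i = C_ii / row_i,
    F1_i = 2 P_i R_i / (P_i + R_i); zero denominators give 0."""
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("cannot build a report from an all-zero confusion matrix")
    diag = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return ClassReport(
        class_names=cm.class_names,
        precision=precision,
        recall=recall,
        f1=f1,
        support=counts.sum(axis=1),
        accuracy=cm.accuracy(),
    )


def macro_f1(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> float:
    """Unweighted mean of per-class F1 scores."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    return classification_report(cm).macro_f1


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_outputs(
    report: ClassReport,
    cm: ConfusionMatrix,
    curves: Mapping[str, Sequence[float]] | None,
    out_dir: str | Path,
    prefix: str = "eval",
) -> dict[str, Path]:
    """Write a confusion-matrix heatmap (PNG), metric curves (PNG), the
    confusion matrix as CSV and the classification report as JSON.

    Outputs are deterministic for equal inputs: fixed colormap, no embedded
    timestamps. Returns a mapping of artifact name to path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: dict[str, Path] = {}
    png_meta = {"Software": None}  # strip the default matplotlib tag for determinism

    # confusion-matrix heatmap with per-cell counts
    fig, ax = plt.subplots(figsize=(4.5, 4.0))
    im = ax.imshow(cm.counts, cmap="Blues")
    thresh = cm.counts.max() / 2 if cm.total else 0
    for i in range(cm.n_classes):
        for j in range(cm.n_classes):
            ax.text(
                j, i, str(cm.counts[i, j]), ha="center", va="center",
                color="white" if cm.counts[i, j] > thresh else "black", fontsize=9,
            )
    ax.set_xticks(range(cm.n_classes), cm.class_names, rotation=30, ha="right", fontsize=7)
    ax.set_yticks(range(cm.n_classes), cm.class_names, fontsize=7)
    ax.set_xlabel("Predicted class")
    ax.set_ylabel("True class")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = out_dir / f"{prefix}_confusion_matrix.png"
    fig.savefig(path, dpi=100, metadata=png_meta)
    plt.close(fig)
    written["confusion_matrix_png"] = path

    if curves:
        fig, ax = plt.subplots(figsize=(5.0, 3.5))
        for name, values in curves.items():
            ax.plot(range(1, len(values) + 1), values, marker="o", ms=3, label=name)
        ax.set_xlabel("Epoch")
        ax.set_ylabel("Metric value")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"{prefix}_curves.png"
        fig.savefig(path, dpi=100, metadata=png_meta)
        plt.close(fig)
        written["curves_png"] = path

    path = out_dir / f"{prefix}_confusion_matrix.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred", *cm.class_names])
        for name, row in zip(cm.class_names, cm.counts):
            writer.writerow([name, *row.tolist()])
    written["confusion_matrix_csv"] = path

    path = out_dir / f"{prefix}_classification_report.json"
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    written["report_json"] = path
    return written
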
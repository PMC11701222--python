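"""Confusion-matrix evaluation: per-class accuracy, OA, AA, Cohen's kappa.

Conventions follow remote-sensing practice: rows of the confusion matrix are
the true category, columns the predicted one.  With TP_i the diagonal entry,
Total_i the row sum and FP_i the column sum minus the diagonal,

    OA    = sum_i TP_i / sum_i Total_i
    AA    = mean_i TP_i / Total_i
    P_e   = sum_i Total_i * (TP_i + FP_i) / (sum_i Total_i)^2
    kappa = (OA - P_e) / (1 - P_e)

Metrics are held in [0, 1] internally and formatted as percentages in
reports.  When P_e = 1 (degenerate single-cell matrices) kappa is undefined
and reported as such (None) rather than forced to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scene_io import LabelMap


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows = true category, columns = predicted category."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {c.shape}")
        if c.min() < 0:
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def true_positives(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def totals(self) -> np.ndarray:
        """Total_i: all samples whose true category is i (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def false_positives(self) -> np.ndarray:
        """FP_i: samples predicted i whose true category differs."""
        return self.counts.sum(axis=0) - self.true_positives


def confusion(truth: LabelMap, predicted: np.ndarray,
              eval_pixels: np.ndarray) -> ConfusionMatrix:
    """Count (true, predicted) pairs over an evaluation pixel set.

    ``eval_pixels`` is a boolean H x W mask; every selected pixel must be
    labeled in the ground truth.
    """
    mask = np.asarray(eval_pixels, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError("eval mask shape differs from label map")
    if not mask.any():
        raise ValueError("empty evaluation pixel set")
    t = truth.labels[mask]
    if (t == 0).any():
        raise ValueError("evaluation set contains unlabeled ground-truth pixels")
    p = np.asarray(predicted)[mask]
    k = truth.n_classes
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (t - 1, p - 1), 1)
    return ConfusionMatrix(cm)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    total = cm.totals.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(cm.true_positives.sum() / total)


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    totals = cm.totals
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0]) + 1
        raise ValueError(f"category {bad} has no evaluation samples")
    return cm.true_positives / totals


def average_accuracy(cm: ConfusionMatrix) -> float:
    return float(per_class_accuracy(cm).mean())


def expected_agreement(cm: ConfusionMatrix) -> float:
    """Chance-agreement term P_e of Cohen's kappa."""
    total = cm.totals.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    pred_totals = cm.true_positives + cm.false_positives
    return float((cm.totals * pred_totals).sum() / total**2)


def kappa(cm: ConfusionMatrix) -> float | None:
    """Cohen's kappa; None when P_e = 1 (undefined)."""
    pe = expected_agreement(cm)
    if pe == 1.0:
        return None
    return float((overall_accuracy(cm) - pe) / (1.0 - pe))


@dataclass(frozen=True)
class MetricReport:
    """Bundled evaluation results for one prediction map."""

    confusion_matrix: ConfusionMatrix
    per_class: np.ndarray
    oa: float
    aa: float
    pe: float
    kappa: float | None

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricReport":
        return cls(
            confusion_matrix=cm,
            per_class=per_class_accuracy(cm),
            oa=overall_accuracy(cm),
            aa=average_accuracy(cm),
            pe=expected_agreement(cm),
            kappa=kappa(cm),
        )

    def as_dict(self, percent: bool = True) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "per_class": [round(float(a) * scale, 4) for a in self.per_class],
            "oa": round(self.oa * scale, 4),
            "aa": round(self.aa * scale, 4),
            "pe": round(self.pe, 6),
            "kappa": None if self.kappa is None else round(self.kappa * scale, 4),
            "units": "percent" if percent else "fraction",
        }

    def save_json(self, path: str | Path, percent: bool = True) -> None:
        Path(path).write_text(json.dumps(self.as_dict(percent), indent=2) + "\n")

    def per_class_table(self) -> list[tuple[int, float]]:
        """(category, accuracy-percent) rows, benchmark-table layout."""
        return [(i + 1, float(a) * 100.0) for i, a in enumerate(self.per_class)]
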
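"""Spectral voting: fuse per-group, per-category masks into one label map.

Each of the C-2 three-band groups yields one binary mask per category, so
every pixel receives C-2 independent binary predictions per category.  The
vote tally T(a, i) counts the positive predictions for pixel a and category
i across groups; the fused label is the category with the highest tally,
with ties broken toward the smallest category index and pixels whose best
tally falls below ``min_votes`` left unassigned (label 0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scene_io import LabelMap


@dataclass(frozen=True)
class MaskStack:
    """Binary decisions of shape (groups, categories, H, W)."""

    decisions: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.decisions)
        if d.ndim != 4:
            raise ValueError(f"decisions must be 4-D (G, K, H, W), got {d.shape}")
        if d.dtype != bool:
            uniq = np.unique(d)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("decisions must be binary")
            d = d.astype(bool)
        object.__setattr__(self, "decisions", d)

    @property
    def n_groups(self) -> int:
        return self.decisions.shape[0]

    @property
    def n_classes(self) -> int:
        return self.decisions.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, decisions=self.decisions)

    @classmethod
    def load(cls, path: str | Path) -> "MaskStack":
        with np.load(path, allow_pickle=False) as data:
            return cls(decisions=data["decisions"])


@dataclass(frozen=True)
class VoteTally:
    """Per-pixel, per-category positive-prediction counts, (K, H, W)."""

    counts: np.ndarray
    n_groups: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError(f"counts must be 3-D (K, H, W), got {c.shape}")
        if c.min() < 0 or c.max() > self.n_groups:
            raise ValueError("counts must lie in [0, n_groups]")
        object.__setattr__(self, "counts", c.astype(np.int64))


@dataclass(frozen=True)
class VotedLabelMap:
    """Fused labels plus the top-1 minus top-2 vote margin per pixel.

    Label 0 marks pixels left unassigned (best tally below ``min_votes``).
    """

    labels: LabelMap
    margin: np.ndarray

    def save_raster(self, path: str | Path) -> None:
        """Plain-text integer raster, one row of labels per line."""
        np.savetxt(path, self.labels.labels, fmt="%d")

    def save_csv(self, path: str | Path) -> None:
        """(row, col, label, margin) records for assigned pixels."""
        rows, cols = np.nonzero(self.labels.labels > 0)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col", "label", "margin"])
            for r, c in zip(rows, cols):
                writer.writerow([r, c, self.labels.labels[r, c],
                                 self.margin[r, c]])


def tally(stack: MaskStack) -> VoteTally:
    """Count positive group predictions per pixel and category."""
    return VoteTally(counts=stack.decisions.sum(axis=0, dtype=np.int64),
                     n_groups=stack.n_groups)


def assign(vote_tally: VoteTally, min_votes: int = 1) -> VotedLabelMap:
    """Pick the category with the highest tally at each pixel.

    Ties break toward the smallest category index; pixels whose maximum
    tally is below ``min_votes`` stay unassigned (label 0).
    """
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    counts = vote_tally.counts
    k = counts.shape[0]
    best = counts.max(axis=0)
    labels = np.argmax(counts, axis=0) + 1  # np.argmax ties -> smallest index
    labels[best < min_votes] = 0
    if k >= 2:
        top2 = np.partition(counts, k - 2, axis=0)[k - 2]
    else:
        top2 = np.zeros_like(best)
    return VotedLabelMap(labels=LabelMap(labels, k), margin=best - top2)
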
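"""Loading, validation and spectral decomposition of hyperspectral scenes.

A hyperspectral scene is an ``H x W x C`` reflectance cube together with an
integer ground-truth raster (0 = unlabeled).  This module reads the common
container formats (MATLAB ``.mat`` files as distributed with the benchmark
scenes, ENVI binary+header pairs, and numpy ``.npz`` archives), validates
them, slices the cube into overlapping three-band groups for a promptable
segmenter, rescales each group to the segmenter's display range, and samples
the handful of seed labels that initialize the semi-supervised loop.

Band indexing is 1-based in documentation and error messages (group ``j``
covers bands ``(j, j+1, j+2)``) and 0-based internally.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io


class SceneValidationError(ValueError):
    """Raised when a cube or label raster violates its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperspectralCube:
    """An ``H x W x C`` grid of finite reflectance values, C >= 3 bands."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise SceneValidationError(
                f"cube must be 3-D (rows, cols, bands), got shape {v.shape}"
            )
        if v.shape[2] < 3:
            raise SceneValidationError(
                f"cube needs at least 3 bands, got {v.shape[2]}"
            )
        finite_per_band = np.isfinite(v).all(axis=(0, 1))
        if not finite_per_band.all():
            bad = int(np.flatnonzero(~finite_per_band)[0]) + 1
            raise SceneValidationError(
                f"cube contains non-finite values (first offending band: {bad})"
            )
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def band_count(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class LabelMap:
    """Integer ``H x W`` raster with values in {0..K}; 0 means unlabeled."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise SceneValidationError(f"label raster must be 2-D, got {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == lab.astype(np.int64)):
                raise SceneValidationError("label raster must hold integers")
            lab = lab.astype(np.int64)
        else:
            lab = lab.astype(np.int64)
        if lab.min() < 0 or lab.max() > self.n_classes:
            raise SceneValidationError(
                f"labels must lie in 0..{self.n_classes}, "
                f"found range [{lab.min()}, {lab.max()}]"
            )
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_pixel_counts(self) -> dict[int, int]:
        """Pixel count per nonzero category."""
        vals, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass(frozen=True)
class BandGroupSequence:
    """The C-2 overlapping three-band slices of a cube, in band order.

    Group ``j`` (1-based) holds raw bands ``(j, j+1, j+2)``; adjacent groups
    share two bands.  Values are the cube's raw values: rescaling to the
    segmenter's display range is a separate, explicit step
    (:func:`normalize_group`).
    """

    groups: tuple[np.ndarray, ...]

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, idx: int) -> np.ndarray:
        return self.groups[idx]


@dataclass(frozen=True)
class SeedLabelSet:
    """The small labeled set: (row, col, category) triples, balanced per class."""

    entries: tuple[tuple[int, int, int], ...]
    per_class: int

    def by_category(self) -> dict[int, list[tuple[int, int]]]:
        out: dict[int, list[tuple[int, int]]] = {}
        for r, c, k in self.entries:
            out.setdefault(k, []).append((r, c))
        return out

    def pixels(self) -> set[tuple[int, int]]:
        return {(r, c) for r, c, _ in self.entries}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _first_array(container: dict, ndim: int, variable: str | None) -> np.ndarray:
    if variable is not None:
        if variable not in container:
            raise SceneValidationError(
                f"variable {variable!r} not found; available: "
                f"{sorted(k for k in container if not k.startswith('__'))}"
            )
        return np.asarray(container[variable])
    for key in sorted(container):
        if key.startswith("__"):
            continue
        arr = np.asarray(container[key])
        if arr.ndim == ndim and np.issubdtype(arr.dtype, np.number):
            return arr
    raise SceneValidationError(f"no {ndim}-D numeric array found in container")


_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}


def _read_envi(path: Path) -> np.ndarray:
    """Minimal ENVI reader: BSQ/BIL/BIP interleaves, no compression."""
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        hdr_path, data_path = path, path.with_suffix("")
    else:
        hdr_path, data_path = Path(str(path) + ".hdr"), path
        if not hdr_path.exists():
            hdr_path = path.with_suffix(".hdr")
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.M):
        fields[m.group(1).strip().lower()] = m.group(2).strip().strip("{}").strip()
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
    except KeyError as exc:
        raise SceneValidationError(f"ENVI header missing field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    byte_order = int(fields.get("byte order", 0))
    raw = np.fromfile(data_path, dtype=dtype, count=lines * samples * bands)
    if raw.size != lines * samples * bands:
        raise SceneValidationError("ENVI data file shorter than header promises")
    if byte_order == 1:
        raw = raw.byteswap()
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise SceneValidationError(f"unknown ENVI interleave {interleave!r}")
    return cube


def load_cube(path: str | Path, dialect: str = "npz",
              variable: str | None = None) -> HyperspectralCube:
    """Load a hyperspectral cube from a MAT, ENVI or npz container.

    Parameters
    ----------
    path:
        File to read.  For ENVI either the header or the data file.
    dialect:
        ``"mat"``, ``"envi"`` or ``"npz"``.
    variable:
        Variable/array name inside the container; benchmark MAT files use
        dataset-specific names.  When omitted, the first 3-D numeric array
        is taken.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "mat":
        arr = _first_array(scipy.io.loadmat(path), 3, variable)
    elif dialect == "npz":
        with np.load(path, allow_pickle=False) as data:
            container = {k: data[k] for k in data.files}
        key = variable if variable is not None else ("cube" if "cube" in container else None)
        arr = _first_array(container, 3, key)
    elif dialect == "envi":
        arr = _read_envi(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return HyperspectralCube(np.asarray(arr, dtype=np.float64))


def load_labels(path: str | Path, dialect: str = "npz",
                variable: str | None = None,
                n_classes: int | None = None) -> LabelMap:
    """Load a ground-truth raster from a MAT/npz container or a CSV of
    (row, col, label) records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "mat":
        arr = _first_array(scipy.io.loadmat(path), 2, variable)
    elif dialect == "npz":
        with np.load(path, allow_pickle=False) as data:
            container = {k: data[k] for k in data.files}
        key = variable if variable is not None else ("truth" if "truth" in container else None)
        arr = _first_array(container, 2, key)
    elif dialect == "csv":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append((int(rec["row"]), int(rec["col"]), int(rec["label"])))
        if not rows:
            raise SceneValidationError(f"empty label CSV: {path}")
        h = max(r for r, _, _ in rows) + 1
        w = max(c for _, c, _ in rows) + 1
        arr = np.zeros((h, w), dtype=np.int64)
        for r, c, lab in rows:
            arr[r, c] = lab
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    arr = np.asarray(arr)
    k = int(arr.max()) if n_classes is None else n_classes
    return LabelMap(arr, k)


# ---------------------------------------------------------------------------
# decomposition / normalization
# ---------------------------------------------------------------------------


def decompose_bands(cube: HyperspectralCube) -> BandGroupSequence:
    """Slice the cube into its C-2 overlapping three-band groups.

    Group ``j`` (1-based) is the raw band triple ``(j, j+1, j+2)``, so
    adjacent groups share two bands — the redundancy the spectral-voting
    step later exploits.
    """
    c = cube.band_count
    if c < 3:  # unreachable through the validated type, kept for raw arrays
        raise SceneValidationError(f"need at least 3 bands, got {c}")
    groups = tuple(cube.values[:, :, j:j + 3] for j in range(c - 2))
    return BandGroupSequence(groups)


def normalize_group(bands3: np.ndarray, mode: str = "minmax",
                    percentile: float = 2.0) -> np.ndarray:
    """Rescale a three-band slice to the segmenter display range [0, 255].

    Each channel is scaled independently.  ``mode="minmax"`` (default) maps
    the channel's min/max to 0/255; ``mode="percentile"`` stretches between
    the ``percentile`` and ``100-percentile`` quantiles and clips.  A
    constant channel maps to all zeros.
    """
    arr = np.asarray(bands3, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SceneValidationError(f"expected an (H, W, 3) slice, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise SceneValidationError("band group contains non-finite values")
    out = np.zeros_like(arr)
    for ch in range(3):
        channel = arr[:, :, ch]
        if mode == "minmax":
            lo, hi = channel.min(), channel.max()
        elif mode == "percentile":
            lo, hi = np.percentile(channel, [percentile, 100.0 - percentile])
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
        if hi > lo:
            out[:, :, ch] = np.clip((channel - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return out


# ---------------------------------------------------------------------------
# seed sampling
# ---------------------------------------------------------------------------


def sample_seed_labels(gt: LabelMap, per_class: int, seed: int) -> SeedLabelSet:
    """Draw ``per_class`` labeled pixels per category, uniformly without
    replacement, reproducibly under ``seed``.

    Categories are visited in ascending order with a single generator, so a
    fixed seed yields a fixed seed set.  A category with fewer than
    ``per_class`` labeled pixels raises an error naming it.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    counts = gt.class_pixel_counts()
    if not counts:
        raise SceneValidationError("ground truth has no labeled pixels")
    entries: list[tuple[int, int, int]] = []
    for cat in sorted(counts):
        rows, cols = np.nonzero(gt.labels == cat)
        if rows.size < per_class:
            raise SceneValidationError(
                f"category {cat} has only {rows.size} labeled pixels, "
                f"need {per_class}"
            )
        # row-major order before choice keeps the draw independent of
        # np.nonzero's traversal details
        order = np.lexsort((cols, rows))
        rows, cols = rows[order], cols[order]
        pick = rng.choice(rows.size, size=per_class, replace=False)
        for idx in sorted(int(i) for i in pick):
            entries.append((int(rows[idx]), int(cols[idx]), cat))
    return SeedLabelSet(tuple(entries), per_class)
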
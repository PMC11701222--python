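"""Promptable-segmenter contract and the synthetic oracle backend.

The iterative pseudo-labeling loop only needs two capabilities from a
segmenter: ``segment`` (point prompts in, a binary mask with scores out) and
``embed`` (a per-pixel feature field the confidence machinery scores against
prompt features).  This module fixes that contract and provides the oracle
backend, which derives masks and features from a known synthetic scene with
controllable corruption so every downstream stage is testable without
pretrained weights.  An adapter to the pretrained foundation segmenter lives
in :mod:`ipgseg.sam_adapter` as an optional extra.

The oracle's corruption model mimics the failure modes of a real promptable
segmenter on spectrally rendered imagery: independent per-pixel label flips
at rate ``flip_rho`` inside an eligibility band around region boundaries
(boundary indecision), plus optional whole-mask dilation (over-segmentation).
Flips are a deterministic function of (backend seed, band-group image,
category), so different band groups fail independently — which is exactly
the redundancy spectral voting averages away — while repeated calls on the
same group reproduce bit-identical results.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

FOREGROUND = "foreground"
BACKGROUND = "background"


@dataclass(frozen=True)
class PointPrompt:
    """A pixel coordinate tagged foreground or background."""

    row: int
    col: int
    polarity: str = FOREGROUND
    provenance: str = "seed"

    def __post_init__(self) -> None:
        if self.polarity not in (FOREGROUND, BACKGROUND):
            raise ValueError(f"polarity must be foreground/background, got {self.polarity!r}")


class PromptSet:
    """Per-category collections of point prompts.

    Enforces that a pixel appears at most once in a category's list and that
    every category present has at least one foreground prompt before it is
    used for segmentation.
    """

    def __init__(self) -> None:
        self._prompts: dict[int, list[PointPrompt]] = {}
        self._pixels: dict[int, set[tuple[int, int]]] = {}

    def add(self, category: int, prompt: PointPrompt) -> None:
        pix = (prompt.row, prompt.col)
        seen = self._pixels.setdefault(category, set())
        if pix in seen:
            raise ValueError(
                f"pixel {pix} already prompted for category {category}"
            )
        seen.add(pix)
        self._prompts.setdefault(category, []).append(prompt)

    def categories(self) -> list[int]:
        return sorted(self._prompts)

    def for_category(self, category: int) -> list[PointPrompt]:
        return list(self._prompts.get(category, []))

    def foreground(self, category: int) -> list[PointPrompt]:
        return [p for p in self._prompts.get(category, []) if p.polarity == FOREGROUND]

    def background(self, category: int) -> list[PointPrompt]:
        return [p for p in self._prompts.get(category, []) if p.polarity == BACKGROUND]

    def counts(self) -> dict[int, int]:
        return {k: len(v) for k, v in self._prompts.items()}

    def all_pixels(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for pix in self._pixels.values():
            out |= pix
        return out

    def to_records(self) -> list[dict]:
        recs = []
        for cat in self.categories():
            for p in self._prompts[cat]:
                recs.append({"row": p.row, "col": p.col, "category": cat,
                             "polarity": p.polarity, "provenance": p.provenance})
        return recs


@dataclass(frozen=True)
class SegmentationResult:
    """Binary mask plus per-pixel score in [0, 1] for one (group, category).

    Invariant: ``mask = score >= mask_threshold`` with threshold 0.5.
    """

    mask: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.shape != self.score.shape:
            raise ValueError("mask and score shapes differ")
        if self.score.min() < 0.0 or self.score.max() > 1.0:
            raise ValueError("scores must lie in [0, 1]")


@dataclass(frozen=True)
class FeatureField:
    """Per-pixel embedding vectors, ``H x W x D``."""

    embedding: np.ndarray
    source: str = "oracle"

    def __post_init__(self) -> None:
        if self.embedding.ndim != 3 or self.embedding.shape[2] < 2:
            raise ValueError("embedding must be H x W x D with D >= 2")

    def at(self, row: int, col: int) -> np.ndarray:
        return self.embedding[row, col]


# ---------------------------------------------------------------------------
# trainable prompt projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromptProjection:
    """The only trainable part of the backend: a D x D linear map applied to
    embedding vectors before similarity scoring.  Everything else is frozen."""

    weight: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weight, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"projection must be square, got {w.shape}")
        object.__setattr__(self, "weight", w)

    @classmethod
    def identity(cls, dim: int) -> "PromptProjection":
        return cls(np.eye(dim))

    def apply(self, feats: np.ndarray) -> np.ndarray:
        """Project feature vectors; accepts (..., D) arrays."""
        return np.asarray(feats) @ self.weight.T


def prompt_projection_step(projection: PromptProjection, gradient: np.ndarray,
                           learning_rate: float) -> PromptProjection:
    """One plain gradient step on the projection; all other parameters stay
    frozen.  A non-finite gradient skips the step with a warning."""
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    grad = np.asarray(gradient, dtype=np.float64)
    if grad.shape != projection.weight.shape:
        raise ValueError(
            f"gradient shape {grad.shape} does not match projection "
            f"{projection.weight.shape}"
        )
    if not np.isfinite(grad).all():
        warnings.warn("non-finite gradient; projection step skipped", RuntimeWarning)
        return projection
    if learning_rate == 0.0:
        return projection
    return PromptProjection(projection.weight - learning_rate * grad)


# ---------------------------------------------------------------------------
# oracle backend
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OracleBundle:
    """Everything the oracle backend knows about a synthetic scene.

    ``truth`` is the full-coverage class raster, ``signatures`` the K x C
    per-class spectral curves that double as class feature vectors,
    ``flip_rho`` the per-pixel flip probability inside the boundary
    eligibility band of half-width ``boundary_band``, ``dilate_iters`` an
    optional whole-mask dilation, and ``feature_noise_sd`` the i.i.d.
    Gaussian noise added to embedding vectors.
    """

    truth: np.ndarray
    signatures: np.ndarray
    flip_rho: float = 0.0
    boundary_band: int = 2
    dilate_iters: int = 0
    feature_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_rho <= 1.0:
            raise ValueError("flip_rho must lie in [0, 1]")
        if self.truth.min() < 1:
            raise ValueError("oracle truth must label every pixel (values >= 1)")

    @property
    def n_classes(self) -> int:
        return self.signatures.shape[0]

    def save(self, path: str | Path) -> None:
        meta = {"flip_rho": self.flip_rho, "boundary_band": self.boundary_band,
                "dilate_iters": self.dilate_iters,
                "feature_noise_sd": self.feature_noise_sd, "seed": self.seed}
        np.savez_compressed(path, truth=self.truth, signatures=self.signatures,
                            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "OracleBundle":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            return cls(truth=data["truth"], signatures=data["signatures"], **meta)


def _image_seed(base_seed: int, image3: np.ndarray, salt: int = 0) -> np.random.Generator:
    """Deterministic generator keyed to the image content (hence to the band
    group) and a salt, independent of prompt ordering."""
    crc = zlib.crc32(np.ascontiguousarray(image3, dtype=np.float64).tobytes())
    return np.random.default_rng(np.random.SeedSequence([base_seed, crc, salt]))


class OracleSegmenter:
    """Synthetic segmenter that answers prompts from known ground truth.

    ``segment`` identifies the prompted category from the ground-truth labels
    under the foreground prompts (majority; ties to the smallest category)
    and returns that category's true region, corrupted by boundary-band
    flips and optional dilation.  ``embed`` returns each pixel's class
    signature plus Gaussian noise.  Both are bit-deterministic functions of
    (bundle seed, image, prompts).
    """

    source = "oracle"

    def __init__(self, bundle: OracleBundle) -> None:
        self.bundle = bundle
        self._eligible: dict[int, np.ndarray] = {}
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}
        for cat in range(1, bundle.n_classes + 1):
            region = bundle.truth == cat
            if bundle.boundary_band > 0:
                grown = ndimage.binary_dilation(region, iterations=bundle.boundary_band)
                shrunk = ndimage.binary_erosion(region, iterations=bundle.boundary_band)
                self._eligible[cat] = grown & ~shrunk
            else:
                self._eligible[cat] = np.zeros_like(region)

    @property
    def feature_dim(self) -> int:
        return self.bundle.signatures.shape[1]

    # -- contract -----------------------------------------------------------

    def segment(self, image3: np.ndarray, prompts: list[PointPrompt]) -> SegmentationResult:
        h, w = self.bundle.truth.shape
        fg = [p for p in prompts if p.polarity == FOREGROUND]
        if not fg:
            raise ValueError("at least one foreground prompt is required")
        for p in prompts:
            if not (0 <= p.row < h and 0 <= p.col < w):
                raise ValueError(f"prompt ({p.row}, {p.col}) outside {h}x{w} image")
        cats = np.array([self.bundle.truth[p.row, p.col] for p in fg])
        vals, counts = np.unique(cats, return_counts=True)
        category = int(vals[np.argmax(counts)])  # ties -> smallest category

        crc = zlib.crc32(np.ascontiguousarray(image3, dtype=np.float64).tobytes())
        key = (crc, category)
        if key not in self._mask_cache:
            mask = (self.bundle.truth == category).copy()
            if self.bundle.flip_rho > 0.0:
                rng = _image_seed(self.bundle.seed, image3, salt=category)
                flips = (rng.random((h, w)) < self.bundle.flip_rho) & self._eligible[category]
                mask ^= flips
            if self.bundle.dilate_iters > 0:
                mask = ndimage.binary_dilation(mask, iterations=self.bundle.dilate_iters)
            self._mask_cache[key] = mask
        mask = self._mask_cache[key]
        return SegmentationResult(mask=mask, score=mask.astype(np.float64))

    def embed(self, image3: np.ndarray) -> FeatureField:
        sig = self.bundle.signatures
        emb = sig[self.bundle.truth - 1].astype(np.float64)
        if self.bundle.feature_noise_sd > 0.0:
            rng = _image_seed(self.bundle.seed, image3, salt=0)
            emb = emb + rng.normal(0.0, self.bundle.feature_noise_sd, size=emb.shape)
        return FeatureField(embedding=emb, source=self.source)
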
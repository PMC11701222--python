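"""Synthetic hyperspectral scenes with known structure.

Real benchmark scenes (agricultural and urban land-cover mosaics) consist of
a few spatially contiguous class regions whose per-pixel spectra are smooth
curves over the band index, distorted by sensor noise.  The generator
emulates exactly that: K contiguous regions (Voronoi cells or randomly grown
blobs), one smooth signature per class built from Gaussian bumps over the
band axis with a guaranteed minimum pairwise angular separation, and i.i.d.
additive Gaussian noise.  Smooth signatures make adjacent three-band groups
look alike, which is the redundancy the spectral-voting stage relies on.

Because the class regions and signatures are known, the scene also exports
the oracle knowledge (:class:`~ipgseg.segmenter.OracleBundle`) that drives
the synthetic segmenter backend.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .scene_io import HyperspectralCube, LabelMap
from .segmenter import OracleBundle


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene.

    The defaults are the desk-scale study conditions used throughout the
    tests: a 64x64 scene with 24 bands (hence 22 three-band groups), four
    classes, signatures at least 45 degrees apart, and mild spectral noise.
    """

    height: int = 64
    width: int = 64
    bands: int = 24
    classes: int = 4
    region_model: str = "voronoi"  # or "grown-blobs"
    bumps_per_class: int = 3
    theta_min_deg: float = 45.0
    noise_sd: float = 0.05
    min_region_pixels: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.bands < 3:
            raise ValueError("need at least 3 bands")
        if self.theta_min_deg <= 0:
            raise ValueError("theta_min_deg must be positive")
        if self.region_model not in ("voronoi", "grown-blobs"):
            raise ValueError(f"unknown region model {self.region_model!r}")
        if self.height * self.width < self.classes * self.min_region_pixels:
            raise ValueError("scene too small for the requested regions")


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene: cube, full-coverage truth, signatures, spec echo."""

    cube: HyperspectralCube
    truth: LabelMap
    signatures: np.ndarray
    spec: SceneSpec


class SceneGenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the spec."""


# Moderate-corruption study conditions for the oracle backend, calibrated so
# that a single band group misassigns roughly 10-20% of pixels on the default
# scene — the regime where spectral voting and confidence gating have real
# work to do.  Tests and the acceptance script share these values.
MODERATE_FLIP_RHO = 0.3
MODERATE_BOUNDARY_BAND = 3
MODERATE_FEATURE_NOISE_SD = 0.08


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def _draw_signature(rng: np.random.Generator, bands: int, n_bumps: int) -> np.ndarray:
    """A smooth nonnegative curve: baseline plus Gaussian bumps over band index."""
    axis = np.arange(bands, dtype=np.float64)
    sig = np.full(bands, 0.05)
    for _ in range(n_bumps):
        amp = rng.uniform(0.5, 1.0)
        center = rng.uniform(0, bands - 1)
        width = rng.uniform(0.8, max(1.2, bands / 10))
        sig += amp * np.exp(-0.5 * ((axis - center) / width) ** 2)
    return sig


def _sample_signatures(rng: np.random.Generator, spec: SceneSpec,
                       max_tries: int = 200, restarts: int = 25) -> np.ndarray:
    """Draw K signatures with pairwise angle >= theta_min.

    Rejection sampling with global restarts: each class gets ``max_tries``
    draws against the signatures placed so far, and an unlucky early
    configuration is discarded entirely rather than blocking the rest.
    """
    cos_max = np.cos(np.deg2rad(spec.theta_min_deg))
    for _ in range(restarts):
        sigs: list[np.ndarray] = []
        for _ in range(spec.classes):
            for _ in range(max_tries):
                cand = _draw_signature(rng, spec.bands, spec.bumps_per_class)
                unit = cand / np.linalg.norm(cand)
                if all(float(unit @ (s / np.linalg.norm(s))) <= cos_max + 1e-12
                       for s in sigs):
                    sigs.append(cand)
                    break
            else:
                break
        if len(sigs) == spec.classes:
            return np.stack(sigs)
    raise SceneGenerationError(
        f"could not place {spec.classes} signatures with pairwise "
        f"separation >= {spec.theta_min_deg} degrees in {restarts} rounds "
        f"of {max_tries} draws; relax theta_min or add bands"
    )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


def _distinct_sites(rng: np.random.Generator, h: int, w: int, k: int) -> np.ndarray:
    flat = rng.choice(h * w, size=k, replace=False)
    return np.stack([flat // w, flat % w], axis=1)


def _voronoi_regions(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(50):
        sites = _distinct_sites(rng, h, w, spec.classes)
        d2 = ((rr[None] - sites[:, 0, None, None]) ** 2
              + (cc[None] - sites[:, 1, None, None]) ** 2)
        labels = np.argmin(d2, axis=0) + 1  # ties -> smallest class index
        counts = np.bincount(labels.ravel(), minlength=spec.classes + 1)[1:]
        if counts.min() >= spec.min_region_pixels:
            return labels
    raise SceneGenerationError("could not draw Voronoi regions meeting the "
                               "minimum region size; lower min_region_pixels")


def _grown_blob_regions(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Round-robin randomized flood fill from K sources.

    Each class grows one frontier pixel per turn (random priority within
    its own frontier), so regions stay 4-connected, irregular in outline,
    and close to balanced in size.
    """
    h, w = spec.height, spec.width
    for _ in range(50):
        labels = np.zeros((h, w), dtype=np.int64)
        frontiers: list[list[tuple[float, int, int]]] = [[] for _ in range(spec.classes)]
        for k, (r, c) in enumerate(_distinct_sites(rng, h, w, spec.classes), start=1):
            heapq.heappush(frontiers[k - 1], (rng.random(), int(r), int(c)))
        active = True
        while active:
            active = False
            for k in range(1, spec.classes + 1):
                heap = frontiers[k - 1]
                while heap:
                    _, r, c = heapq.heappop(heap)
                    if labels[r, c]:
                        continue
                    labels[r, c] = k
                    active = True
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < h and 0 <= nc < w and not labels[nr, nc]:
                            heapq.heappush(heap, (rng.random(), nr, nc))
                    break
        counts = np.bincount(labels.ravel(), minlength=spec.classes + 1)[1:]
        if counts.min() >= spec.min_region_pixels:
            return labels
    raise SceneGenerationError("could not grow blob regions meeting the "
                               "minimum region size; lower min_region_pixels")


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate a scene deterministically from its spec.

    Every pixel's spectrum is its class signature plus i.i.d. Gaussian noise
    of standard deviation ``spec.noise_sd``; at ``noise_sd=0`` spectra equal
    the signatures exactly.
    """
    rng = np.random.default_rng(spec.seed)
    signatures = _sample_signatures(rng, spec)
    if spec.region_model == "voronoi":
        truth = _voronoi_regions(rng, spec)
    else:
        truth = _grown_blob_regions(rng, spec)
    cube = signatures[truth - 1].astype(np.float64)
    if spec.noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.noise_sd, size=cube.shape)
    return SyntheticScene(
        cube=HyperspectralCube(cube),
        truth=LabelMap(truth, spec.classes),
        signatures=signatures,
        spec=spec,
    )


def export_oracle(scene: SyntheticScene, flip_rho: float = 0.0,
                  boundary_band: int = 2, dilate_iters: int = 0,
                  feature_noise_sd: float = 0.0,
                  seed: int | None = None) -> OracleBundle:
    """Package the scene's ground truth for the oracle segmenter backend.

    ``flip_rho``/``boundary_band``/``dilate_iters`` set the segmentation
    corruption level and ``feature_noise_sd`` the embedding noise; the seed
    defaults to the scene's own.
    """
    return OracleBundle(
        truth=scene.truth.labels,
        signatures=scene.signatures,
        flip_rho=flip_rho,
        boundary_band=boundary_band,
        dilate_iters=dilate_iters,
        feature_noise_sd=feature_noise_sd,
        seed=scene.spec.seed if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_scene(scene: SyntheticScene, path: str | Path) -> None:
    """Write the scene as a compressed-array container readable by scene_io
    (cube under ``cube``, truth under ``truth``) plus the spec as JSON."""
    spec_json = json.dumps(asdict(scene.spec))
    np.savez_compressed(
        path,
        cube=scene.cube.values,
        truth=scene.truth.labels,
        signatures=scene.signatures,
        spec=np.frombuffer(spec_json.encode(), dtype=np.uint8),
    )


def load_scene(path: str | Path) -> SyntheticScene:
    with np.load(path, allow_pickle=False) as data:
        spec = SceneSpec(**json.loads(bytes(data["spec"]).decode()))
        return SyntheticScene(
            cube=HyperspectralCube(data["cube"]),
            truth=LabelMap(data["truth"], spec.classes),
            signatures=np.asarray(data["signatures"]),
            spec=spec,
        )
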
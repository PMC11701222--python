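"""Patch-based classification: dataset assembly, CNN training, map prediction.

Every labeled pixel (seed or pseudo label) contributes one 9x9 spectral
window centered on it, reflect-padded at scene borders; the center pixel
defines the patch label.  Patches are standardized per band with statistics
taken from the training patches, the small CNN from :mod:`ipgseg.cnn` is
trained with SGD (learning rate 0.05, momentum 0.7, weight decay 1e-4), and
the trained model predicts a full-coverage label map with per-pixel class
probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cnn import SGD, PatchCNN
from .scene_io import HyperspectralCube, LabelMap, SeedLabelSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Classifier hyperparameters; the SGD settings are the framework's
    standard values, epoch count and batch size are package defaults."""

    learning_rate: float = 0.05
    momentum: float = 0.7
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    widths: tuple[int, int] = (32, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass(frozen=True)
class PatchDataset:
    """9x9 windows centered on labeled pixels, with per-patch categories."""

    patches: np.ndarray          # (N, size, size, C)
    labels: np.ndarray           # (N,) categories in 1..K
    coords: np.ndarray           # (N, 2) row, col of the center pixel
    n_classes: int
    splits: np.ndarray | None = None   # optional per-patch tags

    def __len__(self) -> int:
        return self.patches.shape[0]


@dataclass
class TrainedClassifier:
    """A trained CNN plus the band statistics needed to reuse it."""

    model: PatchCNN
    band_mean: np.ndarray
    band_sd: np.ndarray
    patch_size: int
    n_classes: int
    epoch_losses: list[float]


@dataclass(frozen=True)
class PredictionMap:
    """Full-coverage predicted labels and per-pixel class probabilities."""

    labels: LabelMap
    scores: np.ndarray           # (H, W, K), rows sum to 1

    def __post_init__(self) -> None:
        if (self.labels.labels < 1).any():
            raise ValueError("prediction map must assign every pixel a category")


def extract_patches(cube: HyperspectralCube, labels: LabelMap,
                    size: int = 9) -> PatchDataset:
    """One patch per labeled pixel; reflect padding supplies border context."""
    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    if labels.shape != (cube.height, cube.width):
        raise ValueError("label raster shape differs from cube")
    half = size // 2
    padded = np.pad(cube.values, ((half, half), (half, half), (0, 0)),
                    mode="reflect")
    rows, cols = np.nonzero(labels.labels > 0)
    patches = np.empty((rows.size, size, size, cube.band_count),
                       dtype=cube.values.dtype)
    for i, (r, c) in enumerate(zip(rows, cols)):
        patches[i] = padded[r:r + size, c:c + size, :]
    return PatchDataset(
        patches=patches,
        labels=labels.labels[rows, cols],
        coords=np.stack([rows, cols], axis=1),
        n_classes=labels.n_classes,
    )


def build_training_set(seeds: SeedLabelSet, pseudo: list[tuple[int, int, int]],
                       shape: tuple[int, int], n_classes: int) -> LabelMap:
    """Union of seed and pseudo labels as a raster.

    On a pixel conflict the seed (ground-truth) label wins and the conflict
    is logged; pseudo entries are (row, col, category).
    """
    raster = np.zeros(shape, dtype=np.int64)
    for r, c, k in pseudo:
        raster[r, c] = k
    for r, c, k in seeds.entries:
        if raster[r, c] not in (0, k):
            logger.warning(
                "pixel (%d, %d): pseudo label %d overridden by seed label %d",
                r, c, raster[r, c], k,
            )
        raster[r, c] = k
    return LabelMap(raster, n_classes)


def _standardize(patches: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return ((patches - mean) / sd).astype(np.float64)


def train_classifier(data: PatchDataset, cfg: TrainConfig) -> TrainedClassifier:
    """Train the patch CNN; deterministic given ``cfg.seed``.

    Requires at least one patch per category.  Per-epoch mean training loss
    is recorded.
    """
    present = np.unique(data.labels)
    missing = sorted(set(range(1, data.n_classes + 1)) - {int(v) for v in present})
    if missing:
        raise ValueError(f"no training patches for categories {missing}")

    mean = data.patches.mean(axis=(0, 1, 2))
    sd = data.patches.std(axis=(0, 1, 2))
    sd = np.where(sd > 0, sd, 1.0)
    x = _standardize(data.patches, mean, sd).transpose(0, 3, 1, 2)  # NCHW
    y = data.labels.astype(np.int64) - 1

    model = PatchCNN(in_channels=x.shape[1], n_classes=data.n_classes,
                     widths=cfg.widths, seed=cfg.seed)
    opt = SGD(cfg.learning_rate, cfg.momentum, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)

    epoch_losses: list[float] = []
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grads(x[idx], y[idx])
            model.set_parameters(opt.step(model.parameters(), grads))
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
    return TrainedClassifier(
        model=model, band_mean=mean, band_sd=sd,
        patch_size=data.patches.shape[1], n_classes=data.n_classes,
        epoch_losses=epoch_losses,
    )


def save_checkpoint(clf: TrainedClassifier, path) -> None:
    """Persist parameters, band statistics and training curve as arrays."""
    payload = {f"param/{k}": v for k, v in clf.model.parameters().items()}
    payload.update(
        band_mean=clf.band_mean, band_sd=clf.band_sd,
        meta=np.array([clf.patch_size, clf.n_classes]),
        epoch_losses=np.asarray(clf.epoch_losses),
    )
    np.savez_compressed(path, **payload)


def load_checkpoint(path) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as data:
        params = {k.removeprefix("param/"): data[k]
                  for k in data.files if k.startswith("param/")}
        patch_size, n_classes = (int(v) for v in data["meta"])
        w1 = params["conv1.weight"].shape[0]
        w2 = params["conv2.weight"].shape[0]
        model = PatchCNN(in_channels=params["conv1.weight"].shape[1],
                         n_classes=n_classes, widths=(w1, w2))
        model.set_parameters(params)
        return TrainedClassifier(
            model=model, band_mean=data["band_mean"], band_sd=data["band_sd"],
            patch_size=patch_size, n_classes=n_classes,
            epoch_losses=[float(v) for v in data["epoch_losses"]],
        )


def predict_map(clf: TrainedClassifier, cube: HyperspectralCube,
                chunk: int = 512) -> PredictionMap:
    """Classify every pixel of the cube with the trained model."""
    mean_c = clf.band_mean.shape[0]
    if cube.band_count != mean_c:
        raise ValueError(
            f"cube has {cube.band_count} bands but the model was trained "
            f"on {mean_c}"
        )
    size, half = clf.patch_size, clf.patch_size // 2
    padded = np.pad(cube.values, ((half, half), (half, half), (0, 0)),
                    mode="reflect")
    h, w = cube.height, cube.width
    coords = [(r, c) for r in range(h) for c in range(w)]
    scores = np.empty((h * w, clf.n_classes))
    for start in range(0, len(coords), chunk):
        block = coords[start:start + chunk]
        batch = np.stack([padded[r:r + size, c:c + size, :] for r, c in block])
        xb = _standardize(batch, clf.band_mean, clf.band_sd).transpose(0, 3, 1, 2)
        scores[start:start + len(block)] = clf.model.softmax(clf.model.forward(xb))
    scores = scores.reshape(h, w, clf.n_classes)
    labels = scores.argmax(axis=2) + 1
    return PredictionMap(labels=LabelMap(labels, clf.n_classes), scores=scores)
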
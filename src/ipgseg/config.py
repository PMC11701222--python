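"""Schema-validated run configuration.

A run is described by one YAML document with nested sections mirroring the
pipeline stages.  Validation is strict: unknown keys are rejected before any
stage executes, and the single global seed fans out to per-stage seeds by
stable hashing of the stage name, so each stage is individually reproducible
without user-side seed bookkeeping.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classifier import TrainConfig
from .confidence import Thresholds
from .loop import IPGConfig
from .synthetic import SceneSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneSection(_Strict):
    height: int = 64
    width: int = 64
    bands: int = 24
    classes: int = 4
    region_model: str = "voronoi"
    bumps_per_class: int = 3
    theta_min_deg: float = 45.0
    noise_sd: float = 0.05
    min_region_pixels: int = 64

    def to_spec(self, seed: int) -> SceneSpec:
        return SceneSpec(seed=seed, **self.model_dump())


class OracleSection(_Strict):
    """Corruption level of the oracle segmenter backend."""

    flip_rho: float = 0.0
    boundary_band: int = 2
    dilate_iters: int = 0
    feature_noise_sd: float = 0.0


class InputSection(_Strict):
    """External scene files; when ``cube_path`` is unset the scene section
    drives the synthetic generator instead."""

    cube_path: str | None = None
    cube_dialect: str = "mat"
    cube_variable: str | None = None
    labels_path: str | None = None
    labels_dialect: str = "mat"
    labels_variable: str | None = None


class IPGSection(_Strict):
    iterations: int = 50
    selections_per_class: int = 1
    tau_high: float = 0.8
    tau_low: float = 0.5
    kappa_high: float = 0.2
    min_votes: int = 1
    projection_lr: float = 0.01
    normalize_mode: str = "minmax"
    seeds_per_class: int = 5

    def to_config(self, seed: int) -> IPGConfig:
        return IPGConfig(
            iterations=self.iterations,
            selections_per_class=self.selections_per_class,
            thresholds=Thresholds(self.tau_high, self.tau_low, self.kappa_high),
            min_votes=self.min_votes,
            projection_lr=self.projection_lr,
            normalize_mode=self.normalize_mode,
            seed=seed,
        )


class TrainSection(_Strict):
    learning_rate: float = 0.05
    momentum: float = 0.7
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    widths: tuple[int, int] = (32, 64)
    patch_size: int = 9

    def to_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            weight_decay=self.weight_decay, epochs=self.epochs,
            batch_size=self.batch_size, widths=tuple(self.widths), seed=seed,
        )


class RunConfig(_Strict):
    seed: int = 0
    backend: str = "oracle"
    output_dir: str = "runs/default"
    checkpoint: str | None = None  # foundation backend only
    scene: SceneSection = Field(default_factory=SceneSection)
    oracle: OracleSection = Field(default_factory=OracleSection)
    inputs: InputSection = Field(default_factory=InputSection)
    ipg: IPGSection = Field(default_factory=IPGSection)
    train: TrainSection = Field(default_factory=TrainSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed = stable hash of (global seed, stage name), below 2^31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)
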
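import numpy as np
import pytest

from ipgseg import (
    OracleSegmenter,
    SceneSpec,
    export_oracle,
    generate_scene,
    sample_seed_labels,
)


@pytest.fixture(scope="session")
def zero_noise_scene():
    """32x32, 12 bands, 3 classes, spectra exactly equal to signatures."""
    return generate_scene(SceneSpec(height=32, width=32, bands=12, classes=3,
                                    min_region_pixels=32, noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def noisy_scene():
    """Same geometry with mild spectral noise."""
    return generate_scene(SceneSpec(height=32, width=32, bands=12, classes=3,
                                    min_region_pixels=32, noise_sd=0.05, seed=1))


@pytest.fixture()
def clean_backend(zero_noise_scene):
    return OracleSegmenter(export_oracle(zero_noise_scene))


@pytest.fixture()
def zero_noise_seeds(zero_noise_scene):
    return sample_seed_labels(zero_noise_scene.truth, per_class=5, seed=7)


def ledger_precision(entries, truth: np.ndarray) -> float:
    """Fraction of pseudo labels matching the ground-truth raster."""
    if not entries:
        return float("nan")
    hits = sum(truth[e.row, e.col] == e.category for e in entries)
    return hits / len(entries)
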
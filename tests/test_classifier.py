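import numpy as np
import pytest

from ipgseg.classifier import (
    TrainConfig,
    build_training_set,
    extract_patches,
    predict_map,
    train_classifier,
)
from ipgseg.scene_io import HyperspectralCube, LabelMap, SeedLabelSet


def _toy_cube(h=12, w=12, c=4, seed=0):
    rng = np.random.default_rng(seed)
    return HyperspectralCube(rng.uniform(0, 1, size=(h, w, c)))


class TestExtractPatches:
    def test_even_size_rejected(self):
        cube = _toy_cube()
        labels = LabelMap(np.ones((12, 12), dtype=int), 1)
        with pytest.raises(ValueError):
            extract_patches(cube, labels, size=8)

    def test_interior_patch_equals_raw_window(self):
        cube = _toy_cube()
        labels = np.zeros((12, 12), dtype=int)
        labels[6, 6] = 1
        ds = extract_patches(cube, LabelMap(labels, 1), size=5)
        np.testing.assert_array_equal(ds.patches[0], cube.values[4:9, 4:9, :])
        assert ds.labels[0] == 1

    def test_corner_patch_uses_reflection(self):
        cube = _toy_cube()
        labels = np.zeros((12, 12), dtype=int)
        labels[0, 0] = 1
        ds = extract_patches(cube, LabelMap(labels, 1), size=5)
        assert ds.patches.shape == (1, 5, 5, 4)
        # reflect padding: row -1 mirrors row 1, col -1 mirrors col 1
        np.testing.assert_array_equal(ds.patches[0, 1, 1], cube.values[1, 1])
        np.testing.assert_array_equal(ds.patches[0, 2, 2], cube.values[0, 0])
        np.testing.assert_array_equal(ds.patches[0, 0, 2], cube.values[2, 0])

    def test_one_patch_per_labeled_pixel(self):
        cube = _toy_cube(20, 20, 3)
        rng = np.random.default_rng(1)
        labels = np.zeros((20, 20), dtype=int)
        flat = rng.choice(400, size=145, replace=False)
        labels[flat // 20, flat % 20] = rng.integers(1, 4, size=145)
        ds = extract_patches(cube, LabelMap(labels, 3), size=9)
        assert len(ds) == 145
        assert ds.patches.shape == (145, 9, 9, 3)


class TestBuildTrainingSet:
    def _seeds(self):
        return SeedLabelSet(((0, 0, 1), (5, 5, 2)), per_class=1)

    def test_empty_pseudo_gives_seeds_only(self):
        lm = build_training_set(self._seeds(), [], (8, 8), 2)
        assert (lm.labels > 0).sum() == 2
        assert lm.labels[0, 0] == 1 and lm.labels[5, 5] == 2

    def test_disjoint_union_adds(self):
        lm = build_training_set(self._seeds(), [(1, 1, 2), (2, 2, 1)], (8, 8), 2)
        assert (lm.labels > 0).sum() == 4

    def test_conflict_resolved_toward_seed(self, caplog):
        with caplog.at_level("WARNING"):
            lm = build_training_set(self._seeds(), [(0, 0, 2)], (8, 8), 2)
        assert lm.labels[0, 0] == 1
        assert "overridden" in caplog.text


class TestTrainClassifier:
    def _separable_dataset(self, n_per_class=20, seed=0):
        """Two classes with well-separated constant spectra."""
        rng = np.random.default_rng(seed)
        h = w = 16
        cube_vals = np.zeros((h, w, 4))
        labels = np.zeros((h, w), dtype=int)
        for i in range(n_per_class):
            r, c = divmod(i, w)
            cube_vals[r, c] = [1, 0, 0, 0] + rng.normal(0, 0.01, 4)
            labels[r, c] = 1
            cube_vals[r + 8, c] = [0, 0, 0, 1] + rng.normal(0, 0.01, 4)
            labels[r + 8, c] = 2
        cube = HyperspectralCube(cube_vals)
        return extract_patches(cube, LabelMap(labels, 2), size=5), cube

    def test_separable_classes_reach_full_training_accuracy(self):
        ds, _ = self._separable_dataset()
        clf = train_classifier(ds, TrainConfig(epochs=60, batch_size=16,
                                               widths=(8, 8), seed=0))
        x = ((ds.patches - clf.band_mean) / clf.band_sd).transpose(0, 3, 1, 2)
        pred = clf.model.forward(x).argmax(axis=1) + 1
        assert (pred == ds.labels).mean() == 1.0

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        ds, _ = self._separable_dataset()
        cfg = TrainConfig(learning_rate=0.0, momentum=0.0, weight_decay=0.0,
                          epochs=1, widths=(4, 4), seed=3)
        clf = train_classifier(ds, cfg)
        from ipgseg.cnn import PatchCNN
        fresh = PatchCNN(4, 2, widths=(4, 4), seed=3)
        for name, p in fresh.parameters().items():
            np.testing.assert_array_equal(clf.model.parameters()[name], p)

    def test_same_seed_reproduces_loss_trajectory(self):
        ds, _ = self._separable_dataset()
        cfg = TrainConfig(epochs=10, widths=(4, 4), seed=5)
        a = train_classifier(ds, cfg)
        b = train_classifier(ds, cfg)
        np.testing.assert_allclose(a.epoch_losses, b.epoch_losses, rtol=1e-12)

    def test_missing_category_rejected(self):
        ds, _ = self._separable_dataset()
        broken = type(ds)(patches=ds.patches[ds.labels == 1],
                          labels=ds.labels[ds.labels == 1],
                          coords=ds.coords[ds.labels == 1], n_classes=2)
        with pytest.raises(ValueError, match=r"categories \[2\]"):
            train_classifier(broken, TrainConfig(epochs=1))


class TestPredictMap:
    def test_scores_are_distributions_and_map_covers_scene(self):
        ds, cube = TestTrainClassifier()._separable_dataset()
        clf = train_classifier(ds, TrainConfig(epochs=30, batch_size=16,
                                               widths=(8, 8), seed=0))
        pred = predict_map(clf, cube)
        np.testing.assert_allclose(pred.scores.sum(axis=2), 1.0, rtol=1e-9)
        assert pred.labels.labels.min() >= 1

    def test_separable_scene_recovered_on_held_out_pixels(self):
        ds, cube = TestTrainClassifier()._separable_dataset()
        clf = train_classifier(ds, TrainConfig(epochs=60, batch_size=16,
                                               widths=(8, 8), seed=0))
        pred = predict_map(clf, cube)
        # the labeled block rows generalize to the unlabeled remainder
        assert (pred.labels.labels[:2, :] == 1).mean() > 0.95
        assert (pred.labels.labels[8:10, :] == 2).mean() > 0.95

    def test_band_count_mismatch_rejected(self):
        ds, cube = TestTrainClassifier()._separable_dataset()
        clf = train_classifier(ds, TrainConfig(epochs=1, widths=(4, 4)))
        other = HyperspectralCube(np.ones((8, 8, 6)))
        with pytest.raises(ValueError, match="bands"):
            predict_map(clf, other)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        from ipgseg.classifier import load_checkpoint, save_checkpoint

        ds, cube = TestTrainClassifier()._separable_dataset()
        clf = train_classifier(ds, TrainConfig(epochs=10, widths=(4, 4), seed=0))
        save_checkpoint(clf, tmp_path / "model.npz")
        loaded = load_checkpoint(tmp_path / "model.npz")
        a = predict_map(clf, cube)
        b = predict_map(loaded, cube)
        np.testing.assert_array_equal(a.labels.labels, b.labels.labels)
        np.testing.assert_allclose(a.scores, b.scores, rtol=1e-12)
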
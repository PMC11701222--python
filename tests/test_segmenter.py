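import numpy as np
import pytest
from scipy import ndimage

from ipgseg.scene_io import decompose_bands, normalize_group
from ipgseg.segmenter import (
    BACKGROUND,
    FOREGROUND,
    OracleSegmenter,
    PointPrompt,
    PromptProjection,
    PromptSet,
    prompt_projection_step,
)
from ipgseg.synthetic import export_oracle


def _group_image(scene, index=0):
    return normalize_group(decompose_bands(scene.cube)[index])


def _region_prompts(scene, category, n=3):
    rows, cols = np.nonzero(scene.truth.labels == category)
    step = max(1, rows.size // n)
    return [PointPrompt(int(rows[i]), int(cols[i]), FOREGROUND)
            for i in range(0, n * step, step)][:n]


class TestOracleSegment:
    def test_zero_noise_mask_equals_region(self, zero_noise_scene, clean_backend):
        img = _group_image(zero_noise_scene)
        result = clean_backend.segment(img, _region_prompts(zero_noise_scene, 2))
        np.testing.assert_array_equal(result.mask,
                                      zero_noise_scene.truth.labels == 2)
        # mask/score invariant
        np.testing.assert_array_equal(result.mask, result.score >= 0.5)

    def test_prompt_order_invariance(self, zero_noise_scene, clean_backend):
        img = _group_image(zero_noise_scene)
        prompts = _region_prompts(zero_noise_scene, 1) + [
            PointPrompt(*np.argwhere(zero_noise_scene.truth.labels == 2)[0],
                        BACKGROUND)
        ]
        a = clean_backend.segment(img, prompts)
        b = clean_backend.segment(img, prompts[::-1])
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_single_foreground_prompt_suffices(self, zero_noise_scene, clean_backend):
        img = _group_image(zero_noise_scene)
        result = clean_backend.segment(img, _region_prompts(zero_noise_scene, 3, n=1))
        assert result.mask.any()

    def test_no_foreground_prompt_rejected(self, zero_noise_scene, clean_backend):
        img = _group_image(zero_noise_scene)
        with pytest.raises(ValueError, match="foreground"):
            clean_backend.segment(img, [PointPrompt(0, 0, BACKGROUND)])

    def test_out_of_bounds_prompt_rejected(self, zero_noise_scene, clean_backend):
        img = _group_image(zero_noise_scene)
        with pytest.raises(ValueError, match="outside"):
            clean_backend.segment(img, [PointPrompt(99, 0, FOREGROUND)])

    def test_flip_noise_binomial_agreement(self, zero_noise_scene):
        backend = OracleSegmenter(export_oracle(zero_noise_scene, flip_rho=0.5,
                                                boundary_band=3))
        img = _group_image(zero_noise_scene)
        cat = 1
        result = backend.segment(img, _region_prompts(zero_noise_scene, cat))
        region = zero_noise_scene.truth.labels == cat
        eligible = backend._eligible[cat]
        flipped = (result.mask ^ region)[eligible]
        n = eligible.sum()
        # flip count ~ Binomial(n, 0.5): allow 4 sigma around the mean
        sigma = np.sqrt(n * 0.25)
        assert abs(flipped.sum() - 0.5 * n) < 4 * sigma
        # untouched outside the eligibility band
        assert not (result.mask ^ region)[~eligible].any()

    def test_flip_noise_varies_across_groups(self, zero_noise_scene):
        backend = OracleSegmenter(export_oracle(zero_noise_scene, flip_rho=0.3,
                                                boundary_band=3))
        prompts = _region_prompts(zero_noise_scene, 1)
        a = backend.segment(_group_image(zero_noise_scene, 0), prompts)
        b = backend.segment(_group_image(zero_noise_scene, 5), prompts)
        assert (a.mask != b.mask).any()

    def test_segment_deterministic(self, zero_noise_scene):
        prompts = _region_prompts(zero_noise_scene, 1)
        img = _group_image(zero_noise_scene)
        masks = []
        for _ in range(2):
            backend = OracleSegmenter(export_oracle(zero_noise_scene,
                                                    flip_rho=0.3, boundary_band=3))
            masks.append(backend.segment(img, prompts).mask)
        np.testing.assert_array_equal(masks[0], masks[1])

    def test_dilation_grows_mask(self, zero_noise_scene):
        backend = OracleSegmenter(export_oracle(zero_noise_scene, dilate_iters=1))
        img = _group_image(zero_noise_scene)
        mask = backend.segment(img, _region_prompts(zero_noise_scene, 2)).mask
        region = zero_noise_scene.truth.labels == 2
        assert (mask & region).sum() == region.sum()
        assert mask.sum() > region.sum()


class TestOracleEmbed:
    def test_zero_noise_class_vectors_identical(self, zero_noise_scene, clean_backend):
        field = clean_backend.embed(_group_image(zero_noise_scene)).embedding
        for cat in (1, 2, 3):
            vecs = field[zero_noise_scene.truth.labels == cat]
            assert (vecs == vecs[0]).all()

    def test_cross_class_similarity_bounded(self, zero_noise_scene, clean_backend):
        field = clean_backend.embed(_group_image(zero_noise_scene)).embedding
        theta = zero_noise_scene.spec.theta_min_deg
        bound = np.cos(np.deg2rad(theta))
        r1 = np.argwhere(zero_noise_scene.truth.labels == 1)[0]
        r2 = np.argwhere(zero_noise_scene.truth.labels == 2)[0]
        a, b = field[tuple(r1)], field[tuple(r2)]
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos <= bound + 1e-9

    def test_bitwise_deterministic(self, zero_noise_scene):
        img = _group_image(zero_noise_scene)
        fields = []
        for _ in range(2):
            backend = OracleSegmenter(export_oracle(zero_noise_scene,
                                                    feature_noise_sd=0.1))
            fields.append(backend.embed(img).embedding)
        np.testing.assert_array_equal(fields[0], fields[1])


class TestPromptSet:
    def test_duplicate_pixel_per_category_rejected(self):
        ps = PromptSet()
        ps.add(1, PointPrompt(0, 0, FOREGROUND))
        with pytest.raises(ValueError):
            ps.add(1, PointPrompt(0, 0, BACKGROUND))
        ps.add(2, PointPrompt(0, 0, BACKGROUND))  # other category is fine

    def test_polarity_validation(self):
        with pytest.raises(ValueError):
            PointPrompt(0, 0, "fg")


class TestPromptProjection:
    def test_zero_gradient_is_fixed_point(self):
        proj = PromptProjection.identity(4)
        out = prompt_projection_step(proj, np.zeros((4, 4)), 0.1)
        np.testing.assert_array_equal(out.weight, proj.weight)

    def test_zero_learning_rate_is_noop(self):
        proj = PromptProjection.identity(4)
        out = prompt_projection_step(proj, np.ones((4, 4)), 0.0)
        np.testing.assert_array_equal(out.weight, proj.weight)

    def test_nonfinite_gradient_skipped_with_warning(self):
        proj = PromptProjection.identity(3)
        grad = np.zeros((3, 3))
        grad[0, 0] = np.nan
        with pytest.warns(RuntimeWarning):
            out = prompt_projection_step(proj, grad, 0.1)
        np.testing.assert_array_equal(out.weight, proj.weight)

    def test_quadratic_toy_loss_descends_monotonically(self):
        # L(W) = 0.5 ||W - T||^2 has gradient W - T; small steps must move
        # W toward T strictly monotonically.
        rng = np.random.default_rng(0)
        target = rng.normal(size=(3, 3))
        proj = PromptProjection.identity(3)
        dists = [np.linalg.norm(proj.weight - target)]
        for _ in range(20):
            proj = prompt_projection_step(proj, proj.weight - target, 0.1)
            dists.append(np.linalg.norm(proj.weight - target))
        assert all(b < a for a, b in zip(dists, dists[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prompt_projection_step(PromptProjection.identity(3),
                                   np.zeros((2, 2)), 0.1)
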
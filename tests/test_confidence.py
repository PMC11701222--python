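import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ipgseg.confidence import (
    PromptFeatureSet,
    Thresholds,
    batch_confidence,
    confidence,
    consistency_loss,
    cosine_similarity,
    selection_gate,
    similarities,
    threshold_label,
    total_consistency_loss_and_grad,
    uncertainty,
)


class TestCosineSimilarity:
    def test_identity(self):
        v = np.array([2.0, 3.0, -1.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


def _prompt_set_with_similarities(f_a, sims):
    """Construct prompt vectors whose cosines against f_a are exactly sims."""
    f_a = np.asarray(f_a, dtype=float)
    unit = f_a / np.linalg.norm(f_a)
    # orthogonal complement direction
    other = np.zeros_like(unit)
    other[np.argmin(np.abs(unit))] = 1.0
    other = other - (other @ unit) * unit
    other /= np.linalg.norm(other)
    vecs = [s * unit + np.sqrt(1 - s**2) * other for s in sims]
    return PromptFeatureSet(np.array(vecs))


class TestConfidenceAndUncertainty:
    def test_mean_of_hand_similarities(self):
        f_a = np.array([1.0, 2.0, 0.5])
        ps = _prompt_set_with_similarities(f_a, [0.6, 0.8, 1.0])
        np.testing.assert_allclose(similarities(f_a, ps), [0.6, 0.8, 1.0],
                                   atol=1e-12)
        assert confidence(f_a, ps) == pytest.approx(0.8)
        assert uncertainty(f_a, ps) == pytest.approx((0.04 + 0.0 + 0.04) / 3)

    def test_self_similarity_is_one(self):
        f_a = np.array([3.0, 4.0])
        assert confidence(f_a, PromptFeatureSet(f_a[None, :])) == pytest.approx(1.0)

    def test_orthogonal_prompts_give_zero(self):
        f_a = np.array([1.0, 0.0])
        ps = PromptFeatureSet(np.array([[0.0, 1.0], [0.0, 2.0]]))
        assert confidence(f_a, ps) == pytest.approx(0.0)

    def test_equal_similarities_zero_uncertainty(self):
        f_a = np.array([1.0, 1.0])
        ps = PromptFeatureSet(np.array([[2.0, 2.0], [5.0, 5.0]]))
        assert uncertainty(f_a, ps) == pytest.approx(0.0)

    def test_single_prompt_zero_uncertainty(self):
        assert uncertainty([1.0, 2.0], PromptFeatureSet([[0.3, 0.9]])) == 0.0

    def test_reorder_and_rescale_invariance(self):
        rng = np.random.default_rng(0)
        f_a = rng.normal(size=5)
        vecs = rng.normal(size=(4, 5))
        ps = PromptFeatureSet(vecs)
        perm = PromptFeatureSet(vecs[[2, 0, 3, 1]])
        scaled = PromptFeatureSet(vecs * rng.uniform(0.1, 10, size=(4, 1)))
        assert confidence(f_a, perm) == pytest.approx(confidence(f_a, ps))
        assert confidence(2.5 * f_a, scaled) == pytest.approx(confidence(f_a, ps))
        assert uncertainty(f_a, perm) == pytest.approx(uncertainty(f_a, ps))
        assert uncertainty(2.5 * f_a, scaled) == pytest.approx(uncertainty(f_a, ps))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(hnp.arrays(np.float64, st.tuples(st.integers(1, 32)),
                      elements=st.floats(-1, 1)))
    def test_uncertainty_matches_two_pass_variance(self, sims):
        """u must equal the brute-force population variance of the
        similarities, computed with an independent two-pass formula."""
        f_a = np.array([1.0, 0.0, 0.0])
        sims = np.clip(sims, -1.0, 1.0)
        ps = _prompt_set_with_similarities(f_a, sims)
        mean = sum(sims) / len(sims)
        brute = sum((s - mean) ** 2 for s in sims) / len(sims)
        assert uncertainty(f_a, ps) == pytest.approx(brute, abs=1e-10)

    def test_batch_matches_scalar_path(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(6, 4))
        ps = PromptFeatureSet(rng.normal(size=(3, 4)))
        p, u = batch_confidence(feats, ps)
        for i in range(6):
            assert p[i] == pytest.approx(confidence(feats[i], ps))
            assert u[i] == pytest.approx(uncertainty(feats[i], ps))

    def test_empty_prompt_set_rejected(self):
        with pytest.raises(ValueError):
            PromptFeatureSet(np.empty((0, 3)))


class TestThresholdAndGate:
    def test_threshold_label_cases(self):
        t = Thresholds()
        assert threshold_label(0.85, t) == 1
        assert threshold_label(0.3, t) == -1
        assert threshold_label(0.65, t) == 0
        assert threshold_label(0.8, t) == 1   # boundary inclusive
        assert threshold_label(0.5, t) == -1  # boundary inclusive

    def test_selection_gate_cases(self):
        t = Thresholds()
        assert selection_gate(0.9, 0.1, t) == 1
        assert selection_gate(0.9, 0.25, t) == 0
        assert selection_gate(0.5, 0.0, t) == 0

    def test_gate_implies_foreground_label(self):
        t = Thresholds()
        rng = np.random.default_rng(2)
        for _ in range(200):
            p, u = rng.uniform(-1, 1), rng.uniform(0, 0.5)
            if selection_gate(p, u, t):
                assert threshold_label(p, t) == 1

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            Thresholds(tau_high=0.5, tau_low=0.5)
        with pytest.raises(ValueError):
            Thresholds(kappa_high=0.0)


class TestConsistencyLoss:
    def test_hand_value(self):
        # one gated pixel, K=2, p_own=0.8, p_other=0.1
        loss = consistency_loss(gates=[1], p_all=[[0.8, 0.1]], category=1)
        assert loss == pytest.approx(-(np.log(0.8) + np.log(0.9)), abs=1e-9)
        assert loss == pytest.approx(0.32850, abs=1e-5)

    def test_all_gates_zero(self):
        assert consistency_loss([0, 0], [[0.9, 0.1], [0.8, 0.2]], 1) == 0.0

    def test_perfect_separation_limit(self):
        loss = consistency_loss([1], [[1.0, 0.0]], 1)
        assert 0.0 <= loss < 1e-5

    def test_nonnegative_and_monotone_in_own_confidence(self):
        losses = [consistency_loss([1], [[p, 0.2]], 1)
                  for p in np.linspace(0.1, 0.99, 20)]
        assert all(l >= 0 for l in losses)
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            consistency_loss([1], [[0.9]], 1)


class TestProjectionGradient:
    def _setup(self, seed, k=3, d=5):
        rng = np.random.default_rng(seed)
        gated = [rng.normal(size=(rng.integers(1, 4), d)) + 2.0 for _ in range(k)]
        prompts = [rng.normal(size=(rng.integers(1, 5), d)) + 2.0 for _ in range(k)]
        w = np.eye(d) + 0.1 * rng.normal(size=(d, d))
        return w, gated, prompts

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        """The analytic gradient through the cosine similarities must agree
        with a central finite-difference approximation of the loss."""
        w, gated, prompts = self._setup(seed)
        loss, grad = total_consistency_loss_and_grad(w, gated, prompts)
        eps = 1e-6
        rng = np.random.default_rng(seed + 100)
        for _ in range(10):
            i, j = rng.integers(0, w.shape[0], size=2)
            wp, wm = w.copy(), w.copy()
            wp[i, j] += eps
            wm[i, j] -= eps
            lp, _ = total_consistency_loss_and_grad(wp, gated, prompts)
            lm, _ = total_consistency_loss_and_grad(wm, gated, prompts)
            fd = (lp - lm) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_loss_assembles_from_scalar_definition(self):
        """Total loss equals the sum over categories of the per-category
        scalar loss evaluated on the same projected confidences."""
        w, gated, prompts = self._setup(7, k=2, d=4)
        total, _ = total_consistency_loss_and_grad(w, gated, prompts)
        expected = 0.0
        for i, block in enumerate(gated):
            p_all = np.stack([
                batch_confidence(block @ w.T, PromptFeatureSet(pf @ w.T))[0]
                for pf in prompts
            ], axis=1)
            expected += consistency_loss(np.ones(len(block)), p_all, i + 1)
        assert total == pytest.approx(expected, rel=1e-10)

    def test_no_gated_pixels_means_zero_loss_and_gradient(self):
        w, _, prompts = self._setup(3, k=2, d=4)
        empty = [np.empty((0, 4)), np.empty((0, 4))]
        loss, grad = total_consistency_loss_and_grad(w, empty, prompts)
        assert loss == 0.0
        np.testing.assert_array_equal(grad, np.zeros_like(w))


class TestRecordExport:
    def test_records_csv_layout(self, tmp_path):
        from ipgseg.confidence import ConfidenceRecord, records_to_csv

        recs = [ConfidenceRecord(1, 2, 3, 0.9, 0.01, 1, 1, iteration=4)]
        records_to_csv(recs, tmp_path / "records.csv")
        lines = (tmp_path / "records.csv").read_text().splitlines()
        assert lines[0] == "row,col,category,p,u,y,g,iteration"
        assert lines[1].startswith("1,2,3,0.9")
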
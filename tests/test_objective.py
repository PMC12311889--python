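"""Loss functions: worked examples, oracle equivalence and gradient checks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from msicodec import objective as obj

# ---------------------------------------------------------------------------
# independent oracle: literal double-loop transcription of the NT-Xent loss
# ---------------------------------------------------------------------------


def contrastive_oracle(w: np.ndarray, pair_index: np.ndarray,
                       alpha: float, gamma: float) -> float:
    """Direct two-loop evaluation of the contrastive loss definition."""
    n = len(w)

    def sim(a: int, b: int) -> float:
        return float(w[a] @ w[b] / (np.linalg.norm(w[a]) * np.linalg.norm(w[b])))

    total = 0.0
    for i in range(n):
        j = int(pair_index[i])
        denominator = sum(math.exp(sim(i, k) / gamma) for k in range(n) if k != i)
        total += -math.log(math.exp(sim(i, j) / gamma) / denominator)
    return alpha * total


def interleaved_pairs(n: int) -> np.ndarray:
    p = np.arange(2 * n)
    p[0::2] += 1
    p[1::2] -= 1
    return p


class TestCosineSimilarity:
    def test_identity_antipodal_orthogonal(self):
        v = np.array([3.0, -1.0, 2.0])
        assert obj.cosine_similarity(v, v) == pytest.approx(1.0)
        assert obj.cosine_similarity(v, -v) == pytest.approx(-1.0)
        assert obj.cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            obj.cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestContrastiveLoss:
    def test_single_pair_is_zero(self):
        # with 2N = 2 the denominator holds only the positive partner
        w = np.array([[1.0, 2.0], [0.5, -1.0]])
        pairs = np.array([1, 0])
        for gamma in (0.1, 1.0, 5.0):
            loss = obj.contrastive_loss(w, pairs, obj.ContrastiveParams(alpha=1.0, gamma=gamma))
            assert loss == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_pairs_closed_form(self):
        # e1,e1,e2,e2 with e1 perpendicular to e2: each ordered positive pair
        # contributes ln(1 + 2 e^-1)
        w = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        pairs = np.array([1, 0, 3, 2])
        loss = obj.contrastive_loss(w, pairs, obj.ContrastiveParams(alpha=1.0, gamma=1.0))
        expected = 4.0 * math.log(1.0 + 2.0 * math.exp(-1.0))
        assert loss == pytest.approx(expected, rel=1e-12)
        assert loss == pytest.approx(2.20578, abs=1e-4)

    def test_high_temperature_limit(self):
        # as gamma -> inf every softmax becomes uniform over 2N - 1 entries
        rng = np.random.default_rng(5)
        w = rng.normal(size=(8, 4))
        pairs = interleaved_pairs(4)
        loss = obj.contrastive_loss(w, pairs, obj.ContrastiveParams(alpha=1.0, gamma=1e9))
        assert loss == pytest.approx(8 * math.log(7), rel=1e-6)

    @pytest.mark.parametrize("n_pairs", [2, 5, 16, 32])
    def test_matches_double_loop_oracle(self, n_pairs):
        rng = np.random.default_rng(n_pairs)
        w = rng.normal(size=(2 * n_pairs, 6))
        pairs = interleaved_pairs(n_pairs)
        params = obj.ContrastiveParams(alpha=0.37, gamma=0.5)
        fast = obj.contrastive_loss(w, pairs, params)
        slow = contrastive_oracle(w, pairs, 0.37, 0.5)
        assert fast == pytest.approx(slow, abs=1e-6)

    def test_default_alpha_averages_per_anchor(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(6, 4))
        pairs = interleaved_pairs(3)
        auto = obj.contrastive_loss(w, pairs, obj.ContrastiveParams(gamma=0.5))
        manual = obj.contrastive_loss(w, pairs, obj.ContrastiveParams(alpha=1 / 6, gamma=0.5))
        assert auto == pytest.approx(manual)

    def test_numerical_stability_extreme_temperature(self):
        w = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        pairs = np.array([1, 0, 3, 2])
        loss = obj.contrastive_loss(w, pairs, obj.ContrastiveParams(alpha=1.0, gamma=1e-4))
        assert np.isfinite(loss)

    def test_rejects_malformed_pair_index(self):
        w = np.ones((4, 2))
        with pytest.raises(ValueError):
            obj.contrastive_loss(w, np.array([0, 1, 2, 3]))  # fixed points
        with pytest.raises(ValueError):
            obj.contrastive_loss(w, np.array([1, 2, 3, 0]))  # not an involution
        with pytest.raises(ValueError):
            obj.contrastive_loss(np.ones((0, 2)), np.array([]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(6, 5))
        pairs = interleaved_pairs(3)
        params = obj.ContrastiveParams(alpha=1.0, gamma=0.7)
        _, grad = obj.contrastive_loss_grad(w, pairs, params)
        eps = 1e-6
        for i in range(6):
            for j in range(5):
                wp, wm = w.copy(), w.copy()
                wp[i, j] += eps
                wm[i, j] -= eps
                num = (obj.contrastive_loss(wp, pairs, params)
                       - obj.contrastive_loss(wm, pairs, params)) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-7)


class TestMeanLoss:
    def test_worked_examples(self):
        assert obj.mean_loss([[1.0, -1.0], [2.0, -2.0]]) == pytest.approx(0.0)
        assert obj.mean_loss([[1.0, 1.0], [3.0, 3.0]]) == pytest.approx(5.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(5, 4))
        assert obj.mean_loss(3.0 * w) == pytest.approx(9.0 * obj.mean_loss(w))

    def test_gradient(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(4, 3))
        loss, grad = obj.mean_loss_grad(w)
        assert loss == pytest.approx(obj.mean_loss(w))
        eps = 1e-7
        for i in range(4):
            for j in range(3):
                wp, wm = w.copy(), w.copy()
                wp[i, j] += eps
                wm[i, j] -= eps
                num = (obj.mean_loss(wp) - obj.mean_loss(wm)) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestStandardLoss:
    def test_unit_sigma_is_zero(self):
        assert obj.standard_loss([[1.0], [-1.0]]) == pytest.approx(0.0)

    def test_constant_batch_is_one(self):
        # every feature sigma is 0, so each contributes (0 - 1)^2
        w = np.tile([2.0, -3.0, 0.5], (4, 1))
        assert obj.standard_loss(w) == pytest.approx(1.0)

    def test_sigma_two(self):
        assert obj.standard_loss([[2.0], [-2.0]]) == pytest.approx(1.0)

    def test_population_convention(self):
        # [0, 2]: population sigma 1 (loss 0); sample sigma sqrt(2) would not be
        assert obj.standard_loss([[0.0], [2.0]]) == pytest.approx(0.0)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            obj.standard_loss([[1.0, 2.0]])

    def test_gradient(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=(5, 3))
        loss, grad = obj.standard_loss_grad(w)
        assert loss == pytest.approx(obj.standard_loss(w))
        eps = 1e-7
        for i in range(5):
            for j in range(3):
                wp, wm = w.copy(), w.copy()
                wp[i, j] += eps
                wm[i, j] -= eps
                num = (obj.standard_loss(wp) - obj.standard_loss(wm)) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestMseLoss:
    def test_examples_and_symmetry(self):
        assert obj.mse_loss([[1.0, 2.0]], [[1.0, 2.0]]) == pytest.approx(0.0)
        assert obj.mse_loss([[0.0, 0.0, 2.0]], [[0.0, 0.0, 0.0]]) == pytest.approx(4 / 3)
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        assert obj.mse_loss(a, b) == pytest.approx(obj.mse_loss(b, a))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            obj.mse_loss(np.zeros((2, 3)), np.zeros((2, 4)))


class TestTotalLoss:
    def test_selection_and_arithmetic(self):
        w = obj.LossWeights(contrastive=0, mean=0, standard=0, decoder=1)
        total, report = obj.total_loss(5.0, 4.0, 3.0, 2.0, w)
        assert total == pytest.approx(2.0)
        w = obj.LossWeights(contrastive=0.1, mean=0.01, standard=0.01, decoder=1)
        total, report = obj.total_loss(1.0, 1.0, 1.0, 1.0, w)
        assert total == pytest.approx(1.12)
        assert report.weighted_total == pytest.approx(
            0.1 * report.contrastive + 0.01 * report.mean
            + 0.01 * report.standard + 1.0 * report.mse, rel=1e-9,
        )

    def test_nan_diagnosed_by_name(self):
        w = obj.LossWeights()
        with pytest.raises(FloatingPointError, match="standard"):
            obj.total_loss(1.0, 1.0, float("nan"), 1.0, w)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            obj.LossWeights(contrastive=0, mean=0, standard=0, decoder=0)


class TestBatchOrderInvariance:
    def test_losses_invariant_under_batch_permutation(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=(8, 5))
        pairs = interleaved_pairs(4)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        w_p = w[perm]
        pairs_p = inv[pairs[perm]]
        params = obj.ContrastiveParams(alpha=1.0, gamma=0.5)
        assert obj.contrastive_loss(w_p, pairs_p, params) == pytest.approx(
            obj.contrastive_loss(w, pairs, params))
        assert obj.mean_loss(w_p) == pytest.approx(obj.mean_loss(w))
        assert obj.standard_loss(w_p) == pytest.approx(obj.standard_loss(w))
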
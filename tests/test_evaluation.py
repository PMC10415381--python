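import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.stats import ortho_group

from cscore.evaluation import (
    AttenuationInputs,
    adjusted_rand_index,
    attenuation_factor,
    average_coexpression,
    mean_correlation_bias,
    precision_recall,
    subspace_distance,
)


class TestAttenuationFactor:
    def test_anchor_value(self):
        a = attenuation_factor(AttenuationInputs(s=5000, mu=0.01, cv=1.0))
        assert a == pytest.approx(np.sqrt(50 / 51), abs=1e-6)
        assert a == pytest.approx(0.99015, abs=1e-4)

    def test_limits(self):
        low = attenuation_factor(AttenuationInputs(s=5000, mu=1e-12, cv=1.0))
        high = attenuation_factor(AttenuationInputs(s=5000, mu=1e6, cv=1.0))
        assert low < 1e-3
        assert high == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("arg", ["s", "mu", "cv"])
    def test_strictly_increasing_in_each_argument(self, arg):
        base = {"s": 2000.0, "mu": 1e-3, "cv": 0.7}
        grid = np.logspace(-2, 2, 25) * base[arg]
        vals = [attenuation_factor(AttenuationInputs(**{**base, arg: g})) for g in grid]
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            AttenuationInputs(s=0, mu=1, cv=1)


class TestAverageCoexpression:
    def test_identity_and_constant(self):
        np.testing.assert_allclose(average_coexpression(np.eye(4)), np.zeros(4))
        M = np.full((5, 5), 0.3)
        np.fill_diagonal(M, 1.0)
        np.testing.assert_allclose(average_coexpression(M), np.full(5, 0.3))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(7, 7))
        M = (A + A.T) / 2
        want = [np.mean([M[j, k] for k in range(7) if k != j]) for j in range(7)]
        np.testing.assert_allclose(average_coexpression(M), want)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            average_coexpression(np.eye(1))


class TestPrecisionRecall:
    def test_perfect_scores_area_one(self):
        truth = np.array([True, True, False, False])
        _, _, area = precision_recall(np.array([0.9, 0.8, 0.1, 0.0]), truth)
        assert area == pytest.approx(1.0)

    def test_random_scores_area_near_prevalence(self):
        rng = np.random.default_rng(1)
        truth = rng.random(4000) < 0.5
        _, _, area = precision_recall(rng.random(4000), truth)
        assert area == pytest.approx(0.5, abs=0.05)

    def test_matches_exhaustive_threshold_sweep(self):
        scores = np.array([0.1, 0.9, 0.35, 0.6, 0.55, 0.2, 0.8, 0.05, 0.7, 0.4])
        truth = np.array([0, 1, 0, 1, 1, 0, 1, 0, 0, 1], bool)
        prec, rec, _ = precision_recall(scores, truth)
        pts = set(zip(np.round(prec, 10), np.round(rec, 10)))
        for thr in scores:
            sel = np.abs(scores) >= thr
            pt = (round(truth[sel].mean(), 10), round(truth[sel].sum() / truth.sum(), 10))
            assert pt in pts

    def test_area_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        truth = rng.random(200) < 0.3
        _, _, a1 = precision_recall(scores, truth)
        _, _, a2 = precision_recall(np.exp(5 * scores), truth)
        assert a1 == pytest.approx(a2)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(np.array([1.0, 2.0]), np.array([False, False]))


class TestARI:
    def test_identity_and_degenerate(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0
        assert adjusted_rand_index([1, 1, 1, 1], [1, 2, 1, 2]) == 0.0

    def test_random_labelings_center_at_zero(self):
        rng = np.random.default_rng(3)
        vals = [
            adjusted_rand_index(rng.integers(0, 4, 200), rng.integers(0, 4, 200))
            for _ in range(50)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestSubspaceDistance:
    def test_same_span_is_zero_and_complement_is_one(self):
        U = np.eye(6)[:, :3]
        assert subspace_distance(U, U) == pytest.approx(0.0)
        V = np.eye(6)[:, 3:]
        assert subspace_distance(U, V) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_principal_angle_formula(self, seed):
        rng = np.random.default_rng(seed)
        U = np.linalg.qr(rng.normal(size=(10, 4)))[0]
        V = np.linalg.qr(rng.normal(size=(10, 4)))[0]
        want = np.sqrt(np.mean(np.sin(subspace_angles(U, V)) ** 2))
        assert subspace_distance(U, V) == pytest.approx(want, abs=1e-10)

    def test_invariant_to_right_rotation(self):
        rng = np.random.default_rng(5)
        U = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        V = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        Q = ortho_group.rvs(3, random_state=6)
        assert subspace_distance(U @ Q, V) == pytest.approx(
            subspace_distance(U, V), abs=1e-10)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            subspace_distance(np.ones((4, 2)), np.eye(4)[:, :2])


def test_mean_correlation_bias_detects_expression_trend():
    p = 30
    mu = np.logspace(-4, -1, p)
    a = np.sqrt(5000 * mu / (1 + 5000 * mu))  # attenuation with cv=1
    rho = 0.5 * np.outer(a, a)
    np.fill_diagonal(rho, 1.0)
    assert mean_correlation_bias(mu, rho) > 0.9
    # an expression-independent network carries no such trend
    rng = np.random.default_rng(0)
    noise = rng.normal(0, 0.1, (p, p))
    flat = 0.5 + (noise + noise.T) / 2
    np.fill_diagonal(flat, 1.0)
    assert abs(mean_correlation_bias(mu, flat)) < 0.5
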
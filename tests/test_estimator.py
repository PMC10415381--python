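import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cscore.estimator import (
    EstimationError,
    estimate_network,
    regularize_theta,
    run_irls,
    wls_covariance,
    wls_mean,
    wls_variance,
)
from cscore.io import CountMatrix


def minimize_1d(objective, bracket=(-100.0, 100.0)):
    res = minimize_scalar(objective, bounds=bracket, method="bounded",
                          options={"xatol": 1e-12})
    return res.x


class TestClosedForms:
    def test_exact_proportionality_gives_slope(self):
        s = np.array([2.0, 5.0, 9.0])
        assert wls_mean(2 * s, s, np.array([0.3, 1.0, 2.0])) == pytest.approx(2.0)
        assert wls_mean(np.zeros(3), s, np.ones(3)) == 0.0

    def test_variance_hand_arithmetic(self):
        s = np.ones(2)
        assert wls_variance(np.array([3.0, 3.0]), s, 1.0, np.ones(2)) == pytest.approx(3.0)
        # counts below the Poisson floor give a negative moment estimate
        assert wls_variance(np.array([1.0, 1.0]), s, 1.0, np.ones(2)) == pytest.approx(-1.0)

    def test_covariance_hand_arithmetic(self):
        s = np.ones(2)
        x = np.array([2.0, 0.0])
        assert wls_covariance(x, x, s, 1.0, 1.0, np.ones(2)) == pytest.approx(1.0)
        # zero residual on one side kills the cross-product
        assert wls_covariance(x, 3.0 * s, s, 1.0, 3.0, np.ones(2)) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_each_matches_numerical_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        s = rng.uniform(1, 10, n)
        w = rng.uniform(0.1, 2, n)
        x = rng.poisson(3 * s).astype(float)
        x2 = rng.poisson(2 * s).astype(float)

        mu_hat = wls_mean(x, s, w)
        assert mu_hat == pytest.approx(
            minimize_1d(lambda m: np.sum(w * (x - s * m) ** 2)), abs=1e-8)

        sig_hat = wls_variance(x, s, mu_hat, w)
        obj = lambda v: np.sum(w * ((x - s * mu_hat) ** 2 - s * mu_hat - s**2 * v) ** 2)
        assert sig_hat == pytest.approx(minimize_1d(obj), abs=1e-8)

        cov_hat = wls_covariance(x, x2, s, mu_hat, 2.0, w)
        obj_c = lambda v: np.sum(w * ((x - s * mu_hat) * (x2 - s * 2.0) - s**2 * v) ** 2)
        assert cov_hat == pytest.approx(minimize_1d(obj_c), abs=1e-8)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            wls_mean(np.array([]), np.array([]), np.array([]))


class TestRegularizeTheta:
    def test_forced_medians(self):
        assert regularize_theta(np.array([1, 2, 3.]), np.array([1, 4, 9.])) == 1.0
        assert regularize_theta(np.array([1, 2, 1.]), np.array([1, 8, 3.])) == 2.0

    def test_zero_mean_genes_excluded(self):
        theta = regularize_theta(np.array([0.0, 1.0, 1.0]), np.array([99.0, 2.0, 4.0]))
        assert theta == 3.0

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0.5, 2, 101)
        sjj = rng.uniform(0.1, 5, 101)
        ratios = np.sort(sjj / mu**2)
        assert regularize_theta(mu, sjj) == pytest.approx(ratios[50])

    def test_no_eligible_gene(self):
        with pytest.raises(EstimationError):
            regularize_theta(np.zeros(3), np.ones(3))


def reference_irls(counts, depths, tol=0.05, max_iter=10):
    """Plain per-gene loop implementation of the estimation recipe.

    Deliberately scalar and explicit, as an independent check on the
    vectorized pipeline.
    """
    X = counts.astype(float)
    s = depths.astype(float)
    n, p = X.shape
    f_mu = lambda j, w: np.sum(w * s * X[:, j]) / np.sum(w * s * s)
    f_sig = lambda j, m, h: (
        np.sum(h * s * s * ((X[:, j] - s * m) ** 2 - s * m)) / np.sum(h * s**4)
    )
    mu = np.array([f_mu(j, np.ones(n)) for j in range(p)])
    sig = np.array([f_sig(j, mu[j], np.ones(n)) for j in range(p)])
    trace = [(mu.copy(), sig.copy())]
    for _ in range(max_iter):
        theta = max(np.median(sig / mu**2), 0.0)
        mu_new, sig_new = np.empty(p), np.empty(p)
        for j in range(p):
            w = 1.0 / (s * mu[j] + s**2 * mu[j] ** 2 * theta)
            mu_new[j] = f_mu(j, w)
            h = 1.0 / (s * mu_new[j] + s**2 * mu_new[j] ** 2 * theta) ** 2
            sig_new[j] = f_sig(j, mu_new[j], h)
        ok = (sig > 0) & (sig_new > 0)
        delta = np.max(np.abs(np.log(sig_new[ok]) - np.log(sig[ok])))
        mu, sig = mu_new, sig_new
        trace.append((mu.copy(), sig.copy()))
        if delta < tol:
            break
    return trace


class TestIRLS:
    def test_fixed_point_for_exactly_proportional_gene(self):
        s = np.arange(1, 51)
        cm = CountMatrix(s[:, None], ["g"], [f"c{i}" for i in range(50)],
                         depths=s)
        est = run_irls(cm)
        assert est.mu[0] == pytest.approx(1.0)

    def test_matches_step_by_step_reference(self):
        rng = np.random.default_rng(5)
        s = rng.integers(50, 200, 50)
        z = rng.gamma(2.0, 0.05, size=(50, 3))
        counts = rng.poisson(s[:, None] * z)
        cm = CountMatrix(counts, ["a", "b", "c"], [f"c{i}" for i in range(50)],
                         depths=s)
        est = run_irls(cm)
        trace = reference_irls(cm.counts, cm.depths)
        mu_ref, sig_ref = trace[est.iterations]
        np.testing.assert_allclose(est.mu, mu_ref, rtol=1e-10)
        np.testing.assert_allclose(est.sigma_jj, sig_ref, rtol=1e-10)

    def test_constant_depth_unit_weight_mean_is_sample_mean(self):
        rng = np.random.default_rng(8)
        x = rng.poisson(5.0, 30).astype(float)
        s = np.full(30, 100.0)
        assert wls_mean(x, s, np.ones(30)) == pytest.approx(np.mean(x / 100.0))

    def test_all_zero_genes_is_estimation_error(self):
        cm = CountMatrix(np.zeros((3, 2), int), ["a", "b"], ["c1", "c2", "c3"],
                         depths=np.array([5, 5, 5]))
        with pytest.raises(EstimationError):
            run_irls(cm)

    def test_converges_quickly_on_model_data(self, independent_cm):
        est = run_irls(independent_cm)
        assert est.converged
        assert est.iterations <= 5
        assert len(est.delta_trace) == est.iterations
        assert est.delta_trace[-1] < 0.05


class TestEstimateNetwork:
    def test_diagonal_is_one_and_matrices_symmetric(self, independent_cm):
        res = estimate_network(independent_cm)
        ok = ~res.flagged_mask()
        np.testing.assert_allclose(np.diag(res.rho)[ok], 1.0)
        np.testing.assert_allclose(res.rho, res.rho.T)
        np.testing.assert_allclose(res.sigma, res.sigma.T, rtol=1e-12)
        assert np.all(np.abs(res.rho) <= 1.0)
        off = res.pval[~np.eye(res.pval.shape[0], dtype=bool)]
        assert np.all((off >= 0) & (off <= 1))

    def test_flagged_genes_zeroed(self):
        rng = np.random.default_rng(3)
        s = rng.integers(500, 2000, 200)
        z = rng.gamma(2.0, 2.5e-4, size=(200, 3))
        counts = rng.poisson(s[:, None] * z)
        counts[:, 2] = 0  # never observed
        cm = CountMatrix(counts, ["a", "b", "dead"], [f"c{i}" for i in range(200)],
                         depths=s)
        res = estimate_network(cm)
        assert 2 in res.flags
        assert np.all(res.rho[2, :] == 0)
        assert np.all(res.pval[2, :] == 1)
        assert np.all(res.qval[2, :2] == 1)

    def test_pairwise_matrix_equals_per_pair_loop(self, independent_cm):
        from cscore.estimator import wls_covariance

        cm = independent_cm
        res = estimate_network(cm)
        est = res.moments
        s = cm.depths.astype(float)
        rng = np.random.default_rng(0)
        for j, jp in rng.integers(0, cm.n_genes, size=(10, 2)):
            if j == jp or j in res.flags or jp in res.flags:
                continue
            u_j = 1 / (s * est.mu[j] + s**2 * est.mu[j] ** 2 * est.theta)
            u_jp = 1 / (s * est.mu[jp] + s**2 * est.mu[jp] ** 2 * est.theta)
            want = wls_covariance(
                cm.counts[:, j], cm.counts[:, jp], s, est.mu[j], est.mu[jp], u_j * u_jp
            )
            assert res.sigma[j, jp] == pytest.approx(want, rel=1e-10)

    def test_rho_invariant_to_cell_relabeling(self):
        rng = np.random.default_rng(11)
        s = rng.integers(1000, 8000, 300)
        z = rng.gamma(2.0, 0.005, size=(300, 5))
        cm = CountMatrix(rng.poisson(s[:, None] * z), list("abcde"),
                         [f"c{i}" for i in range(300)], depths=s)
        perm = rng.permutation(300)
        res1 = estimate_network(cm)
        res2 = estimate_network(cm.subset_cells(perm))
        np.testing.assert_allclose(res1.rho, res2.rho, atol=1e-10)
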
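"""Independence test for gene pairs under the Poisson measurement model.

When two genes have independent latent expression, the weighted moment
estimate of their covariance is asymptotically normal with a variance that
can be computed from the per-gene means and variances alone.  The
standardized covariance

    T_jj' = sum_i s_i^2 (x_ij - s_i mu_j)(x_ij' - s_i mu_j') g_ijj'
            / sqrt( sum_i s_i^4 v_ij v_ij' g_ijj'^2 )

with ``v_ij = s_i mu_j + s_i^2 sigma_jj`` (the count variance) therefore
follows N(0, 1) under the null, giving analytic two-sided p values; q
values control the FDR over all tested pairs via Benjamini-Hochberg.

When the variance factors ``v`` reuse the regularized variances
``sigma_jj = mu_j^2 theta`` that also define the weights ``g``, the
denominator simplifies to ``sqrt(sum_i s_i^4 g_ijj')``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TestInputs", "test_statistic", "p_values", "bh_adjust"]


@dataclass
class TestInputs:
    """Plug-in quantities for the pairwise test statistic."""

    __test__ = False  # not a pytest class

    mu: np.ndarray
    sigma_jj: np.ndarray
    theta: float
    counts: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma_jj = np.asarray(self.sigma_jj, float)
        self.counts = np.asarray(self.counts, float)
        self.depths = np.asarray(self.depths, float)
        n, p = self.counts.shape
        if len(self.mu) != p or len(self.sigma_jj) != p or len(self.depths) != n:
            raise ValueError("inconsistent dimensions")
        if np.any(self.depths <= 0):
            raise ValueError("depths must be positive")


def test_statistic(
    j: int, jp: int, ti: TestInputs, *, regularized: bool = True
) -> float:
    """Standardized covariance T for one gene pair.

    ``regularized`` chooses the null variance factors: the regularized
    ``s mu + s^2 mu^2 theta`` (matching the covariance weights) or the raw
    plug-in ``s mu + s^2 sigma_jj``.
    """
    s = ti.depths
    mu_j, mu_jp = ti.mu[j], ti.mu[jp]
    u_j = 1.0 / (s * mu_j + s**2 * mu_j**2 * ti.theta)
    u_jp = 1.0 / (s * mu_jp + s**2 * mu_jp**2 * ti.theta)
    g = u_j * u_jp
    r = (ti.counts[:, j] - s * mu_j) * (ti.counts[:, jp] - s * mu_jp)
    num = np.sum(s**2 * r * g)
    if regularized:
        v_j = s * mu_j + s**2 * mu_j**2 * ti.theta
        v_jp = s * mu_jp + s**2 * mu_jp**2 * ti.theta
    else:
        v_j = s * mu_j + s**2 * ti.sigma_jj[j]
        v_jp = s * mu_jp + s**2 * ti.sigma_jj[jp]
    den = np.sqrt(np.sum(s**4 * v_j * v_jp * g**2))
    return float(num / den)


def test_statistic_matrix(
    num: np.ndarray,
    den: np.ndarray,
    U: np.ndarray,
    s: np.ndarray,
    mu: np.ndarray,
    sigma_jj: np.ndarray,
    theta: float,
    flagged: np.ndarray,
    *,
    regularized: bool = True,
) -> np.ndarray:
    """All-pairs T from precomputed covariance numerator/denominator.

    ``num`` and ``den`` are the weighted cross-product sums from the network
    estimator (``sigma = num / den``); ``U`` holds the per-gene weight
    factors ``u_ij``.  With regularized variance factors the null variance
    of the numerator is exactly ``den``, so ``T = num / sqrt(den)``.
    """
    if regularized:
        tstat = num / np.sqrt(den)
    else:
        V = np.outer(s, mu) + np.outer(s * s, sigma_jj)
        E = V * U**2 * (s * s)[:, None]
        tstat = num / np.sqrt(E.T @ E)
    np.fill_diagonal(tstat, np.nan)
    tstat[flagged, :] = np.nan
    tstat[:, flagged] = np.nan
    return tstat


def p_values(T: np.ndarray) -> np.ndarray:
    """Two-sided normal p values, ``p = 2 Phi(-|T|)``; NaN statistics map to 1."""
    T = np.asarray(T, float)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(T))
    p = np.where(np.isnan(T), 1.0, p)
    if p.ndim == 2:
        np.fill_diagonal(p, np.nan)
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def q_value_matrix(pval: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """BH across all tested (unflagged) off-diagonal pairs; flagged pairs get q=1."""
    p = pval.shape[0]
    qval = np.ones_like(pval)
    np.fill_diagonal(qval, np.nan)
    iu, ju = np.triu_indices(p, k=1)
    ok = ~(flagged[iu] | flagged[ju])
    if np.any(ok):
        q = bh_adjust(pval[iu[ok], ju[ok]])
        qval[iu[ok], ju[ok]] = q
        qval[ju[ok], iu[ok]] = q
    return qval
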
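"""Moment-based IRLS estimation of cell-type-specific co-expression.

Model: for cell ``i`` with sequencing depth ``s_i``, the observed UMI count
of gene ``j`` is Poisson distributed around ``s_i z_ij``, where ``z_ij`` is
the latent relative expression with mean ``mu_j`` and covariance
``sigma_jj'`` across cells of one cell type.  Co-expression is the latent
correlation ``rho_jj' = sigma_jj' / sqrt(sigma_jj sigma_j'j')``.

First and second moments of the counts give three estimating equations,

    x_ij                                ~ s_i mu_j
    (x_ij - s_i mu_j)^2 - s_i mu_j      ~ s_i^2 sigma_jj
    (x_ij - s_i mu_j)(x_ij' - s_i mu_j')~ s_i^2 sigma_jj'

each solved by weighted least squares with closed-form solutions.  Weights
are refreshed iteratively (IRLS) as the inverse residual variances
``w_ij = 1/(s_i mu_j + s_i^2 sigma_jj)``, with the per-gene over-dispersion
``theta_j = sigma_jj / mu_j^2`` shrunk to its cross-gene median so that the
weights stay stable for noisy genes.  Squared weights are used for the
variance fit and products of per-gene weights for the covariance fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MomentEstimates",
    "CoexpressionResult",
    "EstimationError",
    "wls_mean",
    "wls_variance",
    "wls_covariance",
    "regularize_theta",
    "run_irls",
    "estimate_network",
]

# per-gene flags
ZERO_GENE = "ZERO_GENE"
NEGATIVE_VARIANCE = "NEGATIVE_VARIANCE"


class EstimationError(RuntimeError):
    """Raised when no gene admits a valid moment estimate."""


@dataclass
class MomentEstimates:
    """Per-gene moment estimates with the IRLS trace.

    ``theta`` is the cross-gene median over-dispersion used in the final
    weights.  ``delta_trace[t]`` is the maximum absolute change of
    ``log sigma_jj`` between iterations ``t`` and ``t-1``, over genes whose
    variance estimate is positive in both.
    """

    mu: np.ndarray
    sigma_jj: np.ndarray
    theta: float
    iterations: int
    converged: bool
    delta_trace: np.ndarray
    flags: dict[int, set[str]] = field(default_factory=dict)


@dataclass
class CoexpressionResult:
    """Symmetric pairwise co-expression estimates and test results.

    ``rho`` is clipped to [-1, 1]; ``tstat`` has NaN on the diagonal and on
    flagged genes; flagged rows/columns carry ``rho = 0``, ``pval = 1``,
    ``qval = 1``.
    """

    gene_ids: list[str]
    rho: np.ndarray
    sigma: np.ndarray
    tstat: np.ndarray
    pval: np.ndarray
    qval: np.ndarray
    flags: dict[int, set[str]]
    moments: MomentEstimates | None = None
    n_clipped: int = 0

    def flagged_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.gene_ids), dtype=bool)
        for i in self.flags:
            mask[i] = True
        return mask

    def edge_list(self):
        """Long-format upper-triangle edge table (gene_i, gene_j, rho, T, p, q)."""
        import pandas as pd

        p = len(self.gene_ids)
        iu, ju = np.triu_indices(p, k=1)
        return pd.DataFrame(
            {
                "gene_i": [self.gene_ids[i] for i in iu],
                "gene_j": [self.gene_ids[j] for j in ju],
                "rho": self.rho[iu, ju],
                "T": self.tstat[iu, ju],
                "p": self.pval[iu, ju],
                "q": self.qval[iu, ju],
            }
        )


def _check_inputs(x: np.ndarray, s: np.ndarray, w: np.ndarray) -> None:
    if len(x) == 0:
        raise ValueError("zero-length input")
    if not (len(x) == len(s) == len(w)):
        raise ValueError("input lengths differ")


def wls_mean(x: np.ndarray, s: np.ndarray, w: np.ndarray) -> float:
    """Weighted least squares fit of ``x_i ~ s_i mu``.

    Minimizes ``sum_i w_i (x_i - s_i mu)^2``; the closed-form solution is
    ``sum(w s x) / sum(w s^2)``.
    """
    x, s, w = np.asarray(x, float), np.asarray(s, float), np.asarray(w, float)
    _check_inputs(x, s, w)
    return float(np.sum(w * s * x) / np.sum(w * s * s))


def wls_variance(x: np.ndarray, s: np.ndarray, mu_hat: float, h: np.ndarray) -> float:
    """Weighted least squares fit of the latent variance ``sigma_jj``.

    Minimizes ``sum_i h_i [ (x_i - s_i mu)^2 - s_i mu - s_i^2 sigma ]^2``.
    The moment estimate may be negative; callers must flag such genes.
    """
    x, s, h = np.asarray(x, float), np.asarray(s, float), np.asarray(h, float)
    _check_inputs(x, s, h)
    r2 = (x - s * mu_hat) ** 2 - s * mu_hat
    return float(np.sum(h * s * s * r2) / np.sum(h * s**4))


def wls_covariance(
    x_j: np.ndarray,
    x_jp: np.ndarray,
    s: np.ndarray,
    mu_j: float,
    mu_jp: float,
    g: np.ndarray,
) -> float:
    """Weighted least squares fit of the latent covariance ``sigma_jj'``.

    Minimizes ``sum_i g_i [ (x_ij - s_i mu_j)(x_ij' - s_i mu_j') - s_i^2 sigma ]^2``.
    """
    x_j, x_jp = np.asarray(x_j, float), np.asarray(x_jp, float)
    s, g = np.asarray(s, float), np.asarray(g, float)
    _check_inputs(x_j, s, g)
    cross = (x_j - s * mu_j) * (x_jp - s * mu_jp)
    return float(np.sum(g * s * s * cross) / np.sum(g * s**4))


def regularize_theta(mu: np.ndarray, sigma_jj: np.ndarray) -> float:
    """Cross-gene median of the over-dispersion ``sigma_jj / mu_j^2``.

    Genes with ``mu_j <= 0`` are excluded.  The median is floored at zero:
    the weights ``1/(s mu + s^2 mu^2 theta)`` require ``theta >= 0``, and a
    negative median can only arise when most variance estimates are
    negative, i.e. when the latent expression is essentially Poisson.
    """
    mu = np.asarray(mu, float)
    sigma_jj = np.asarray(sigma_jj, float)
    ok = mu > 0
    if not np.any(ok):
        raise EstimationError("no gene with positive mean for theta regularization")
    return float(max(np.median(sigma_jj[ok] / mu[ok] ** 2), 0.0))


def _vectorized_mu(X: np.ndarray, s: np.ndarray, W: np.ndarray) -> np.ndarray:
    # columns of W are per-gene weights; identical to wls_mean per gene
    return np.einsum("ij,i,ij->j", W, s, X) / (W.T @ (s * s))


def _vectorized_sigma(
    X: np.ndarray, s: np.ndarray, mu: np.ndarray, H: np.ndarray
) -> np.ndarray:
    r2 = (X - np.outer(s, mu)) ** 2 - np.outer(s, mu)
    return np.einsum("ij,i,ij->j", H, s * s, r2) / (H.T @ s**4)


def run_irls(
    cm: CountMatrix, tol: float = 0.05, max_iter: int = 10
) -> MomentEstimates:
    """Estimate ``mu_j`` and ``sigma_jj`` for all genes by IRLS.

    Starts from ordinary least squares (unit weights); each iteration
    recomputes the regularized over-dispersion ``theta`` (cross-gene median
    of ``sigma_jj / mu_j^2``), refreshes weights
    ``w_ij = 1/(s_i mu_j + s_i^2 mu_j^2 theta)``, updates ``mu_j`` with
    ``w``, then ``sigma_jj`` with ``h = w^2`` (recomputed at the updated
    ``mu_j``).  Stops when the maximum change of ``log sigma_jj`` drops
    below ``tol`` or after ``max_iter`` iterations.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    X = cm.counts.astype(float)
    s = cm.depths.astype(float)
    n, p = X.shape

    flags: dict[int, set[str]] = {}
    zero = cm.zero_genes()
    for j in np.flatnonzero(zero):
        flags.setdefault(j, set()).add(ZERO_GENE)
    if zero.all():
        raise EstimationError("all genes have zero counts")

    ones = np.ones((n, p))
    mu = _vectorized_mu(X, s, ones)
    sigma = _vectorized_sigma(X, s, mu, ones)

    delta_trace: list[float] = []
    converged = False
    t = 0
    theta = regularize_theta(mu[~zero], sigma[~zero])
    while t < max_iter:
        t += 1
        theta = regularize_theta(mu[~zero], sigma[~zero])
        with np.errstate(divide="ignore"):
            W = 1.0 / (np.outer(s, mu) + np.outer(s * s, mu * mu) * theta)
        W[:, zero] = 1.0  # placeholder; flagged genes are ignored downstream
        mu_new = _vectorized_mu(X, s, W)
        with np.errstate(divide="ignore"):
            H = (
                1.0
                / (np.outer(s, mu_new) + np.outer(s * s, mu_new * mu_new) * theta) ** 2
            )
        H[:, zero] = 1.0
        sigma_new = _vectorized_sigma(X, s, mu_new, H)

        valid = (sigma > 0) & (sigma_new > 0) & ~zero
        if np.any(valid):
            delta = float(
                np.max(np.abs(np.log(sigma_new[valid]) - np.log(sigma[valid])))
            )
        else:
            delta = 0.0
        delta_trace.append(delta)
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break

    theta = regularize_theta(mu[~zero], sigma[~zero])
    for j in np.flatnonzero((sigma <= 0) & ~zero):
        flags.setdefault(j, set()).add(NEGATIVE_VARIANCE)
    if not converged:
        logger.warning("IRLS did not converge in %d iterations (delta=%.4g)",
                       max_iter, delta_trace[-1] if delta_trace else float("nan"))
    return MomentEstimates(
        mu=mu,
        sigma_jj=sigma,
        theta=theta,
        iterations=t,
        converged=converged,
        delta_trace=np.asarray(delta_trace),
        flags=flags,
    )


def estimate_network(
    cm: CountMatrix,
    tol: float = 0.05,
    max_iter: int = 10,
    *,
    regularized_test_variance: bool = True,
) -> CoexpressionResult:
    """Estimate the full co-expression matrix with independence tests.

    Runs :func:`run_irls`, then estimates all pairwise covariances with
    weights ``g_ijj' = u_ij u_ij'`` where
    ``u_ij = 1/(s_i mu_j + s_i^2 mu_j^2 theta)``, and converts to
    correlations.  Correlations outside [-1, 1] — possible for moment
    estimators — are clipped, with the count logged.  Genes with
    non-positive variance estimates are flagged and zeroed out of the
    network.  Test statistics, p values and BH q values come from
    :mod:`cscore.testing`.

    ``regularized_test_variance`` selects whether the null variance factors
    in the test statistic reuse the regularized variances ``mu^2 theta``
    (default, consistent with the weights ``g``) or the raw per-gene
    ``sigma_jj`` estimates.
    """
    from . import testing

    est = run_irls(cm, tol=tol, max_iter=max_iter)
    X = cm.counts.astype(float)
    s = cm.depths.astype(float)
    n, p = X.shape
    mu, sigma_jj, theta = est.mu, est.sigma_jj, est.theta

    flagged = np.zeros(p, dtype=bool)
    for j in est.flags:
        flagged[j] = True
    if flagged.all():
        raise EstimationError("all genes flagged; no testable pairs")

    # per-gene weight factor u_ij; g_ijj' = u_ij * u_ij'
    mu_safe = np.where(flagged, 1.0, mu)
    U = 1.0 / (np.outer(s, mu_safe) + np.outer(s * s, mu_safe * mu_safe) * theta)
    R = X - np.outer(s, mu)  # residuals

    # sigma_jj' = sum_i s_i^2 r_ij u_ij r_ij' u_ij' / sum_i s_i^4 u_ij u_ij'
    A = R * U * s[:, None]
    B = U * s[:, None] ** 2
    num = A.T @ A
    den = B.T @ B
    sigma = num / den
    np.fill_diagonal(sigma, sigma_jj)

    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(np.where(sigma_jj > 0, sigma_jj, np.nan))
        rho = sigma / np.outer(scale, scale)
    np.fill_diagonal(rho, 1.0)

    n_clipped = int(np.sum(np.abs(rho[~np.isnan(rho)]) > 1) )
    if n_clipped:
        logger.info("clipped %d correlation entries to [-1, 1]", n_clipped)
    rho = np.clip(rho, -1.0, 1.0)
    rho[flagged, :] = 0.0
    rho[:, flagged] = 0.0

    tstat = testing.test_statistic_matrix(
        num,
        den,
        U,
        s,
        mu,
        sigma_jj,
        theta,
        flagged,
        regularized=regularized_test_variance,
    )
    pval = testing.p_values(tstat)
    pval[flagged, :] = 1.0
    pval[:, flagged] = 1.0
    qval = testing.q_value_matrix(pval, flagged)

    return CoexpressionResult(
        gene_ids=list(cm.gene_ids),
        rho=rho,
        sigma=sigma,
        tstat=tstat,
        pval=pval,
        qval=qval,
        flags=est.flags,
        moments=est,
        n_clipped=n_clipped,
    )
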
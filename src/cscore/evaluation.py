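"""Evaluation metrics and diagnostics for co-expression estimates.

Includes the Poisson-measurement attenuation factor (how much a raw count
correlation understates the latent correlation), per-gene average
co-expression profiles, precision-recall against a known pair truth set,
adjusted Rand index for module recovery, a projection-based subspace
distance for comparing network spectra, and the mean-correlation bias
diagnostic (association between expression level and apparent
co-expression, an artifact signature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skmetrics

__all__ = [
    "AttenuationInputs",
    "attenuation_factor",
    "average_coexpression",
    "precision_recall",
    "adjusted_rand_index",
    "subspace_distance",
    "mean_correlation_bias",
]


@dataclass
class AttenuationInputs:
    s: float  # sequencing depth
    mu: float  # relative expression level
    cv: float  # coefficient of variation sqrt(sigma_jj)/mu_j

    def __post_init__(self) -> None:
        if self.s <= 0 or self.mu <= 0 or self.cv <= 0:
            raise ValueError("s, mu and cv must all be positive")


def attenuation_factor(ai: AttenuationInputs) -> float:
    """Factor by which Poisson measurement noise shrinks a count correlation.

    With latent variance ``Var(z) = (cv * mu)^2`` and count variance
    ``s mu + s^2 Var(z)``, the correlation of counts equals the latent
    correlation times ``a_j a_j'`` with

        a = sqrt( s cv^2 / (1/mu + s cv^2) )

    Strictly increasing in each of ``mu``, ``s`` and ``cv``, approaching 1
    for highly expressed genes — which is why count correlations look
    stronger for high expressors even when the latent correlation is flat.
    """
    s, mu, cv = ai.s, ai.mu, ai.cv
    return float(np.sqrt(s * cv**2 / (1.0 / mu + s * cv**2)))


def average_coexpression(rho: np.ndarray) -> np.ndarray:
    """Per-gene mean of off-diagonal co-expressions."""
    rho = np.asarray(rho, float)
    p = rho.shape[0]
    if rho.shape != (p, p) or p < 2:
        raise ValueError("rho must be square with at least 2 genes")
    off = rho.copy()
    np.fill_diagonal(off, 0.0)
    return off.sum(axis=1) / (p - 1)


def precision_recall(
    scores: np.ndarray, truth: np.ndarray, ordering: str = "abs_desc"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall sweep over pair scores against a boolean truth set.

    ``ordering='abs_desc'`` ranks pairs by |score| descending (correlation
    magnitudes); ``'pvalue_asc'`` ranks ascending (p values).  Area is the
    trapezoid integral of precision over recall.  Returns
    ``(precision, recall, area)``.
    """
    scores = np.asarray(scores, float).ravel()
    truth = np.asarray(truth, bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    if not truth.any():
        raise ValueError("truth set has no positive pairs")
    if ordering == "abs_desc":
        ranking = np.abs(scores)
    elif ordering == "pvalue_asc":
        ranking = -scores
    else:
        raise ValueError(f"unknown ordering: {ordering!r}")
    precision, recall, _ = _skmetrics.precision_recall_curve(truth, ranking)
    # integrate precision d(recall); at a tied recall keep the precision of
    # the most stringent threshold reaching it, so the curve is a function
    order = np.lexsort((-precision, recall))
    r_sorted, p_sorted = recall[order], precision[order]
    first = np.ones(len(r_sorted), dtype=bool)
    first[1:] = np.diff(r_sorted) > 0
    area = float(np.trapezoid(p_sorted[first], r_sorted[first]))
    return precision, recall, area


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two clusterings."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    return float(_skmetrics.adjusted_rand_score(a, b))


def subspace_distance(U: np.ndarray, V: np.ndarray) -> float:
    """Normalized distance between the column spans of two orthonormal bases.

    ``||U U^T - V V^T||_F / sqrt(2k)``, which equals
    ``sqrt(mean_i sin^2 theta_i)`` over the k principal angles: 0 iff the
    spans coincide, 1 iff they are orthogonal.
    """
    U, V = np.asarray(U, float), np.asarray(V, float)
    if U.shape != V.shape:
        raise ValueError("U and V must have the same shape")
    k = U.shape[1]
    for M, name in ((U, "U"), (V, "V")):
        if not np.allclose(M.T @ M, np.eye(k), atol=1e-8):
            raise ValueError(f"{name} does not have orthonormal columns")
    diff = U @ U.T - V @ V.T
    return float(np.linalg.norm(diff, "fro") / np.sqrt(2 * k))


def mean_correlation_bias(mean_expression: np.ndarray, rho: np.ndarray) -> float:
    """Spearman correlation of expression level vs. average co-expression.

    A strongly positive value is the signature of attenuation-driven bias:
    genes look more connected merely because they are highly expressed.
    """
    avg = average_coexpression(rho)
    res = stats.spearmanr(np.asarray(mean_expression, float), avg)
    return float(res.statistic)
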
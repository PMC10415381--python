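"""Normalization-based correlation baselines.

These are the standard workflows this package's estimator is designed to
improve on: scale counts to a fixed library size (``scale_factor * x / s``),
optionally log-transform (``log(scale_factor * x / s + 1)``, natural log),
and correlate genes with Pearson or Spearman.  Significance uses the
correlation statistic ``t = r sqrt((n-2)/(1-r^2))`` referred to a standard
normal, two-sided, with BH adjustment across pairs.

Because normalized counts still carry Poisson measurement noise and
depth-driven artifacts, these baselines show two systematic failures that
the latent-moment estimator avoids: spurious correlation on independent
genes when depths vary, and attenuation of true correlation for weakly
expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CountMatrix
from .testing import bh_adjust

__all__ = ["NormalizedMatrix", "normalize", "correlation_test", "BaselineResult"]


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # cells x genes
    scheme: str  # 'scaled' | 'lognorm'
    scale_factor: float


@dataclass
class BaselineResult:
    """Pairwise correlation estimates with normal-approximation tests."""

    gene_ids: list[str]
    method: str
    rho: np.ndarray
    tstat: np.ndarray
    pval: np.ndarray
    qval: np.ndarray
    degenerate: np.ndarray  # zero-variance genes (r undefined, p = 1)


def normalize(
    cm: CountMatrix, scheme: str = "lognorm", scale_factor: float = 1e4
) -> NormalizedMatrix:
    """Library-size normalization, optionally log1p-transformed."""
    scaled = scale_factor * cm.counts / cm.depths[:, None]
    if scheme == "scaled":
        values = scaled
    elif scheme == "lognorm":
        values = np.log1p(scaled)
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    return NormalizedMatrix(values=values, scheme=scheme, scale_factor=scale_factor)


def correlation_test(
    nm: NormalizedMatrix, method: str = "pearson", gene_ids: list[str] | None = None
) -> BaselineResult:
    """All-pairs correlation with two-sided normal p values.

    Pairs at the |r| = 1 pole (t undefined) get p = 0; genes with zero
    variance get NaN correlation and p = 1.
    """
    V = np.asarray(nm.values, float)
    n, p = V.shape
    if n < 3:
        raise ValueError("need at least 3 cells")
    if method == "spearman":
        # average ranks for ties — counts are heavily tied
        V = stats.rankdata(V, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")

    sd = V.std(axis=0)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(V, rowvar=False)
    r = np.asarray(r, float)
    np.fill_diagonal(r, 1.0)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        r_c = np.clip(r, -1.0, 1.0)
        t = r_c * np.sqrt((n - 2) / (1.0 - r_c**2))
        pval = 2.0 * stats.norm.sf(np.abs(t))
    at_pole = np.isclose(np.abs(r_c), 1.0)
    pval = np.where(at_pole, 0.0, pval)
    pval = np.where(np.isnan(r), 1.0, pval)
    np.fill_diagonal(pval, np.nan)
    np.fill_diagonal(t, np.nan)

    qval = np.ones_like(pval)
    np.fill_diagonal(qval, np.nan)
    iu, ju = np.triu_indices(p, k=1)
    ok = ~(degenerate[iu] | degenerate[ju])
    if np.any(ok):
        q = bh_adjust(pval[iu[ok], ju[ok]])
        qval[iu[ok], ju[ok]] = q
        qval[ju[ok], iu[ok]] = q

    if gene_ids is None:
        gene_ids = [f"g{j:05d}" for j in range(p)]
    return BaselineResult(
        gene_ids=list(gene_ids),
        method=method,
        rho=r,
        tstat=t,
        pval=pval,
        qval=qval,
        degenerate=degenerate,
    )
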
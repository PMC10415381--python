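"""Two-group differential co-expression with a label-permutation test.

Workflow: balance the groups by downsampling the larger one, estimate a
co-expression network per group, take the per-pair difference of
correlation estimates, and assess significance by repeatedly reassigning
cells at random to two equal pseudo-groups and recomputing the difference.
The empirical two-sided p value uses the add-one estimator
``(1 + #{|delta_b| >= |delta|}) / (1 + B)`` so it is never exactly zero;
BH adjustment runs across all tested pairs.  Significant pairs can then be
grouped into modules by average-linkage hierarchical clustering on
``1 - |weight|`` adjacency (soft-threshold power 1).

Each permutation re-runs the full moment estimation on both pseudo-groups
— expensive but faithful to how the observed difference was computed.  For
large gene sets, subset to the top expressed genes first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .estimator import estimate_network
from .io import CountMatrix
from .testing import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "subsample_balance",
    "differential_test",
    "extract_modules",
]


@dataclass
class DifferentialResult:
    gene_ids: list[str]
    delta_rho: np.ndarray  # group1 - group2
    perm_pval: np.ndarray
    qval: np.ndarray
    n_permutations: int
    seed: int
    modules: dict[str, int] | None = None
    flags: dict[int, set[str]] = field(default_factory=dict)


def subsample_balance(
    cm1: CountMatrix, cm2: CountMatrix, seed: int = 0
) -> tuple[CountMatrix, CountMatrix]:
    """Downsample the larger group to the smaller group's cell count."""
    rng = np.random.default_rng(seed)
    n1, n2 = cm1.n_cells, cm2.n_cells
    if n1 > n2:
        keep = np.sort(rng.choice(n1, size=n2, replace=False))
        return cm1.subset_cells(keep), cm2
    if n2 > n1:
        keep = np.sort(rng.choice(n2, size=n1, replace=False))
        return cm1, cm2.subset_cells(keep)
    return cm1, cm2


def _pool(cm1: CountMatrix, cm2: CountMatrix) -> CountMatrix:
    if cm1.gene_ids != cm2.gene_ids:
        raise ValueError("groups must share the same gene set and order")
    return CountMatrix(
        counts=np.vstack([cm1.counts, cm2.counts]),
        gene_ids=list(cm1.gene_ids),
        cell_ids=[f"a:{c}" for c in cm1.cell_ids] + [f"b:{c}" for c in cm2.cell_ids],
        depths=np.concatenate([cm1.depths, cm2.depths]),
    )


def differential_test(
    cm1: CountMatrix,
    cm2: CountMatrix,
    B: int = 100,
    seed: int = 0,
    tol: float = 0.05,
    max_iter: int = 10,
) -> DifferentialResult:
    """Permutation test for per-pair differences in co-expression.

    Expects balanced groups (see :func:`subsample_balance`).  Pairs
    involving a gene flagged in either observed network are not tested
    (p = q = 1).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if cm1.n_cells != cm2.n_cells:
        raise ValueError("groups must be balanced; call subsample_balance first")
    n = cm1.n_cells
    pooled = _pool(cm1, cm2)

    res1 = estimate_network(cm1, tol=tol, max_iter=max_iter)
    res2 = estimate_network(cm2, tol=tol, max_iter=max_iter)
    delta = res1.rho - res2.rho
    flags: dict[int, set[str]] = {}
    for f in (res1.flags, res2.flags):
        for j, tags in f.items():
            flags.setdefault(j, set()).update(tags)
    flagged = np.zeros(pooled.n_genes, dtype=bool)
    for j in flags:
        flagged[j] = True

    rng = np.random.default_rng(seed)
    p = pooled.n_genes
    exceed = np.zeros((p, p))
    abs_delta = np.abs(delta)
    for _ in range(B):
        perm = rng.permutation(2 * n)
        ga = pooled.subset_cells(perm[:n])
        gb = pooled.subset_cells(perm[n:])
        ra = estimate_network(ga, tol=tol, max_iter=max_iter)
        rb = estimate_network(gb, tol=tol, max_iter=max_iter)
        exceed += np.abs(ra.rho - rb.rho) >= abs_delta

    perm_pval = (1.0 + exceed) / (1.0 + B)
    np.fill_diagonal(perm_pval, np.nan)
    perm_pval[flagged, :] = 1.0
    perm_pval[:, flagged] = 1.0

    qval = np.ones_like(perm_pval)
    np.fill_diagonal(qval, np.nan)
    iu, ju = np.triu_indices(p, k=1)
    ok = ~(flagged[iu] | flagged[ju])
    if np.any(ok):
        q = bh_adjust(perm_pval[iu[ok], ju[ok]])
        qval[iu[ok], ju[ok]] = q
        qval[ju[ok], iu[ok]] = q

    return DifferentialResult(
        gene_ids=list(cm1.gene_ids),
        delta_rho=delta,
        perm_pval=perm_pval,
        qval=qval,
        n_permutations=B,
        seed=seed,
        flags=flags,
    )


def extract_modules(
    network: np.ndarray,
    significant: np.ndarray | None = None,
    k_or_cut: int | float = 4,
    gene_ids: list[str] | None = None,
) -> dict[str, int]:
    """Cluster genes into modules from a (differential) co-expression network.

    Builds adjacency ``|network|`` masked to significant pairs (soft
    threshold power 1), converts to distance ``1 - adjacency`` and applies
    average-linkage hierarchical clustering.  Genes with no retained edge
    (e.g. flagged genes, or nothing significant) are set aside as
    unassigned — label 0, the analogue of WGCNA's grey module — so they do
    not soak up cluster cuts as maximally distant singletons.  An integer
    ``k_or_cut`` requests that many clusters among the connected genes; a
    float cuts the dendrogram at that height.  Returns gene -> module
    label.
    """
    W = np.asarray(network, float)
    p = W.shape[0]
    if W.shape != (p, p) or not np.allclose(W, W.T, equal_nan=True):
        raise ValueError("network must be a symmetric square matrix")
    adj = np.abs(np.nan_to_num(W))
    if significant is not None:
        adj = np.where(np.asarray(significant, bool), adj, 0.0)
    np.fill_diagonal(adj, 0.0)
    adj = np.clip(adj, 0.0, 1.0)

    if gene_ids is None:
        gene_ids = [f"g{j:05d}" for j in range(p)]
    connected = adj.any(axis=1)
    labels = np.zeros(p, dtype=int)
    m = int(connected.sum())
    if m == 0:
        warnings.warn("no significant pairs; returning a single unassigned module")
        return {g: 0 for g in gene_ids}
    if m == 1:
        labels[connected] = 1
    else:
        sub = adj[np.ix_(connected, connected)]
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        Z = average(squareform(dist, checks=False))
        if isinstance(k_or_cut, (int, np.integer)):
            sub_labels = fcluster(Z, t=int(k_or_cut), criterion="maxclust")
        else:
            sub_labels = fcluster(Z, t=float(k_or_cut), criterion="distance")
        labels[connected] = sub_labels
    return dict(zip(gene_ids, (int(l) for l in labels)))
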
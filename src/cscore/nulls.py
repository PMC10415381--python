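"""Permutation nulls: counts with expression levels preserved, dependence destroyed.

From any count matrix, compute per-cell-normalized expression
``y_ij = x_ij / s_i``, independently permute each gene's ``y`` column
across cells (destroying all cross-gene dependence while exactly
preserving each gene's marginal profile), then regenerate counts by
Poisson sampling at a chosen target depth: ``x'_ij ~ Poisson(t_i y_ij^p)``.

The target depth ``t_i`` is either the cell's observed depth (a null with
realistic depth variation), the median observed depth for every cell (a
constant-depth null), or a custom vector.  Contrasting the two depth modes
isolates artifacts that depth variation induces in normalization-based
correlation estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix

__all__ = ["NullSpec", "permute_null_counts"]


@dataclass
class NullSpec:
    """Depth mode and seed for null generation."""

    depth_mode: str = "observed"  # 'observed' | 'constant-median' | 'custom'
    custom_depths: np.ndarray | None = None
    seed: int = 0


def permute_null_counts(cm: CountMatrix, spec: NullSpec) -> CountMatrix:
    """Generate a no-co-expression count matrix from ``cm``.

    Deterministic given ``spec.seed``; permutations are drawn gene by gene
    in fixed column order from a single seeded generator.  The returned
    matrix carries the target depths ``t_i`` as its depths: the input is
    typically a gene panel, and a real experiment's depths come from the
    full transcriptome, which the panel's own resampled row sums do not
    represent (their compositional noise is an artifact of the panel).
    Realized panel row sums are kept in ``metadata``.
    """
    rng = np.random.default_rng(spec.seed)
    y = cm.counts / cm.depths[:, None]
    n, p = y.shape

    if spec.depth_mode == "observed":
        t = cm.depths.astype(float)
    elif spec.depth_mode == "constant-median":
        t = np.full(n, float(np.median(cm.depths)))
    elif spec.depth_mode == "custom":
        t = np.asarray(spec.custom_depths, float)
        if t is None or t.shape != (n,) or np.any(t <= 0):
            raise ValueError("custom depths must be positive, length n")
    else:
        raise ValueError(f"unknown depth mode: {spec.depth_mode!r}")

    yp = np.empty_like(y)
    for j in range(p):
        yp[:, j] = y[rng.permutation(n), j]
    x = rng.poisson(t[:, None] * yp)

    return CountMatrix(
        counts=x,
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        depths=np.maximum(np.rint(t).astype(np.int64), 1),
        metadata={**cm.metadata, "null_seed": spec.seed,
                  "null_depth_mode": spec.depth_mode, "target_depths": t,
                  "panel_row_sums": x.sum(axis=1)},
    )
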
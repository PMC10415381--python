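"""Synthetic UMI counts from the latent-expression measurement model.

Latent expression ``z_ij`` for gene ``j`` is Gamma(alpha_j, beta_j) with
``mu_j = alpha_j beta_j`` and ``sigma_jj = alpha_j beta_j^2``; cross-gene
dependence comes from a Gaussian copula with correlation matrix ``R``:
``v_i ~ N(0, R)``, ``z_ij = F_j^{-1}(Phi(v_ij))``.  Counts are then Poisson,
``x_ij ~ Poisson(s_i z_ij)``, independently across cells and genes given
``z``.  Marginally each gene is negative binomial — the standard model for
droplet-based UMI data.

Note the copula correlation is not exactly the Pearson correlation of the
``z``'s: skewed Gamma marginals attenuate it slightly (a few percent for
over-dispersion around 0.5), which matters when checking recovery of a
target correlation.

Sequencing depths are either constant, user-supplied, or drawn from a
lognormal — a long-tailed distribution matching what droplet experiments
produce.  The default simulated cell-type has depths with median 5000 and
log-scale spread 0.5.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import CountMatrix

__all__ = [
    "SimulationSpec",
    "simulate_counts",
    "block_correlation",
    "sample_depths",
    "default_marginals",
]


@dataclass
class DepthModel:
    """Sequencing-depth model: 'constant', 'lognormal', or a fixed vector."""

    kind: str = "lognormal"
    value: float = 5000.0  # constant depth, or lognormal median
    sigma: float = 0.5  # lognormal log-scale spread
    vector: np.ndarray | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n <= 0:
            raise ValueError("n must be positive")
        if self.kind == "fixed":
            v = np.asarray(self.vector)
            if v is None or len(v) != n or np.any(v <= 0):
                raise ValueError("fixed depth vector must be positive, length n")
            return v.astype(np.int64)
        if self.value <= 0 or (self.kind == "lognormal" and self.sigma <= 0):
            raise ValueError("depth parameters must be positive")
        if self.kind == "constant":
            return np.full(n, int(round(self.value)), dtype=np.int64)
        if self.kind == "lognormal":
            # exp of N(log median, sigma^2) has median = the requested value
            d = rng.lognormal(mean=np.log(self.value), sigma=self.sigma, size=n)
            return np.maximum(np.rint(d).astype(np.int64), 1)
        raise ValueError(f"unknown depth model: {self.kind!r}")


@dataclass
class SimulationSpec:
    """Marginal Gamma parameters, copula correlation and depth model."""

    mu: np.ndarray
    sigma_jj: np.ndarray
    R: np.ndarray
    n_cells: int
    depth_model: DepthModel = field(default_factory=DepthModel)
    seed: int = 0
    repair_R: bool = False

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma_jj = np.asarray(self.sigma_jj, float)
        self.R = np.asarray(self.R, float)
        p = len(self.mu)
        if np.any(self.mu <= 0) or np.any(self.sigma_jj <= 0):
            raise ValueError("marginal mu and sigma_jj must be positive")
        if self.R.shape != (p, p):
            raise ValueError("R shape must match number of genes")
        if not np.allclose(self.R, self.R.T):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("R must have unit diagonal")

    @property
    def alpha(self) -> np.ndarray:
        """Gamma shape: alpha_j = mu_j^2 / sigma_jj."""
        return self.mu**2 / self.sigma_jj

    @property
    def beta(self) -> np.ndarray:
        """Gamma scale: beta_j = sigma_jj / mu_j."""
        return self.sigma_jj / self.mu


def nearest_correlation(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at zero and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 0.0, None)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A


def simulate_counts(
    spec: SimulationSpec, *, return_latent: bool = False
) -> CountMatrix | tuple[CountMatrix, np.ndarray]:
    """Draw a cells-by-genes UMI count matrix from the copula model.

    Deterministic given ``spec.seed``.  The simulated genes represent a
    panel within a larger transcriptome, so the returned matrix carries the
    drawn depths ``s_i`` (the full-transcriptome totals the Poisson rates
    were scaled by), not the row sums of the panel alone.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.R
    n, p = spec.n_cells, len(spec.mu)

    min_eig = float(np.linalg.eigvalsh(R)[0])
    if min_eig < -1e-10:
        if not spec.repair_R:
            raise ValueError(
                f"R is not positive semi-definite (min eigenvalue {min_eig:.3g}); "
                "set repair_R=True to project to the nearest correlation matrix"
            )
        R = nearest_correlation(R)

    L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    v = rng.standard_normal((n, p)) @ L.T
    uniforms = stats.norm.cdf(v)
    # guard the Gamma quantile function against exactly 0/1
    uniforms = np.clip(uniforms, 1e-15, 1 - 1e-15)
    z = stats.gamma.ppf(uniforms, a=spec.alpha, scale=spec.beta)

    s = spec.depth_model.sample(n, rng)
    x = rng.poisson(s[:, None] * z)

    cm = CountMatrix(
        counts=x,
        gene_ids=[f"g{j:05d}" for j in range(p)],
        cell_ids=[f"c{i:05d}" for i in range(n)],
        depths=s,
        metadata={"seed": spec.seed, "panel_row_sums": x.sum(axis=1)},
    )
    if return_latent:
        return cm, z
    return cm


def block_correlation(
    p: int,
    n_blocks: int,
    within: float | Sequence[float],
    between: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-structured correlation matrix with true cluster labels.

    Genes are split into ``n_blocks`` contiguous groups of (near-)equal
    size; correlation is ``within`` inside a group (a scalar, or one value
    per block for modules of heterogeneous connectivity) and ``between``
    across groups, with unit diagonal.  Returns ``(R, labels)``.
    """
    if p < n_blocks or n_blocks < 1:
        raise ValueError("need 1 <= n_blocks <= p")
    withins = np.broadcast_to(np.asarray(within, float), (n_blocks,))
    labels = np.repeat(np.arange(n_blocks), int(np.ceil(p / n_blocks)))[:p]
    R = np.full((p, p), float(between))
    for b in range(n_blocks):
        m = labels == b
        R[np.ix_(m, m)] = withins[b]
    np.fill_diagonal(R, 1.0)
    min_eig = float(np.linalg.eigvalsh(R)[0])
    if min_eig < -1e-10:
        raise ValueError(
            f"within={within}, between={between} gives a non-PSD matrix "
            f"(min eigenvalue {min_eig:.3g})"
        )
    return R, labels


def sample_depths(n: int, model: DepthModel, seed: int = 0) -> np.ndarray:
    """Draw a depth vector; deterministic given the seed."""
    return model.sample(n, np.random.default_rng(seed))


def default_marginals(
    p: int,
    seed: int = 0,
    *,
    mu_range: tuple[float, float] = (2e-5, 2e-1),
    theta: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-uniform relative-expression means with common over-dispersion.

    Means span four decades by default — mean counts of roughly 0.1 to
    1000 per cell at a depth of 5000, the dynamic range of the top few
    thousand expressed genes in droplet data; ``sigma_jj = theta * mu_j^2``
    gives every gene the same over-dispersion.
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log(mu_range[0]), np.log(mu_range[1])
    mu = np.exp(rng.uniform(lo, hi, size=p))
    return mu, theta * mu**2
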
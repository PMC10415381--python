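import numpy as np
import pytest

from cscore.io import CountMatrix
from cscore.simulate import DepthModel, SimulationSpec, default_marginals, simulate_counts

LONG_TAILED = DepthModel("lognormal", value=5000.0, sigma=1.0)


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """3 cells x 4 genes with hand-checkable depths."""
    counts = np.array([[1, 2, 0, 3], [0, 1, 4, 0], [2, 2, 2, 2]])
    return CountMatrix(
        counts=counts,
        gene_ids=["gA", "gB", "gC", "gD"],
        cell_ids=["c1", "c2", "c3"],
    )


@pytest.fixture(scope="session")
def independent_cm() -> CountMatrix:
    """100 independent Gamma-Poisson genes, 1000 cells, long-tailed depths."""
    mu, sigma_jj = default_marginals(100, seed=7)
    spec = SimulationSpec(
        mu=mu, sigma_jj=sigma_jj, R=np.eye(100), n_cells=1000,
        depth_model=LONG_TAILED, seed=7,
    )
    return simulate_counts(spec)


def rng_counts(seed: int, n: int = 12, p: int = 6) -> CountMatrix:
    """Small random count matrix for round-trip / property tests."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(3.0, size=(n, p))
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(p)],
        cell_ids=[f"c{i}" for i in range(n)],
    )
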
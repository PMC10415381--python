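# cscore

Cell-type-specific gene co-expression estimation and testing from
single-cell RNA-seq UMI counts.

## The problem

Estimating which genes are co-expressed within one cell type from droplet
scRNA-seq data is harder than correlating normalized counts. Two artifacts
get in the way:

1. **Sequencing-depth variation.** Cells differ several-fold in total UMI
   count. Normalization does not fully remove the shared depth signal, so
   independent genes can look correlated.
2. **Measurement attenuation.** UMI counts are a noisy Poisson readout of
   the underlying expression. Correlations computed on counts (or any
   transform of them) are shrunk toward zero by the factor
   `a_j = sqrt(s·CV_j² / (1/μ_j + s·CV_j²))` per gene — close to 1 for
   highly expressed genes, near 0 for weakly expressed ones. The result is
   a *mean-correlation bias*: high expressors look more connected than
   they are, and real co-expression among weak genes is missed.

## The model

For cell *i* with sequencing depth *s_i* (total UMI count) and gene *j*,

    x_ij | z_ij ~ Poisson(s_i · z_ij),

where `z_i = (z_i1, …, z_ip)` is the latent relative expression with mean
`μ_j` and covariance `σ_jj'`. Co-expression is the latent correlation
`ρ_jj' = σ_jj' / sqrt(σ_jj σ_j'j')` — a quantity about expression, not
about counts. First and second moments of the counts give three estimating
equations,

    x_ij                         = s_i μ_j + ε_ij
    (x_ij − s_i μ_j)² − s_i μ_j  = s_i² σ_jj + η_ij
    (x_ij − s_i μ_j)(x_ij' − s_i μ_j') = s_i² σ_jj' + ξ_ijj'

each solved by weighted least squares in closed form. Weights are the
inverse residual variances `w_ij = 1/(s_i μ_j + s_i² σ_jj)` and are
refreshed by iteratively re-weighted least squares (IRLS), with the
per-gene over-dispersion `θ_j = σ_jj/μ_j²` regularized to its cross-gene
median for stability. Under the null hypothesis that two genes are
independent, the standardized covariance

    T_jj' = Σ_i s_i²(x_ij − s_i μ_j)(x_ij' − s_i μ_j') g_ijj'
            / sqrt(Σ_i s_i⁴ (s_i μ_j + s_i² σ_jj)(s_i μ_j' + s_i² σ_j'j') g_ijj'²)

is asymptotically N(0, 1), giving analytic p values for every pair, with
Benjamini-Hochberg control of the FDR across pairs.

The package also ships a Gamma-Poisson Gaussian-copula count simulator, a
permute-and-resample null generator, normalization-based Pearson/Spearman
baselines, two-group differential co-expression with a label-permutation
test and module extraction, and evaluation metrics (attenuation factor,
precision-recall, adjusted Rand index, subspace distance).

## Worked example

```python
import numpy as np
from cscore import (SimulationSpec, DepthModel, block_correlation,
                    simulate_counts, estimate_network,
                    extract_modules, adjusted_rand_index)
from cscore.simulate import default_marginals

# four co-expressed modules, 100 genes, 2000 cells, long-tailed depths
mu, sigma_jj = default_marginals(100, seed=0, mu_range=(1e-5, 1e-2))
R, truth = block_correlation(100, 4, within=[0.2, 0.4, 0.6, 0.8])
spec = SimulationSpec(mu=mu, sigma_jj=sigma_jj, R=R, n_cells=2000,
                      depth_model=DepthModel("lognormal", 5000, 1.0), seed=0)
cm = simulate_counts(spec)

res = estimate_network(cm)
print(f"converged in {res.moments.iterations} iterations "
      f"(theta = {res.moments.theta:.3f})")
edges = res.edge_list()
sig = edges[edges.q < 0.05]
print(f"{len(sig)} of {len(edges)} gene pairs significant at q < 0.05")

modules = extract_modules(res.rho, None, 4, gene_ids=res.gene_ids)
ari = adjusted_rand_index(list(modules.values()), truth)
print(f"module recovery ARI vs planted blocks: {ari:.2f}")
```

prints

```
converged in 2 iterations (theta = 0.495)
1081 of 4950 gene pairs significant at q < 0.05
module recovery ARI vs planted blocks: 1.00
```

The IRLS settles in two reweighting steps and recovers the common
over-dispersion (0.5) almost exactly; the four planted modules — including
the weakly connected one at within-correlation 0.2, whose genes sit at
mean counts well below 1 per cell — are recovered perfectly.

The same pipeline is available from the shell:

```
cscore simulate --genes 100 --cells 2000 --blocks 4 --seed 0 --out sim
cscore estimate sim.counts --out net        # rho/p/q matrices + edge list
cscore permute-null sim.counts --out null   # no-co-expression control data
cscore diff g1.counts g2.counts -B 100 --modules 4 --out diff
```

Every command writes a JSON manifest with the effective configuration and
seed; repeated runs with the same seed are byte-identical.

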
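# Methods

## Model and estimand

UMI counts are modeled as a Poisson readout of latent relative expression:
for cell *i* of one cell type, with sequencing depth `s_i` (the cell's
total UMI count over the full gene set), the count for gene *j* is
`x_ij | z_ij ~ Poisson(s_i z_ij)`, independently across genes given `z`.
The latent vector `z_i` has mean `μ` and covariance `Σ = (σ_jj')`; no
distributional form is assumed for `z` in estimation. The estimand is the
latent correlation `ρ_jj' = σ_jj'/√(σ_jj σ_j'j')`, i.e. co-expression of
expression levels, not of counts. The measurement model implies
`E x_ij = s_i μ_j`, `Var x_ij = s_i μ_j + s_i² σ_jj` and
`E (x_ij − s_i μ_j)(x_ij' − s_i μ_j') = s_i² σ_jj'`, which is what makes
moment-based correction of both depth variation and Poisson attenuation
possible.

## Estimation

Each of the three moment equations is a one-parameter weighted least
squares problem with a closed-form ratio solution:

- mean: `μ̂ = Σ w_i s_i x_i / Σ w_i s_i²`
- variance: `σ̂_jj = Σ h_i s_i²[(x_i − s_i μ̂)² − s_i μ̂] / Σ h_i s_i⁴`
- covariance: `σ̂_jj' = Σ g_i s_i²(x_ij − s_i μ̂_j)(x_ij' − s_i μ̂_j') / Σ g_i s_i⁴`

These are the unique minimizers of the stated objectives (verified in the
test suite against a bounded scalar minimizer to 1e-8). The IRLS loop:

1. initialize `μ̂, σ̂_jj` by ordinary least squares (unit weights);
2. regularize over-dispersion: `θ̂ = median_j σ̂_jj/μ̂_j²` over genes with
   `μ̂_j > 0`, floored at 0 (the weights below require `θ ≥ 0`; a negative
   median can only occur when most variance estimates are negative, i.e.
   essentially Poisson data);
3. set `w_ij = 1/(s_i μ̂_j + s_i² μ̂_j² θ̂)`, update `μ̂_j`, then
   `h_ij = w_ij²` recomputed at the updated mean, update `σ̂_jj`;
4. stop when `Δ = max_j |log σ̂_jj⁽ᵗ⁾ − log σ̂_jj⁽ᵗ⁻¹⁾| < 0.05` (genes with
   non-positive variance estimates are excluded from Δ), hard cap at 10
   iterations. On model data the loop converges in 2-3 iterations.

Pairwise covariances use `g_ijj' = u_ij u_ij'` with
`u_ij = 1/(s_i μ̂_j + s_i² μ̂_j² θ̂)` and are computed for all pairs at once
as weighted cross-products (two rank-n matrix products); the unit tests
pin this to the per-pair loop. Correlations landing outside [−1, 1] —
possible for moment ratios — are clipped with the count logged. Genes with
`σ̂_jj ≤ 0` (typically near-zero expression) or with all-zero counts are
flagged and zeroed out of the network rather than aborting the run:
`ρ = 0`, `p = q = 1` on their rows.

## Independence test

Under independence of `z_ij` and `z_ij'`, the error variance of the
covariance equation factorizes as
`Var(ξ_ijj') = (s_i μ_j + s_i² σ_jj)(s_i μ_j' + s_i² σ_j'j') = 1/g_ijj'`,
so the standardized covariance `T = σ̂_jj'/√Var(σ̂_jj')` is asymptotically
N(0, 1). By default the variance factors in the denominator reuse the
regularized variances `μ̂² θ̂` — the same quantities that define `g` — in
which case the denominator simplifies to `√(Σ_i s_i⁴ g_ijj')`. Plugging
the raw per-gene `σ̂_jj` instead is exposed as an option
(`regularized_test_variance=False`); the two differ negligibly on model
data, and the regularized default is what keeps the statistic stable for
noisy genes. Two-sided p values come from the normal tail; q values are
Benjamini-Hochberg over all tested (unflagged) off-diagonal pairs.

## Simulator

Latent expression is Gamma: `z_ij ~ Gamma(α_j, β_j)` with
`μ_j = α_j β_j`, `σ_jj = α_j β_j²`; marginally the counts are negative
binomial (goodness-of-fit tested at n = 50,000). Cross-gene dependence is a
Gaussian copula: `v_i ~ N(0, R)`, `z_ij = F_j⁻¹(Φ(v_ij))`. The copula
correlation is not exactly the Pearson correlation of the latent values —
skewed Gamma marginals attenuate it by a few percent at over-dispersion
0.5 — so recovery of a target correlation is only expected to ±0.05, and
that tolerance is part of the experiment definitions, not a fitted number.

Defaults define the synthetic study conditions:

- marginal means log-uniform over (2e-5, 2e-1) — four decades, mean counts
  ~0.1 to 1000 per cell at depth 5000, the dynamic range of a
  top-expressed gene panel in droplet data;
- common over-dispersion θ = 0.5 (`σ_jj = 0.5 μ_j²`);
- depths lognormal with median 5000 and log-sd 1.0, a long-tailed
  distribution spanning roughly 500-40,000.

The simulated genes represent a *panel* inside a larger transcriptome, so
the returned matrix carries the drawn `s_i` as depths (the totals the
Poisson rates were scaled by), not the panel's own row sums. Using panel
row sums as depths injects compositional noise that has no analogue in
real data, where depths come from ~20k genes; empirically it breaks the
null calibration of T (sd 1.17 instead of 1.00).

What the simulator does **not** emulate: ambient RNA, doublets, batch
effects, cell-to-cell depth/expression dependence, zero inflation beyond
the NB, or gene-specific over-dispersion heterogeneity. Passing tests
therefore demonstrate correctness under the measurement model, not
robustness to those artifacts.

## Permutation null

From any count matrix: `y_ij = x_ij/s_i`, each gene's `y` column is
independently permuted across cells (destroying all cross-gene dependence,
exactly preserving each gene's marginal profile), and counts are redrawn
as `Poisson(t_i y^p_ij)` with target depth `t_i` either the observed `s_i`
(varying-depth null), the median depth (constant-depth null) or a custom
vector. The returned matrix carries `t_i` as depths — the panel's realized
row sums again carry panel-compositional noise that full-transcriptome
depths would not — with realized sums kept in metadata.

## Baselines

Library-size scaling (`10⁴·x/s`) and log-normalization (`log(10⁴·x/s+1)`,
natural log) with Pearson or Spearman correlation (average ranks for the
heavy ties of count data). Significance uses `t = r√((n−2)/(1−r²))`
referred to a standard normal, two-sided — the normal reference rather
than t_{n−2} is deliberate, matching how such baselines are commonly
evaluated, and is immaterial at the cell counts involved. These baselines
exist to demonstrate the two artifacts: depth-driven p-value inflation on
null data, and expression-dependent attenuation of true correlations.

## Differential co-expression

Groups are balanced by downsampling, networks estimated per group, and the
per-pair difference `Δρ̂` tested by relabeling cells into two random equal
pseudo-groups B times (default 100) and re-running the full estimation on
each — expensive but faithful to how the observed difference is computed.
The empirical two-sided p value uses the add-one estimator
`(1 + #{|Δ̂ᵇ| ≥ |Δ̂|})/(1 + B)`, so attainable p values are exactly
`{1/(B+1), …, 1}`. The permutation design assumes the two groups share
marginal expression distributions (same cell type across conditions);
groups with systematically different marginals violate exchangeability.

Module extraction replaces WGCNA with average-linkage hierarchical
clustering on distance `1 − |weight|` (soft-threshold power 1), restricted
to significant pairs when a mask is given. Genes with no retained edge are
returned as unassigned (label 0, the analogue of WGCNA's grey module);
without this, flagged all-zero genes absorb the cluster cuts as maximally
distant singletons. Both a fixed-k cut and a height cut are exposed.

## Evaluation metrics

- attenuation factor `a = √(s·CV²/(1/μ + s·CV²))`, strictly increasing in
  each argument;
- per-gene average co-expression (mean off-diagonal ρ per gene);
- precision-recall over pair scores with trapezoid area over recall (at
  tied recall the precision of the most stringent threshold is kept);
- adjusted Rand index (pair-counting, chance-corrected);
- subspace distance `‖UUᵀ − VVᵀ‖_F/√(2k) = √(mean sin²θ_i)` over principal
  angles — one of several equivalent conventions; this one is fixed and
  normalized to [0, 1];
- mean-correlation-bias diagnostic: Spearman correlation between per-gene
  mean expression and per-gene average estimated co-expression.

## Experiment designs (`cscore.experiments`)

All experiments derive their randomness from one seed via `SeedSequence`
children and run in seconds on one CPU; sizes were chosen so the summary
statistics are stable at the tolerances the claims are stated with.

- **Convergence**: 25 runs of 100 independent genes × 1000 cells; fraction
  converging within 5 IRLS iterations.
- **Null centering**: one 200-gene × 1000-cell source matrix, 12
  permutation-null replicates under observed (varying) depths; grand mean
  of per-gene average co-expression and its Spearman trend against
  expression, measured on the replicate-averaged profile. A single
  replicate's trend statistic has null sd ≈ 0.09 at p = 200, so the
  repeated-permutation design is what makes the "no trend" claim
  measurable at the 0.1 level.
- **Null calibration**: 150 independent genes × 1000 cells → 11,175 null
  pairs (≥10,000 after flagged genes drop out); KS test of p values
  against Uniform[0,1] and the first two moments of T.
- **Correlation recovery**: 250 pairs at copula correlation 0.5, pair
  means log-uniform over four decades, 1000 cells; mean ρ̂ over unflagged
  pairs (flagged genes are structural zeros and would measure the flagging
  rule, not the estimator), expression trend, and the log-normalized
  Pearson baseline in the lowest-expression quartile.
- **Module recovery**: 100 genes × 2000 cells, four planted modules with
  heterogeneous within-correlations (0.2, 0.4, 0.6, 0.8) over means
  log-uniform in (1e-5, 1e-2) — the low-to-moderate expression band where
  measurement error dominates and the estimators separate. Clustering runs
  on the estimate matrix directly (the significance mask belongs to the
  differential workflow). With homogeneous strong blocks over a
  well-expressed panel both estimators saturate at ARI 1 and the
  comparison is uninformative; the heterogeneous design is the stand-in
  for a realistic modular network with weak modules.
- **Differential null**: two groups of 500 cells from one generative model
  over 50 genes, B = 100 label permutations; fraction of p below α
  compared with the binomial band (plus the 1/(B+1) grid resolution).

## Known limitations

- Moment estimates of ρ for genes with mean counts ≪ 0.1 per cell are
  noisy and may be clipped at ±1 or flagged; the estimator corrects
  attenuation bias but cannot create information that is not in the
  counts.
- The Σ_j μ_j = 1 constraint of the relative-expression formulation is not
  enforced after gene filtering; μ̂ is reported on the scale implied by the
  depths used.
- The asymptotic N(0,1) null needs moderate cell numbers; at very small n
  the tails are heavier than normal.
- Permutation-based differential testing assumes shared marginals between
  groups and re-runs the full estimation per permutation, so it is meant
  for gene panels (hundreds of genes), not whole transcriptomes.
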
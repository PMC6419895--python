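# Methods

## Model

Counts `c_ij` for taxon i in sample j are treated as a multinomial draw
from latent relative abundances; the latent absolute (basis) abundances
are assumed log-normal across samples with per-taxon variance `w_i = ω_i²`
and pairwise Pearson correlation `ρ_ij` on the log scale. Because only
relative information survives sequencing, inference operates on the
log-ratio variances `t_ij = Var[log(f_i/f_j)]`, which are invariant to
per-sample scaling and satisfy `t_ij = w_i + w_j − 2 ρ_ij ω_i ω_j`.

Summing over partners and assuming most cross terms vanish (the sparsity
assumption) gives the linear system `M w = t_row` with `M_ii = d − 1`,
`M_ij = 1`, `t_row_i = Σ_{j≠i} t_ij`. The unexcluded `M` equals
`(d−2)I + 𝟙𝟙ᵀ`, which is positive definite for `d ≥ 2`, so the base solve
cannot be singular. Correlations follow by inverting the `t_ij` identity
and clipping to `[−1, 1]`.

## Estimation procedure

1. **Fractions.** Each sample column with counts `c` parameterizes
   Dirichlet(`c + pseudocount`); fractions are one posterior draw
   (stochastic mode) or the posterior mean `(c+ψ)/Σ(c+ψ)` (deterministic
   mode). Pseudocount default 1, the convention of existing
   implementations; it guarantees strictly positive fractions.
2. **Variation matrix.** Sample variance of the pairwise log-ratio
   differences, computed via `Var(a−b) = Var a + Var b − 2 Cov(a,b)` on
   the log fractions (one d×d covariance instead of d² passes). Natural
   log; unbiased n−1 denominator by default, with `ddof=0` exposed because
   the choice is not universal. Tiny negative rounding residues are
   clipped to 0 and exact symmetry/zero diagonal are enforced.
3. **Exclusion loop.** Up to `exclusion_iterations` (default 10) rounds:
   solve for `w`, form `ρ` (clipped inside the loop, so the pair search
   sees clipped values), find the pair maximizing |ρ| strictly above
   `exclusion_threshold` (default 0.1; ties break to smallest indices),
   and remove it — its `t_ij` leaves both row sums, and the four affected
   entries of `M` are decremented. A taxon participating in
   `d_active − 3` excluded pairs violates sparsity so broadly that its
   estimates are meaningless: it is promoted to full exclusion, its pairs
   are released (promotion can cascade as the limit shrinks), and its
   row/column — diagonal included — is reported NaN. Below 4 active taxa
   the system is ill-posed and the run errors out.
4. **Aggregation.** `iterations` (default 50; 20 in the recovery
   benchmarks) replicate estimations on fresh Dirichlet draws, combined
   by the entry-wise NaN-skipping median (robust, and NaN only when every
   replicate excluded the entry). Exclusion state resets each replicate.
   With pre-computed fractions, replication is pointless and collapses to
   one deterministic pass — the mode that makes independent
   implementations exactly comparable.

Solved variances are clamped below at `variance_floor` (default 1e-6),
keeping the `ρ` denominator away from zero; the floor is part of the
algorithm's contract and the test oracles apply it too.

**Reproducibility.** Every random draw derives from a single integer
seed. Replicate k uses the substream `SeedSequence(seed, spawn_key=(k,))`;
bootstrap table k resamples row r with the substream keyed `(seed, k, r)`.
Results are therefore bit-identical for any thread count, and bootstrap
generation parallelizes without coordination.

## Significance testing

Bootstrap tables resample each row independently, with replacement, from
its own counts: associations are destroyed, marginal count distributions
preserved. (A `permute` mode — shuffling within rows — is exposed as a
config option; with-replacement is the default convention.) Correlations
are re-estimated on each bootstrap table with the same configuration as
the observed run, and `b_ij` counts replicates with
`|ρ̂_boot| ≥ |ρ̂_obs|` (two-sided; a one-sided option exists).

The naive `b/m` understates P-values — it can return 0 — because it
ignores that the resampling pool is finite and can recall the observed
arrangement. The estimator used here averages the binomial exceedance
CDF over the pool of `m_t` equally likely distinct resamples:

```
p = (1/m_t) Σ_{j=1..m_t} BinomCDF(b; m, j/m_t)
```

with `m_t` for a pair taken as the product of the two rows'
multiset-permutation counts `n!/Π r_k!` (computed in log space via
log-gamma; rows must be integer-valued, which is why real-valued
abundance tables are accepted for correlation but rejected here — such
users should rely on the `(b+1)/(m+1)` limit). The product convention is
conservative: with-replacement resampling actually has more distinct
outcomes than orderings, so the reported P-values err slightly upward.

Numerics: the sum is evaluated exactly for `m_t ≤ 10,000` (vectorized
binomial CDF). Beyond that, it is a right-endpoint Riemann sum of
`∫₀¹ BinomCDF(b; m, q) dq = (b+1)/(m+1)`, and the Euler–Maclaurin
endpoint correction gives `p ≈ (b+1)/(m+1) − (g(0) − g(1))/(2 m_t)` with
error `O(m_t⁻²)` — at the cutoff that error is below 1e-9, and at
`m_t = 1e12` the value agrees with the limit form to better than 1e-6.
`b = m` returns exactly 1 in every regime. The estimator is strictly
positive for every pool with `m_t ≥ 2`; a pool of size 1 means both rows
are constant, in which case every resample reproduces the observed data,
`b = m` is forced, and `p = 1`.

Two edge conventions the formulae do not decide: a bootstrap replicate
can itself exclude a taxon (NaN correlation) — such entries are dropped
from both `b` and the effective `m` for that entry rather than counted as
non-exceedances, which would bias `p` downward; and covariance replicates
are aggregated with the same NaN-skipping median as correlations.
Benjamini–Hochberg adjustment over the d(d−1)/2 upper-triangle tests is
available in the edge-filter step but off by default: raw P-values are
reported, and the correction choice is left to the user.

## Synthetic data

`simulate_counts` draws per-sample log-abundances from
N(`log_mean`, `basis_covariance`), exponentiates, normalizes, and draws
counts from Multinomial(depth, fractions) — exactly the regime the
log-ratio approximation is derived under, which makes parameter recovery
a fair benchmark. `planted_pair_spec` gives unit basis variances with a
single correlated pair. The generator emulates compositional closure,
finite sequencing depth, and log-normal between-sample variation; it does
**not** emulate sequencing error, chimeras, OTU-clustering artifacts,
batch effects, or taxa absent from the reference — so passing recovery
tests demonstrates correctness of the estimator under its own model, not
robustness to those real-data pathologies.

Benchmark problem sizes are chosen to exercise the asymptotics while
staying comfortably interactive: recovery uses d=10 taxa, n=2000 samples,
depth 1e5, one pair planted at ρ=0.8, 20 replicate estimations; null
calibration uses d=8, n=100, depth 2000, 200 bootstrap replicates with
10 estimation replicates each. With 28 pairs, the Kolmogorov–Smirnov
statistic of perfectly uniform P-values has median ≈ 0.16, so observed
KS values in the 0.1–0.25 range across seeds are consistent with good
calibration.

## Degenerate inputs and limitations

- Tables need ≥ 2 taxa and ≥ 2 samples; filtering that leaves fewer than
  2 taxa errors with advice to relax thresholds. Filtering is inclusive
  (≥) at both thresholds and idempotent.
- Small, noisy tables at the default threshold 0.1 can exhaust the
  exclusion loop until fewer than 4 taxa remain; this raises rather than
  returning silently meaningless numbers. Raising the threshold or
  capping `exclusion_iterations` is the remedy.
- The sparsity assumption is structural: with many strong correlations
  the basis solve is biased no matter the exclusion budget.
- No cross-tool bit-compatibility of random draws is attempted;
  equivalence with other implementations is meaningful only in the
  deterministic pre-computed-fractions mode.
- HDF5 BIOM input is out of scope; the TSV dialect is the interface.
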
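"""Bootstrap significance testing with the unbiased P-value estimator.

Builds a small table with one strong planted association, estimates the
observed correlations, re-estimates on bootstrap tables whose rows are
resampled independently (destroying all associations), and converts the
exceedance counts into unbiased empirical P-values.
"""

import numpy as np

import sparcor as sc

table, _ = sc.simulate_counts(
    sc.planted_pair_spec(d=8, n=100, rho=0.9, depth=2000), seed=5
)
cfg = sc.EstimationConfig(iterations=5)
observed = sc.infer_correlations(table, cfg, seed=6)

m = 100  # bootstrap replicates
bs = sc.BootstrapSet(source=table, count=m, seed=7)
boot_corrs = [
    sc.infer_correlations(bs.table(k), cfg, seed=100 + k).correlation
    for k in range(m)
]
p = sc.pvalue_matrix(observed, boot_corrs, table)

print(f"observed rho for the planted pair: {observed.correlation[0, 1]:.3f}")
print(f"its P-value over {m} bootstrap replicates: {p[0, 1]:.4f}")
iu = np.triu_indices(8, 1)
null_ps = np.array([p[i, j] for i, j in zip(*iu) if (i, j) != (0, 1)])
null_ps = null_ps[np.isfinite(null_ps)]
print(f"null-pair P-values: min {null_ps.min():.3f}, "
      f"median {np.median(null_ps):.3f}, max {null_ps.max():.3f}")
print("The planted pair should be far below 0.05; the independent pairs "
      "should spread roughly uniformly over (0, 1] and never reach "
      "exactly 0 -- the estimator accounts for the finite pool of "
      "distinct resamples.")
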
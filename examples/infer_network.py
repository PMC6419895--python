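"""Estimate a correlation network from a simulated count table.

Simulates 10 taxa over 1000 samples with one pair of taxa planted at basis
correlation 0.8, runs the median-of-replicates estimator, and compares
the estimates against the known truth.
"""

import numpy as np

import sparcor as sc

spec = sc.planted_pair_spec(d=10, n=1000, rho=0.8, depth=50_000)
table, truth = sc.simulate_counts(spec, seed=1)
print(f"simulated table: {table.n_otus} taxa x {table.n_samples} samples, "
      f"depth {table.counts.sum(axis=0)[0]} reads/sample")

cfg = sc.EstimationConfig(iterations=20, exclusion_iterations=10,
                          exclusion_threshold=0.1)
result = sc.infer_correlations(table, cfg, seed=2)

print(f"planted pair ({table.otu_ids[0]}, {table.otu_ids[1]}): "
      f"true rho = 0.80, estimated rho = {result.correlation[0, 1]:.3f}")
null = result.correlation.copy()
np.fill_diagonal(null, 0.0)
null[0, 1] = null[1, 0] = 0.0
print(f"largest |rho| among the {10 * 9 // 2 - 1} truly independent pairs: "
      f"{np.nanmax(np.abs(null)):.3f}")
print("A good estimate puts the planted pair near 0.8 and every other "
      "pair near 0 despite the compositional closure of the data.")
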
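"""Synthetic compositional count tables with known basis correlations.

The generative model is the one the log-ratio estimator is derived under:
latent absolute abundances are log-normal, samples are independent, and
sequencing is multinomial at a fixed per-sample depth. Per sample, a
log-abundance vector is drawn from N(log_mean, basis_covariance),
exponentiated, normalized to the simplex, and counts are drawn from
Multinomial(depth, fractions). The true basis correlation matrix implied
by ``basis_covariance`` is returned alongside the table so estimators can
be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table_io import OtuTable

__all__ = ["BasisSpec", "simulate_counts", "planted_pair_spec"]


@dataclass(frozen=True)
class BasisSpec:
    """Parameters of the log-normal/multinomial generative model.

    depth is the per-sample total read count, either a single integer or a
    length-n vector of integers.
    """

    d: int
    n: int
    log_mean: np.ndarray = field(repr=False)
    basis_covariance: np.ndarray = field(repr=False)
    depth: int | np.ndarray = 100_000

    def __post_init__(self) -> None:
        lm = np.asarray(self.log_mean, dtype=float)
        cov = np.asarray(self.basis_covariance, dtype=float)
        object.__setattr__(self, "log_mean", lm)
        object.__setattr__(self, "basis_covariance", cov)
        if lm.shape != (self.d,):
            raise ValueError(f"log_mean must have shape ({self.d},)")
        if cov.shape != (self.d, self.d):
            raise ValueError(f"basis_covariance must be {self.d}x{self.d}")
        if not np.allclose(cov, cov.T):
            raise ValueError("basis_covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ValueError("basis_covariance is not positive semi-definite")
        depth = np.broadcast_to(np.asarray(self.depth), (self.n,))
        if np.any(depth < 1):
            raise ValueError("depth must be >= 1")

    def truth(self) -> np.ndarray:
        """Basis correlation matrix implied by the covariance."""
        sd = np.sqrt(np.diag(self.basis_covariance))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = self.basis_covariance / np.outer(sd, sd)
        rho = np.where(np.outer(sd, sd) > 0, rho, 0.0)
        np.fill_diagonal(rho, 1.0)
        return rho


def simulate_counts(
    spec: BasisSpec, seed: int | np.random.Generator = 0
) -> tuple[OtuTable, np.ndarray]:
    """Simulate a count table; returns (table, true basis correlation matrix).

    Column sums of the table equal the requested depth exactly (multinomial
    sampling conserves the per-sample total).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    log_abund = rng.multivariate_normal(
        spec.log_mean, spec.basis_covariance, size=spec.n, method="svd"
    )  # (n, d)
    abund = np.exp(log_abund)
    fractions = abund / abund.sum(axis=1, keepdims=True)
    depth = np.broadcast_to(np.asarray(spec.depth), (spec.n,))
    counts = np.empty((spec.d, spec.n), dtype=np.int64)
    for s in range(spec.n):
        counts[:, s] = rng.multinomial(int(depth[s]), fractions[s])
    otu_ids = tuple(f"OTU_{i}" for i in range(spec.d))
    sample_ids = tuple(f"S_{s}" for s in range(spec.n))
    return OtuTable(otu_ids, sample_ids, counts), spec.truth()


def planted_pair_spec(
    d: int, n: int, rho: float, depth: int = 100_000
) -> BasisSpec:
    """Unit basis variances with a single correlated pair (taxa 0 and 1).

    All other taxa are mutually independent; |rho| < 1 keeps the 2x2 block
    positive definite (eigenvalues 1 +/- rho).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if d < 4:
        raise ValueError("need d >= 4 taxa")
    cov = np.eye(d)
    cov[0, 1] = cov[1, 0] = rho
    return BasisSpec(
        d=d, n=n, log_mean=np.zeros(d), basis_covariance=cov, depth=depth
    )
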
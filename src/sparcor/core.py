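"""Basis-correlation estimation from log-ratio variances.

The estimator works on the variation matrix t_ij = Var[log(f_i/f_j)].
Writing omega_i^2 for the latent (un-normalized) basis variance of taxon i
and rho_ij for the basis Pearson correlation,

    t_ij = omega_i^2 + omega_j^2 - 2 rho_ij omega_i omega_j.

Under the sparsity assumption -- most pairs uncorrelated, so the cross
terms roughly cancel when summed over partners -- summing over j gives a
linear system for the basis variances alone:

    sum_{j != i} t_ij  =  (d - 1) w_i + sum_{j != i} w_j,    w_i = omega_i^2,

i.e. M w = t_row with M = I*(d-2) + ones. Solving it and inverting the
t_ij identity yields the correlation estimates. Pairs whose estimated
|rho| is large violate the sparsity assumption, so the strongest pair is
iteratively excluded from the sums (each exclusion removes t_ij from both
rows and decrements the corresponding entries of M) and the system is
re-solved. A taxon that ends up strongly correlated with nearly everything
cannot be handled by this scheme at all and is dropped with NaN estimates.

Replicate runs over fresh Dirichlet fraction draws are aggregated by the
entry-wise median.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .fractions import FractionMatrix, draw_fractions, variation_matrix
from .table_io import OtuTable

__all__ = [
    "EstimationConfig",
    "ExclusionState",
    "CorrelationResult",
    "solve_basis_variances",
    "correlations_from_basis",
    "find_strongest_pair",
    "estimate_once",
    "infer_correlations",
]

#: below this many active taxa the basis system is ill-posed
MIN_ACTIVE_OTUS = 4


@dataclass(frozen=True)
class EstimationConfig:
    """Tunable parameters of the correlation estimator.

    iterations
        Number of replicate Dirichlet-draw estimations aggregated by the
        median. Ignored (forced to 1) when fractions are supplied
        pre-computed.
    exclusion_iterations
        Maximum number of strongly correlated pairs removed from the basis
        system within one estimation.
    exclusion_threshold
        A pair is removed only if its current |rho| exceeds this (strict
        inequality).
    pseudocount
        Added to every count before Dirichlet parameterization.
    variance_floor
        Lower clamp on solved basis variances; keeps the rho denominator
        away from zero.
    seed
        Master seed; every random draw derives from it deterministically.
    threads
        Worker threads for replicate iterations. Affects wall time only:
        each iteration uses a substream keyed by (seed, iteration index),
        so results are identical for any thread count.
    ddof
        Delta degrees of freedom of the log-ratio variance (1 = unbiased
        n-1 denominator, the package convention).
    """

    iterations: int = 50
    exclusion_iterations: int = 10
    exclusion_threshold: float = 0.1
    pseudocount: float = 1.0
    variance_floor: float = 1e-6
    seed: int = 0
    threads: int = 1
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.exclusion_iterations < 0:
            raise ValueError("exclusion_iterations must be >= 0")
        if not 0.0 <= self.exclusion_threshold <= 1.0:
            raise ValueError("exclusion_threshold must be in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")


class ExclusionState:
    """Bookkeeping of excluded pairs and fully excluded taxa.

    Invariants: no pair in ``excluded_pairs`` touches an OTU in
    ``excluded_otus`` (such pairs are released on promotion), and
    ``pair_counts[i]`` equals the number of excluded pairs containing i.
    """

    def __init__(self, d: int) -> None:
        self.d = d
        self.excluded_pairs: set[tuple[int, int]] = set()
        self.excluded_otus: set[int] = set()
        self.pair_counts = np.zeros(d, dtype=int)

    @property
    def d_active(self) -> int:
        return self.d - len(self.excluded_otus)

    def active_indices(self) -> np.ndarray:
        return np.array(
            [i for i in range(self.d) if i not in self.excluded_otus], dtype=int
        )

    def exclude_pair(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("cannot exclude a diagonal pair")
        pair = (min(i, j), max(i, j))
        if pair in self.excluded_pairs:
            return
        self.excluded_pairs.add(pair)
        self.pair_counts[pair[0]] += 1
        self.pair_counts[pair[1]] += 1

    def exclude_otu(self, i: int) -> None:
        """Drop taxon i entirely, releasing every pair it participated in."""
        self.excluded_otus.add(i)
        released = {p for p in self.excluded_pairs if i in p}
        for a, b in released:
            self.pair_counts[a] -= 1
            self.pair_counts[b] -= 1
        self.excluded_pairs -= released
        self.pair_counts[i] = 0


@dataclass(frozen=True)
class CorrelationResult:
    """Estimated correlation and covariance matrices with exclusion notes.

    Rows/columns of taxa in ``excluded_otus`` are NaN (diagonal included);
    every other correlation entry is finite, in [-1, 1], with unit diagonal.
    """

    otu_ids: tuple[str, ...]
    correlation: np.ndarray = field(repr=False)
    covariance: np.ndarray = field(repr=False)
    excluded_otus: frozenset[str] = frozenset()


def solve_basis_variances(
    t: np.ndarray,
    ex: ExclusionState,
    variance_floor: float = 1e-6,
    min_active: int = MIN_ACTIVE_OTUS,
) -> np.ndarray:
    """Solve the basis-variance linear system M w = t_row.

    Over the active (non-excluded) taxa, t_row_i sums t_ij across active
    partners, M_ii = d_active - 1 and M_ij = 1; each excluded pair (i, j)
    removes t_ij from both row sums and decrements M_ii, M_jj, M_ij, M_ji.
    Solved variances below ``variance_floor`` are clamped to it.

    Returns a length-d vector with NaN at excluded taxa. ``min_active``
    exists to relax the d >= 4 well-posedness guard in controlled
    validation settings; production callers leave it alone.
    """
    active = ex.active_indices()
    da = len(active)
    if da < min_active:
        raise ValueError(
            f"only {da} active OTUs remain; the basis-variance system needs "
            f"at least {min_active} -- relax exclusion settings or filter less"
        )
    sub = t[np.ix_(active, active)]
    t_row = sub.sum(axis=1)
    m = np.ones((da, da)) + (da - 2) * np.eye(da)
    pos = {otu: k for k, otu in enumerate(active)}
    for i, j in ex.excluded_pairs:
        ai, aj = pos[i], pos[j]
        t_row[ai] -= sub[ai, aj]
        t_row[aj] -= sub[ai, aj]
        m[ai, ai] -= 1.0
        m[aj, aj] -= 1.0
        m[ai, aj] -= 1.0
        m[aj, ai] -= 1.0
    try:
        w_active = np.linalg.solve(m, t_row)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "basis-variance system is singular after exclusions"
        ) from exc
    w = np.full(ex.d, np.nan)
    w[active] = np.maximum(w_active, variance_floor)
    return w


def correlations_from_basis(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Invert t_ij = w_i + w_j - 2 rho sqrt(w_i w_j) for the correlations.

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i) sqrt(w_j)), clipped to
    [-1, 1]; unit diagonal. NaN basis variances (excluded taxa) propagate
    to their whole row and column, diagonal included.
    """
    sd = np.sqrt(w)
    with np.errstate(invalid="ignore"):
        rho = (w[:, None] + w[None, :] - t) / (2.0 * np.outer(sd, sd))
        rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    nan_mask = np.isnan(w)
    rho[nan_mask, :] = np.nan
    rho[:, nan_mask] = np.nan
    return rho


def find_strongest_pair(
    corr: np.ndarray, ex: ExclusionState, threshold: float
) -> tuple[int, int] | None:
    """Strongest not-yet-excluded pair by |rho|, or None if none exceeds
    ``threshold`` (strict). Ties break to the smallest i, then smallest j."""
    d = corr.shape[0]
    with np.errstate(invalid="ignore"):
        mag = np.where(np.isnan(corr), -np.inf, np.abs(corr))
    # restrict to the upper triangle of active, non-excluded pairs
    valid = np.triu(np.ones((d, d), dtype=bool), k=1)
    if ex.excluded_otus:
        idx = np.array(sorted(ex.excluded_otus), dtype=int)
        valid[idx, :] = False
        valid[:, idx] = False
    for i, j in ex.excluded_pairs:
        valid[i, j] = False
    mag = np.where(valid, mag, -np.inf)
    best = mag.max()
    if not best > threshold:
        return None
    # argwhere is row-major sorted, so the first hit is the lexicographic min
    i, j = np.argwhere(mag == best)[0]
    return int(i), int(j)


def estimate_once(fr: FractionMatrix, cfg: EstimationConfig) -> CorrelationResult:
    """One full estimation pass on a fixed fraction matrix.

    Alternates solve -> correlations -> exclude-strongest-pair for at most
    ``cfg.exclusion_iterations`` rounds, promoting a taxon to full exclusion
    once it participates in d_active - 3 excluded pairs, then reports the
    correlation and covariance of the final solve.
    """
    t = variation_matrix(fr, ddof=cfg.ddof)
    d = fr.n_otus
    ex = ExclusionState(d)
    w = solve_basis_variances(t, ex, cfg.variance_floor)
    corr = correlations_from_basis(t, w)
    for _ in range(cfg.exclusion_iterations):
        pair = find_strongest_pair(corr, ex, cfg.exclusion_threshold)
        if pair is None:
            break
        ex.exclude_pair(*pair)
        # promote any taxon now excluded with almost every partner; releasing
        # its pairs can push another taxon over the (shrinking) limit
        promoted = True
        while promoted:
            promoted = False
            limit = ex.d_active - 3
            for i in range(d):
                if i not in ex.excluded_otus and ex.pair_counts[i] >= limit:
                    ex.exclude_otu(i)
                    promoted = True
                    break
        w = solve_basis_variances(t, ex, cfg.variance_floor)
        corr = correlations_from_basis(t, w)
    sd = np.sqrt(w)
    cov = corr * np.outer(sd, sd)
    diag = np.where(np.isnan(w), np.nan, w)
    np.fill_diagonal(cov, diag)
    excluded_ids = frozenset(fr.otu_ids[i] for i in ex.excluded_otus)
    return CorrelationResult(fr.otu_ids, corr, cov, excluded_ids)


def _iteration_result(
    table: OtuTable, cfg: EstimationConfig, seed: int, index: int
) -> CorrelationResult:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )
    fr = draw_fractions(table, cfg.pseudocount, rng)
    return estimate_once(fr, cfg)


def infer_correlations(
    table: OtuTable | None,
    cfg: EstimationConfig | None = None,
    seed: int | None = None,
    fractions: FractionMatrix | None = None,
) -> CorrelationResult:
    """Median correlation/covariance over replicate Dirichlet-draw estimations.

    With ``fractions`` supplied (the pre-computed-fractions workflow) the
    estimate is fully deterministic and iterations collapse to a single
    :func:`estimate_once` call. Otherwise ``cfg.iterations`` replicate
    estimations are run, each on a fresh Dirichlet draw from a substream
    keyed by (seed, iteration); entries are aggregated by the NaN-skipping
    median, so an entry is NaN only if excluded in every replicate.
    """
    cfg = cfg or EstimationConfig()
    if fractions is not None:
        if table is not None and fractions.fractions.shape != table.counts.shape:
            raise ValueError(
                f"fraction matrix shape {fractions.fractions.shape} does not "
                f"match table shape {table.counts.shape}"
            )
        return estimate_once(fractions, cfg)
    if table is None:
        raise ValueError("either a count table or a fraction matrix is required")
    if seed is None:
        seed = cfg.seed
    indices = range(cfg.iterations)
    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            results = list(
                pool.map(lambda k: _iteration_result(table, cfg, seed, k), indices)
            )
    else:
        results = [_iteration_result(table, cfg, seed, k) for k in indices]
    corr_stack = np.stack([r.correlation for r in results])
    cov_stack = np.stack([r.covariance for r in results])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        corr = np.nanmedian(corr_stack, axis=0)
        cov = np.nanmedian(cov_stack, axis=0)
    # a taxon is reported excluded only if every replicate excluded it
    always_excluded = frozenset.intersection(
        *[r.excluded_otus for r in results]
    )
    return CorrelationResult(table.otu_ids, corr, cov, always_excluded)
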
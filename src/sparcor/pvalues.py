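"""Unbiased empirical P-values from bootstrap correlation matrices.

The naive empirical P-value b/m (b of m bootstrap statistics at least as
extreme as observed) understates significance badly when b = 0 and, more
subtly, ignores that the resampling null space is finite: a count row has
only mt = n!/prod(r_k!) distinct orderings, and a resample can recall the
observed arrangement itself. The estimator used here integrates the
binomial sampling model over that finite pool:

    p  =  (1/mt) * sum_{j=1..mt} P[X <= b],   X ~ Binomial(m, j/mt),

which is strictly positive whenever the pool has more than one element,
and converges to the familiar (b + 1)/(m + 1) as mt -> infinity. For a
pair of taxa the pool size is the product of the two rows' ordering
counts, since the bootstrap perturbs both rows independently.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

from .core import CorrelationResult
from .table_io import OtuTable

__all__ = [
    "count_extreme",
    "count_distinct_orderings",
    "unbiased_pvalue",
    "pvalue_matrix",
]

#: above this pool size the exact sum is replaced by its O(mt^-2) approximation
EXACT_MT_CUTOFF = 10_000

#: log pool sizes beyond this are treated as infinite (exp would overflow)
_LOG_MT_OVERFLOW = 700.0


def count_extreme(
    observed: np.ndarray, bootstrap_corrs: Sequence[np.ndarray]
) -> np.ndarray:
    """b_ij = number of bootstrap replicates with |rho| >= |observed rho|.

    Two-sided by magnitude. Entries where the observed correlation is NaN
    (excluded taxa) are returned as -1 and propagate to NaN P-values.
    """
    observed = np.asarray(observed, dtype=float)
    if len(bootstrap_corrs) < 1:
        raise ValueError("at least one bootstrap correlation matrix is required")
    b = np.zeros(observed.shape, dtype=int)
    obs_mag = np.abs(observed)
    for k, mat in enumerate(bootstrap_corrs):
        mat = np.asarray(mat, dtype=float)
        if mat.shape != observed.shape:
            raise ValueError(
                f"bootstrap matrix {k} has shape {mat.shape}, "
                f"observed has {observed.shape}"
            )
        with np.errstate(invalid="ignore"):
            b += (np.abs(mat) >= obs_mag).astype(int)
    b[np.isnan(observed)] = -1
    return b


def count_distinct_orderings(row: np.ndarray) -> float:
    """Natural log of the number of distinct orderings of a count row.

    log(n! / prod_k r_k!) over the multiplicities r_k of tied values,
    computed in log space via log-gamma. Zero iff the row is constant.
    Requires integer values: the multiset-permutation count is only
    meaningful for exactly tied counts. For real-valued abundances use the
    mt -> infinity limit (b+1)/(m+1) instead.
    """
    row = np.asarray(row)
    if not np.all(row == np.floor(row)):
        raise ValueError(
            "distinct-ordering counts require integer counts; for real-valued "
            "abundances fall back to the (b+1)/(m+1) limit form"
        )
    n = row.size
    _, multiplicities = np.unique(row, return_counts=True)
    log_mt = float(gammaln(n + 1) - gammaln(multiplicities + 1).sum())
    return max(log_mt, 0.0)


def _pvalue_exact(b: int, m: int, mt: int) -> float:
    j = np.arange(1, mt + 1, dtype=float)
    return float(np.mean(binom.cdf(b, m, j / mt)))


def unbiased_pvalue(b: int, m: int, mt: float) -> float:
    """Repetition-aware empirical P-value for b of m exceedances, pool size mt.

    Exact summation up to ``EXACT_MT_CUTOFF``; beyond that the sum is a
    right-endpoint Riemann approximation of integral_0^1 BinomCDF(b; m, q) dq
    = (b+1)/(m+1), corrected by the Euler-Maclaurin endpoint term
    (g(0) - g(1))/(2 mt). The result is in (0, 1]: equal to 1 when b = m,
    and strictly positive for every pool with mt >= 2 (for mt = 1 the only
    resample is the original data, which forces b = m in any consistent
    input).
    """
    if not 0 <= b <= m:
        raise ValueError(f"need 0 <= b <= m, got b={b}, m={m}")
    if mt < 1:
        raise ValueError(f"pool size mt must be >= 1, got {mt}")
    if b == m:
        return 1.0
    if math.isinf(mt) or mt > EXACT_MT_CUTOFF:
        limit = (b + 1) / (m + 1)
        if math.isinf(mt):
            return limit
        # g(0) = CDF at q=0 is 1; g(1) = CDF at q=1 is 0 since b < m
        p = limit - 0.5 / mt
        return min(max(p, limit / 2), 1.0)
    return min(_pvalue_exact(b, m, int(round(mt))), 1.0)


def pvalue_matrix(
    observed: CorrelationResult,
    bootstrap_corrs: Sequence[np.ndarray],
    table: OtuTable,
    two_sided: bool = True,
) -> np.ndarray:
    """Symmetric matrix of unbiased empirical P-values for every taxon pair.

    The pool size for pair (i, j) is exp(log_mt_i + log_mt_j), the product
    of the two rows' distinct-ordering counts (capped at infinity when the
    log overflows, where the (b+1)/(m+1) limit applies). The diagonal is
    reported as 1; excluded taxa propagate NaN.
    """
    if len(bootstrap_corrs) < 1:
        raise ValueError("at least one bootstrap correlation matrix is required")
    corr = observed.correlation
    d = corr.shape[0]
    if table.n_otus != d:
        raise ValueError(
            f"table has {table.n_otus} OTUs but correlation matrix is {d}x{d}"
        )
    stack = np.stack([np.asarray(mat, dtype=float) for mat in bootstrap_corrs])
    if stack.shape[1:] != corr.shape:
        raise ValueError(
            f"bootstrap matrices have shape {stack.shape[1:]}, "
            f"observed has {corr.shape}"
        )
    # a bootstrap replicate can itself exclude a taxon (NaN); such entries
    # are dropped from both the exceedance count and the replicate count
    valid = np.isfinite(stack)
    m_eff = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        if two_sided:
            exceed = np.abs(stack) >= np.abs(corr)[None, :, :]
        else:
            exceed = stack >= corr[None, :, :]
    b = np.where(valid, exceed, False).sum(axis=0)
    log_mt = np.array([count_distinct_orderings(row) for row in table.counts])
    p = np.ones((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            if np.isnan(corr[i, j]) or m_eff[i, j] == 0:
                p[i, j] = p[j, i] = np.nan
                continue
            log_pool = log_mt[i] + log_mt[j]
            mt = math.inf if log_pool > _LOG_MT_OVERFLOW else math.exp(log_pool)
            # a pool below 2 means both rows are constant: only the original
            # arrangement exists, so round up and let b = m give p = 1
            mt = max(mt, 1.0)
            p[i, j] = p[j, i] = unbiased_pvalue(
                int(b[i, j]), int(m_eff[i, j]), mt
            )
    nan_rows = np.isnan(corr).all(axis=1)
    p[nan_rows, :] = np.nan
    p[:, nan_rows] = np.nan
    return p
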
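"""Compositional fractions and the log-ratio variation matrix.

Counts are converted to relative abundances through a Dirichlet model:
each sample column with counts ``c`` parameterizes Dirichlet(c + pseudocount),
from which a fraction vector is either drawn (stochastic replicate runs) or
taken at its posterior mean (deterministic mode, enabling exact cross-run
comparison). The pseudocount guarantees strictly positive fractions, so log
ratios are always defined.

The variation matrix collects t_ij = Var_samples[log(f_i / f_j)], the
scale-invariant dispersion statistic on which basis-correlation estimation
operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .table_io import OtuTable, _read_tsv, ID_LABEL, _FLOAT_FMT

__all__ = [
    "FractionMatrix",
    "draw_fractions",
    "mean_fractions",
    "variation_matrix",
    "read_fractions",
    "write_fractions",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class FractionMatrix:
    """Strictly positive relative abundances; every sample column sums to 1."""

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    fractions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        if fr.ndim != 2:
            raise ValueError("fractions must be a 2-D matrix")
        if fr.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("fraction matrix shape does not match id lists")
        if np.any(fr <= 0):
            raise ValueError("fractions must be strictly positive")
        colsums = fr.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-12):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"sample column {self.sample_ids[j]!r} sums to {colsums[j]!r}, not 1"
            )

    @property
    def n_otus(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_samples(self) -> int:
        return self.fractions.shape[1]


def draw_fractions(
    table: OtuTable, pseudocount: float = 1.0, rng: np.random.Generator | None = None
) -> FractionMatrix:
    """One Dirichlet posterior draw of fractions per sample column.

    Column j is a single draw from Dirichlet(c_j + pseudocount) where c_j is
    the sample's count vector. Replicate draws are what make repeat runs of
    the estimator "similar but non-identical"; fixing ``rng`` fixes the draw.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if rng is None:
        rng = np.random.default_rng()
    alpha = table.counts.astype(float) + pseudocount
    # one Dirichlet draw per column; normalized gamma draws keep the
    # column-major layout simple
    gammas = rng.standard_gamma(alpha)
    # guard against underflow to exactly 0 at tiny alpha
    tiny = np.finfo(float).tiny
    gammas = np.maximum(gammas, tiny)
    fr = gammas / gammas.sum(axis=0, keepdims=True)
    return FractionMatrix(table.otu_ids, table.sample_ids, fr)


def mean_fractions(table: OtuTable, pseudocount: float = 1.0) -> FractionMatrix:
    """Deterministic Dirichlet posterior mean: (c + pseudocount) / column total."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    alpha = table.counts.astype(float) + pseudocount
    fr = alpha / alpha.sum(axis=0, keepdims=True)
    return FractionMatrix(table.otu_ids, table.sample_ids, fr)


def variation_matrix(fr: FractionMatrix, ddof: int = 1) -> np.ndarray:
    """Log-ratio variance matrix t_ij = Var[log(f_i) - log(f_j)] across samples.

    Uses the identity Var(a-b) = Var(a) + Var(b) - 2 Cov(a,b) on the log
    fractions, so the cost is one d x d covariance rather than d^2 passes.
    ``ddof=1`` (unbiased, n-1 denominator) is the package convention; ``ddof=0``
    is exposed because the choice is not universal across implementations.

    Natural logarithm throughout. Result is symmetric, zero-diagonal,
    non-negative, and invariant to rescaling any sample column.
    """
    if fr.n_samples < 2:
        raise ValueError("need at least 2 samples to compute variances")
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    logf = np.log(fr.fractions)
    cov = np.cov(logf, ddof=ddof)
    cov = np.atleast_2d(cov)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    # exact symmetry and zero diagonal; clip negatives from rounding
    t = 0.5 * (t + t.T)
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def write_fractions(fr: FractionMatrix, path: PathLike) -> None:
    """Write a fraction matrix in the OTU-table TSV dialect (real cells)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ID_LABEL + "\t" + "\t".join(fr.sample_ids) + "\n")
        for otu_id, row in zip(fr.otu_ids, fr.fractions):
            fh.write(otu_id + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_fractions(path: PathLike) -> FractionMatrix:
    """Read a pre-computed fraction matrix (columns renormalized to sum to 1)."""
    df = _read_tsv(path)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: fractions must be finite and strictly positive")
    values = values / values.sum(axis=0, keepdims=True)
    return FractionMatrix(
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
        values,
    )
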
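"""Reading, writing and pre-filtering of OTU tables and square result matrices.

File dialect: tab-separated, UTF-8, no quoting. OTU tables have one header
line whose first cell is an identifier label (conventionally ``#OTU ID``),
followed by sample identifiers; each subsequent line is one OTU with its
identifier and per-sample counts. Square matrices (correlation, covariance,
P-values) use the same layout with OTU ids on both axes; excluded entries
are serialized as the token ``nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SquareMatrixFile",
    "read_otu_table",
    "write_otu_table",
    "read_square_matrix",
    "write_square_matrix",
    "filter_otus",
]

PathLike = Union[str, Path]

#: identifier label written in the first header cell of emitted files
ID_LABEL = "#OTU ID"

# full printed precision: 17 significant digits round-trips any float64
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class OtuTable:
    """A taxa-by-samples table of non-negative counts.

    ``counts`` has shape ``(len(otu_ids), len(sample_ids))``. Counts are
    integers in strict mode; real-valued abundances (as emitted by some
    denoising pipelines) are tolerated when constructed with
    ``strict=False`` at read time, but are rejected later by the
    permutation-counting step of the P-value workflow.
    """

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        d, n = counts.shape
        if len(self.otu_ids) != d:
            raise ValueError(f"{len(self.otu_ids)} OTU ids for {d} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if d < 2 or n < 2:
            raise ValueError(
                f"need at least 2 OTUs and 2 samples, got {d} OTUs x {n} samples"
            )
        if len(set(self.otu_ids)) != d:
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def is_integer(self) -> bool:
        return bool(np.issubdtype(self.counts.dtype, np.integer))


@dataclass(frozen=True)
class SquareMatrixFile:
    """A labeled square matrix as stored on disk (correlations, P-values...)."""

    row_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"matrix is not square: shape {values.shape}")
        if len(self.row_ids) != values.shape[0]:
            raise ValueError("row_ids length does not match matrix dimension")


def _read_tsv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    # validate field counts up front: pandas silently reshapes ragged input
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        n_fields = header.count("\t") + 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if line.rstrip("\n").count("\t") + 1 != n_fields:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"(expected {n_fields} tab-separated fields)"
                )
    try:
        df = pd.read_csv(
            path, sep="\t", header=0, index_col=0, dtype=str,
            quoting=3, encoding="utf-8", skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV in {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows or columns")
    return df


def read_otu_table(path: PathLike, strict: bool = True) -> OtuTable:
    """Read a BIOM-TSV OTU table (rows = OTUs, columns = samples).

    Parameters
    ----------
    path
        Tab-separated file with a header line; the first header cell is an
        identifier label and is ignored.
    strict
        When True (default) every cell must parse as a non-negative
        integer. When False, real-valued cells are accepted.
    """
    df = _read_tsv(path)
    otu_ids = [str(i) for i in df.index]
    if len(set(otu_ids)) != len(otu_ids):
        dup = next(i for i in otu_ids if otu_ids.count(i) > 1)
        raise ValueError(f"{path}: duplicate OTU id {dup!r}")
    sample_ids = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative count at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    if strict:
        if not np.all(values == np.floor(values)):
            i, j = np.argwhere(values != np.floor(values))[0]
            raise ValueError(
                f"{path}: non-integer count {values[i, j]!r} at OTU "
                f"{otu_ids[i]!r}, sample {sample_ids[j]!r} "
                "(pass strict=False to accept real-valued abundances)"
            )
        values = values.astype(np.int64)
    return OtuTable(tuple(otu_ids), tuple(sample_ids), values)


def write_otu_table(table: OtuTable, path: PathLike) -> None:
    """Write an OTU table in the same dialect ``read_otu_table`` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ID_LABEL + "\t" + "\t".join(table.sample_ids) + "\n")
        int_mode = table.is_integer
        for otu_id, row in zip(table.otu_ids, table.counts):
            if int_mode:
                cells = [str(int(v)) for v in row]
            else:
                cells = [_FLOAT_FMT % v for v in row]
            fh.write(otu_id + "\t" + "\t".join(cells) + "\n")


def write_square_matrix(
    ids: Sequence[str], values: np.ndarray, path: PathLike
) -> None:
    """Serialize a labeled square matrix; NaN entries become the token ``nan``."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix is not square: shape {values.shape}")
    if len(ids) != values.shape[0]:
        raise ValueError("ids length does not match matrix dimension")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ID_LABEL + "\t" + "\t".join(ids) + "\n")
        for row_id, row in zip(ids, values):
            cells = ["nan" if math.isnan(v) else _FLOAT_FMT % v for v in row]
            fh.write(row_id + "\t" + "\t".join(cells) + "\n")


def read_square_matrix(path: PathLike) -> SquareMatrixFile:
    """Read a labeled square matrix written by :func:`write_square_matrix`."""
    df = _read_tsv(path)
    row_ids = tuple(str(i) for i in df.index)
    col_ids = tuple(str(c) for c in df.columns)
    if row_ids != col_ids:
        raise ValueError(f"{path}: row ids do not match column ids in header")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return SquareMatrixFile(row_ids, values)


def filter_otus(
    table: OtuTable, min_total_count: int = 0, min_prevalence: int = 0
) -> OtuTable:
    """Drop poorly represented OTUs before correlation estimation.

    Keeps exactly the OTUs with row sum >= ``min_total_count`` AND at least
    ``min_prevalence`` samples with a non-zero count (both thresholds
    inclusive). Sample set and surviving row order are unchanged.
    """
    if min_total_count < 0 or min_prevalence < 0:
        raise ValueError("filter thresholds must be non-negative")
    totals = table.counts.sum(axis=1)
    prevalence = (table.counts > 0).sum(axis=1)
    keep = (totals >= min_total_count) & (prevalence >= min_prevalence)
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError(
            f"filtering left {n_keep} OTU(s); at least 2 are required -- "
            "relax min_total_count/min_prevalence"
        )
    return OtuTable(
        tuple(i for i, k in zip(table.otu_ids, keep) if k),
        table.sample_ids,
        table.counts[keep],
    )
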
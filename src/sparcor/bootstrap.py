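"""Bootstrap null tables for significance testing.

Each OTU row is resampled independently, with replacement, from its own
observed counts. This destroys every inter-taxon association while leaving
each taxon's marginal count distribution intact, which is exactly the null
the empirical P-values are computed against. Column totals are NOT
preserved -- this is a row-marginal null, not a rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Union

import numpy as np

from .table_io import OtuTable, write_otu_table

__all__ = ["BootstrapSet", "bootstrap_table", "generate_bootstraps"]

PathLike = Union[str, Path]
ResampleMode = Literal["with_replacement", "permute"]


@dataclass(frozen=True)
class BootstrapSet:
    """A reproducible collection of bootstrap tables derived from one source."""

    source: OtuTable
    count: int
    seed: int
    resample_mode: ResampleMode = "with_replacement"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("bootstrap count must be >= 1")
        if self.resample_mode not in ("with_replacement", "permute"):
            raise ValueError(f"unknown resample mode {self.resample_mode!r}")

    def table(self, k: int) -> OtuTable:
        """The k-th bootstrap table, a pure function of (seed, k)."""
        if not 0 <= k < self.count:
            raise IndexError(f"bootstrap index {k} out of range [0, {self.count})")
        return _keyed_bootstrap(self.source, self.seed, k, self.resample_mode)


def _row_rng(seed: int, table_index: int, row_index: int) -> np.random.Generator:
    # per-(row, table) substream so generation parallelizes reproducibly
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(table_index, row_index))
    )


def _keyed_bootstrap(
    table: OtuTable, seed: int, table_index: int, mode: ResampleMode
) -> OtuTable:
    n = table.n_samples
    out = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        rng = _row_rng(seed, table_index, i)
        if mode == "with_replacement":
            out[i] = row[rng.integers(0, n, size=n)]
        else:
            out[i] = row[rng.permutation(n)]
    return OtuTable(table.otu_ids, table.sample_ids, out)


def bootstrap_table(
    table: OtuTable,
    rng: np.random.Generator,
    resample_mode: ResampleMode = "with_replacement",
) -> OtuTable:
    """One bootstrap table: every row resampled from its own counts.

    Each emitted cell value occurs somewhere in the corresponding source
    row, and a constant row reproduces itself exactly.
    """
    n = table.n_samples
    out = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        if resample_mode == "with_replacement":
            out[i] = row[rng.integers(0, n, size=n)]
        elif resample_mode == "permute":
            out[i] = row[rng.permutation(n)]
        else:
            raise ValueError(f"unknown resample mode {resample_mode!r}")
    return OtuTable(table.otu_ids, table.sample_ids, out)


def generate_bootstraps(bs: BootstrapSet, out_prefix: PathLike) -> list[Path]:
    """Write ``bs.count`` bootstrap tables as <prefix>_<k>.tsv.

    The k-th file is a deterministic function of (seed, k): regenerating
    with the same seed yields byte-identical files.
    """
    prefix = Path(out_prefix)
    if prefix.parent != Path("") and not prefix.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {prefix.parent}")
    paths = []
    for k in range(bs.count):
        path = prefix.parent / f"{prefix.name}_{k}.tsv"
        try:
            write_otu_table(bs.table(k), path)
        except OSError as exc:
            raise OSError(f"failed writing bootstrap table {path}: {exc}") from exc
        paths.append(path)
    return paths
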
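"""OTU count tables: reading, validation, filtering, rarefaction and partitioning.

The entry point of the analysis chain.  Tables are samples x OTUs matrices of
integer read counts; preprocessing follows the conventions of amplicon
community ecology: low-count reads are zeroed per sample to guard against
sequencing/PCR errors, samples are rarefied to a common depth by subsampling
reads without replacement, and paired tables (e.g. leaf-surface vs leaf-interior
communities of the same hosts) are partitioned into compartment-specific and
shared OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "PartitionSummary",
    "read_otu_table",
    "write_otu_table",
    "filter_low_count",
    "rarefy",
    "partition_otus",
    "richness",
]


class OtuTableFormatError(ValueError):
    """Raised when an on-disk table violates the expected format."""


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with identifiers.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    otu_ids : list of str
        Unique OTU identifiers (columns).
    counts : ndarray of int, shape (n_samples, n_otus)
        Nonnegative read counts.
    taxonomy : dict, optional
        Maps otu_id to a ranked taxonomy string (``k__...;p__...;...``).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} id(s): {sorted(set(dupes))}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def present_otus(self) -> set[str]:
        """OTU ids with a nonzero count in at least one sample."""
        mask = self.counts.sum(axis=0) > 0
        return {o for o, m in zip(self.otu_ids, mask) if m}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        otu_ids = [o for o, k in zip(self.otu_ids, keep) if k]
        tax = (
            {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
            if self.taxonomy
            else None
        )
        return OtuTable(list(self.sample_ids), otu_ids, self.counts[:, keep], tax)


@dataclass(frozen=True)
class PartitionSummary:
    """Counts and percentages of compartment-specific vs shared OTUs."""

    n_epiphyte_specific: int
    n_endophyte_specific: int
    n_shared: int
    n_total: int
    pct_epiphyte_specific: float
    pct_endophyte_specific: float
    pct_shared: float


def read_otu_table(
    path,
    taxonomy_path=None,
    orientation: str = "samples",
) -> OtuTable:
    """Read a tab-separated count table.

    The first column holds row identifiers, the header row column identifiers
    (a leading ``#OTU ID`` marker is accepted).  ``orientation`` says what the
    rows are: ``"samples"`` (default) or ``"otus"``; the returned table is
    always samples x OTUs.
    """
    if orientation not in ("samples", "otus"):
        raise ValueError("orientation must be 'samples' or 'otus'")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise OtuTableFormatError(f"duplicate column id(s) in {path}: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    df.index = df.index.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise OtuTableFormatError(f"non-numeric cell in {path}: {exc}") from exc
    bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise OtuTableFormatError(
            f"invalid cell at row {df.index[i]!r}, column {df.columns[j]!r}: "
            f"{df.iat[i, j]!r} (expected a nonnegative integer)"
        )
    counts = values.astype(np.int64)
    if orientation == "otus":
        counts = counts.T
        sample_ids, otu_ids = list(df.columns), list(df.index)
    else:
        sample_ids, otu_ids = list(df.index), list(df.columns)
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(
            taxonomy_path, sep="\t", header=None, index_col=0, dtype=str
        )
        taxonomy = dict(tax.iloc[:, 0])
    try:
        return OtuTable(sample_ids, otu_ids, counts, taxonomy)
    except ValueError as exc:
        raise OtuTableFormatError(str(exc)) from exc


def write_otu_table(table: OtuTable, path, orientation: str = "samples") -> None:
    """Write a table as labeled TSV; inverse of :func:`read_otu_table`."""
    df = table.to_dataframe()
    if orientation == "otus":
        df = df.T
    df.to_csv(path, sep="\t")


def filter_low_count(table: OtuTable, min_reads: int = 10) -> OtuTable:
    """Zero counts below ``min_reads`` per sample; drop OTUs left all-zero.

    Guards against sequencing and PCR errors: a cell with fewer than
    ``min_reads`` reads in a given sample is treated as absence in that sample.
    OTUs that retain at least one cell at or above the threshold are kept.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    counts = table.counts.copy()
    counts[counts < min_reads] = 0
    return OtuTable(
        list(table.sample_ids), list(table.otu_ids), counts, table.taxonomy
    ).drop_empty_otus()


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample's reads to ``depth`` without replacement.

    Each sample's rarefied counts are a multivariate-hypergeometric draw from
    its observed reads, so column sums equal ``depth`` exactly and no count
    exceeds its original value.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    short = np.flatnonzero(totals < depth)
    if short.size:
        raise ValueError(
            f"sample {table.sample_ids[short[0]]!r} has only "
            f"{totals[short[0]]} reads, fewer than depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return OtuTable(list(table.sample_ids), list(table.otu_ids), out, table.taxonomy)


def partition_otus(epi: OtuTable, endo: OtuTable) -> PartitionSummary:
    """Partition OTU ids of paired tables into specific and shared sets.

    An OTU counts as present in a compartment if it has a nonzero count in at
    least one sample of that table.  Percentages are of the union, rounded to
    two decimals.
    """
    epi_set, endo_set = epi.present_otus(), endo.present_otus()
    total = len(epi_set | endo_set)
    if total == 0:
        raise ValueError("both tables are empty: no OTUs to partition")
    n_shared = len(epi_set & endo_set)
    n_epi = len(epi_set - endo_set)
    n_endo = len(endo_set - epi_set)
    pct = lambda n: round(n / total * 100, 2)
    return PartitionSummary(
        n_epiphyte_specific=n_epi,
        n_endophyte_specific=n_endo,
        n_shared=n_shared,
        n_total=total,
        pct_epiphyte_specific=pct(n_epi),
        pct_endophyte_specific=pct(n_endo),
        pct_shared=pct(n_shared),
    )


def richness(table: OtuTable) -> dict[str, int]:
    """Observed OTU richness per sample (count of OTUs with reads > 0)."""
    counts = (table.counts > 0).sum(axis=1)
    return {s: int(c) for s, c in zip(table.sample_ids, counts)}
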
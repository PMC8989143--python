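"""Sample-by-taxon count tables and the abundance/prevalence filters.

Conventions: taxa are table rows keyed by the full lineage string down to
the analysis rank; samples are columns.  Relative abundances are always
derived per sample from the current counts.  "Observed" thresholds are
strict (a taxon at exactly the prevalence cutoff is not observed) and the
sample-read QC is strict-less (a sample with exactly the minimum read
count is retained), matching the usual reporting of these filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import RANK_NAMES, RANK_PREFIXES, SampleMetadata
from .taxonomy import TaxonAssignment


class TaxonTable:
    """Immutable-by-convention counts matrix: taxa rows x sample columns."""

    def __init__(self, counts: pd.DataFrame, rank: str | None = None):
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("duplicate taxon or sample ids")
        self.counts = counts.astype(int)
        self.rank = rank

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def relabund(self) -> pd.DataFrame:
        """Per-sample relative abundances; samples with zero reads get 0."""
        totals = self.counts.sum(axis=0)
        safe = totals.replace(0, 1)
        return self.counts / safe

    def subset_taxa(self, taxa) -> "TaxonTable":
        return TaxonTable(self.counts.loc[list(taxa)], rank=self.rank)

    def subset_samples(self, samples) -> "TaxonTable":
        return TaxonTable(self.counts[list(samples)], rank=self.rank)

    def drop_empty_taxa(self) -> "TaxonTable":
        keep = self.counts.sum(axis=1) > 0
        return TaxonTable(self.counts.loc[keep], rank=self.rank)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonTable) and self.counts.equals(other.counts)


def build_table(
    assignments: list[TaxonAssignment],
    metadata: list[SampleMetadata],
    rank: str = "s",
) -> TaxonTable:
    """Collapse read assignments to ``rank`` and tabulate per sample.

    Reads classified below ``rank`` are aggregated upward; reads not
    classified at ``rank`` fall into an ``<rank>__unclassified`` taxon
    nested under their deepest classified parent.  Every assignment's
    sample must appear in ``metadata``.
    """
    if rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {rank!r}")
    sample_ids = [m.sample_id for m in metadata]
    known = set(sample_ids)
    for a in assignments:
        if a.sample_id not in known:
            raise ValueError(f"assignment {a.read_id!r}: unknown sample {a.sample_id!r}")
    if not assignments:
        return TaxonTable(
            pd.DataFrame(0, index=pd.Index([], dtype=str), columns=sample_ids), rank=rank
        )
    df = pd.DataFrame(
        {
            "taxon": [a.lineage.table_key(rank) for a in assignments],
            "sample": [a.sample_id for a in assignments],
        }
    )
    counts = pd.crosstab(df["taxon"], df["sample"]).reindex(
        columns=sample_ids, fill_value=0
    )
    counts.index.name = None
    counts.columns.name = None
    return TaxonTable(counts.sort_index(), rank=rank)


def per_rank_assigned_fractions(assignments: list[TaxonAssignment]) -> dict[str, float]:
    """Fraction of assigned reads classified at each rank (domain..species).

    With nested lineages these fractions are non-increasing from domain to
    species, the usual rank-wise assignment bookkeeping.
    """
    n = len(assignments)
    out = {}
    for prefix in RANK_PREFIXES:
        k = sum(1 for a in assignments if a.lineage.is_classified_at(prefix))
        out[RANK_NAMES[prefix]] = k / n if n else 0.0
    return out


@dataclass(frozen=True)
class TableFilterConfig:
    min_relabund: float = 0.001  # strict >: "observed" above 0.1%
    min_samples: int = 1
    min_assigned_reads: int = 5000
    rank: str = "s"

    def __post_init__(self) -> None:
        if not (0 <= self.min_relabund < 1):
            raise ValueError("min_relabund must be in [0, 1)")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class FilterResult:
    """A filtered table plus bookkeeping of what was dropped."""

    table: TaxonTable
    dropped_taxa: list[str]
    #: per-sample read counts removed with the dropped taxa ("other" ledger)
    dropped_counts: pd.Series


def sample_qc(table: TaxonTable, min_assigned_reads: int = 5000) -> tuple[TaxonTable, list[str]]:
    """Remove samples with fewer than ``min_assigned_reads`` total reads
    (strict less-than: a sample at exactly the threshold is retained)."""
    totals = table.sample_totals()
    excluded = [s for s in table.sample_ids if totals[s] < min_assigned_reads]
    kept = [s for s in table.sample_ids if totals[s] >= min_assigned_reads]
    return table.subset_samples(kept), excluded


def prevalence_filter(
    table: TaxonTable, min_relabund: float = 0.001, min_samples: int = 1
) -> FilterResult:
    """Keep taxa "observed": relative abundance strictly above
    ``min_relabund`` in at least ``min_samples`` samples."""
    ra = table.relabund
    observed = (ra > min_relabund).sum(axis=1) >= min_samples
    kept = [t for t, ok in observed.items() if ok]
    dropped = [t for t, ok in observed.items() if not ok]
    sub = table.subset_taxa(kept)
    return FilterResult(sub, dropped, table.counts.loc[dropped].sum(axis=0))


def mean_abundance_filter(table: TaxonTable, min_mean: float = 0.01) -> FilterResult:
    """Keep taxa whose arithmetic mean relative abundance across samples is
    strictly above ``min_mean``."""
    means = table.relabund.mean(axis=1)
    kept = [t for t in table.taxa if means[t] > min_mean]
    dropped = [t for t in table.taxa if means[t] <= min_mean]
    sub = table.subset_taxa(kept)
    return FilterResult(sub, dropped, table.counts.loc[dropped].sum(axis=0))
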
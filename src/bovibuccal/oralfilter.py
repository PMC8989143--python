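"""Two-rule oral-contaminant classifier for buccal swab samples.

Buccal swabs approximate rumen contents only after removing taxa of oral
origin.  Given paired buccal and rumen taxon tables, a taxon is flagged
as putative oral bacteria when either

1. it is detected only in buccal samples (never in any rumen sample), or
2. it is shared but its maximum relative abundance across buccal samples
   is more than ``ratio_threshold`` times (default 5x, strict) its
   maximum across rumen samples.

"Detected" means relative abundance strictly above
``presence_min_relabund`` (default 0: any nonzero count) within the
taxon universe the tables were built on, normally the post-prevalence-
filter observed set.  Rule 1 takes precedence so no taxon is counted
twice.  The remaining taxa (rumen-only and unflagged shared) form the
retained universe.

Removing the putative oral taxa from a buccal sample leaves a fraction of
its reads; samples losing more than a configurable fraction (default 0.5)
can be flagged as too contaminated to stand in for rumen contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import TaxonTable


@dataclass(frozen=True)
class OralFilterConfig:
    ratio_threshold: float = 5.0
    presence_min_relabund: float = 0.0
    contamination_flag_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")
        if not 0 <= self.presence_min_relabund < 1:
            raise ValueError("presence_min_relabund must be in [0, 1)")
        if not 0 <= self.contamination_flag_threshold <= 1:
            raise ValueError("contamination_flag_threshold must be in [0, 1]")


@dataclass
class OralFilterReport:
    buccal_only_taxa: set[str]
    flagged_shared_taxa: set[str]
    rumen_only_taxa: set[str]
    retained_taxa: set[str]
    per_sample_removed_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def putative_oral_taxa(self) -> set[str]:
        return self.buccal_only_taxa | self.flagged_shared_taxa

    def to_dict(self) -> dict:
        return {
            "buccal_only_taxa": sorted(self.buccal_only_taxa),
            "flagged_shared_taxa": sorted(self.flagged_shared_taxa),
            "rumen_only_taxa": sorted(self.rumen_only_taxa),
            "retained_taxa": sorted(self.retained_taxa),
            "n_putative_oral": len(self.putative_oral_taxa),
            "n_retained": len(self.retained_taxa | self.rumen_only_taxa),
            "per_sample_removed_fraction": dict(
                sorted(self.per_sample_removed_fraction.items())
            ),
        }


def classify_oral_taxa(
    buccal: TaxonTable, rumen: TaxonTable, cfg: OralFilterConfig = OralFilterConfig()
) -> OralFilterReport:
    """Partition the union taxon universe into buccal-only, flagged-shared,
    rumen-only and retained sets per the two rules above."""
    if rumen.shape[1] == 0 or int(rumen.counts.values.sum()) == 0:
        raise ValueError("rumen reference table is empty")
    universe = sorted(set(buccal.taxa) | set(rumen.taxa))
    bmax = buccal.relabund.max(axis=1).reindex(universe, fill_value=0.0)
    rmax = rumen.relabund.max(axis=1).reindex(universe, fill_value=0.0)
    thr = cfg.presence_min_relabund
    in_b = bmax > thr
    in_r = rmax > thr

    buccal_only = set(bmax.index[in_b & ~in_r])
    rumen_only = set(bmax.index[~in_b & in_r])
    shared = bmax.index[in_b & in_r]
    flagged = set(shared[(bmax[shared] > cfg.ratio_threshold * rmax[shared])])
    retained = set(universe) - buccal_only - rumen_only - flagged
    return OralFilterReport(buccal_only, flagged, rumen_only, retained)


def apply_oral_filter(
    table: TaxonTable, report: OralFilterReport
) -> tuple[TaxonTable, pd.Series]:
    """Remove the report's putative oral taxa from ``table``.

    Returns the filtered table and the per-sample fraction of reads
    removed (0 for samples with no reads)."""
    oral = report.putative_oral_taxa
    unknown = set(table.taxa) - (oral | report.rumen_only_taxa | report.retained_taxa)
    if unknown:
        raise ValueError(f"taxa not covered by the report: {sorted(unknown)[:5]} ...")
    keep = [t for t in table.taxa if t not in oral]
    filtered = table.subset_taxa(keep)
    totals = table.sample_totals().astype(float)
    removed = totals - filtered.sample_totals()
    frac = (removed / totals.replace(0, np.nan)).fillna(0.0)
    report.per_sample_removed_fraction.update(frac.to_dict())
    return filtered, frac


def flag_contaminated_samples(
    removed_fractions: dict[str, float] | pd.Series, threshold: float = 0.5
) -> list[str]:
    """Samples whose removed-read fraction strictly exceeds ``threshold``."""
    items = (
        removed_fractions.items()
        if hasattr(removed_fractions, "items")
        else removed_fractions
    )
    out = []
    for sid, f in items:
        if not 0 <= f <= 1:
            raise ValueError(f"removed fraction for {sid!r} outside [0, 1]")
        if f > threshold:
            out.append(sid)
    return out


def flag_contaminated_samples_by_distance(
    buccal_filtered: TaxonTable,
    rumen: TaxonTable,
    quantile: float = 0.9,
) -> list[str]:
    """Alternative distance-based flag: buccal samples whose mean
    Bray-Curtis dissimilarity to the rumen samples exceeds the given
    quantile of rumen-to-rumen dissimilarities are flagged.

    Stands in for a visual ordination judgement with an explicit numeric
    criterion.
    """
    from .community import bray_curtis
    from .tables import TaxonTable as TT

    universe = sorted(set(buccal_filtered.taxa) | set(rumen.taxa))
    b = buccal_filtered.counts.reindex(universe, fill_value=0)
    r = rumen.counts.reindex(universe, fill_value=0)
    combined = TT(pd.concat([b, r], axis=1), rank=buccal_filtered.rank)
    d = bray_curtis(combined)
    dm = pd.DataFrame(d.values, index=d.ids, columns=d.ids)
    rum_ids = list(r.columns)
    if len(rum_ids) < 2:
        raise ValueError("need >= 2 rumen samples for the distance criterion")
    rr = dm.loc[rum_ids, rum_ids].to_numpy()
    cutoff = float(np.quantile(rr[np.triu_indices(len(rum_ids), k=1)], quantile))
    out = []
    for sid in b.columns:
        if float(dm.loc[sid, rum_ids].mean()) > cutoff:
            out.append(sid)
    return out
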
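"""Alignment-based taxonomy assignment for long 16S amplicon reads.

Each read is locally aligned against every reference sequence under a
LAST-style integer scheme: +r per match, -q per mismatch, and -(a + b*k)
for a gap of length k (defaults r = q = a = b = 1, a deliberately
mismatch-tolerant scheme suited to ~5% error long reads).  The read is
assigned the lineage of the highest-scoring reference; ties go to the
lexicographically smallest reference id so assignment is deterministic.

At desk scale (tens of references) the exact affine-gap local dynamic
programme is affordable, so no seeding or banding heuristics are used.
The DP itself is Biopython's PairwiseAligner configured to this scheme;
``N`` in a read or reference scores as a mismatch against every base,
including another ``N``.

Taxa supported by exactly one assigned read anywhere in the dataset
("singletons") are conventionally excluded before building count tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import Lineage, SequenceRead


@dataclass(frozen=True)
class ScoringScheme:
    """Integer alignment costs; all are magnitudes (costs are subtracted)."""

    match_score: int = 1
    mismatch_cost: int = 1
    gap_open_cost: int = 1
    gap_extend_cost: int = 1

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if min(self.mismatch_cost, self.gap_open_cost, self.gap_extend_cost) < 0:
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    identity: float  # matches / aligned columns, gap columns included
    aligned_query: str
    aligned_ref: str


@dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    reference_id: str
    lineage: Lineage
    score: int
    percent_identity: float
    sample_id: str = ""


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    mat = substitution_matrices.Array(
        "ACGTN", dims=2, data=np.full((5, 5), -float(scheme.mismatch_cost))
    )
    for b in "ACGT":
        mat[b, b] = float(scheme.match_score)
    aln.substitution_matrix = mat
    # a gap of length k costs a + b*k: the first gap column costs a+b,
    # each further column costs b
    aln.open_gap_score = -float(scheme.gap_open_cost + scheme.gap_extend_cost)
    aln.extend_gap_score = -float(scheme.gap_extend_cost)
    return aln


def local_align(query: str, ref: str, scheme: ScoringScheme = ScoringScheme()) -> LocalAlignment:
    """Optimal affine-gap local alignment of ``query`` against ``ref``.

    Returns one optimal traceback.  If no positive-scoring local alignment
    exists the score is 0 and the alignment is empty.
    """
    if not query or not ref:
        raise ValueError("empty sequence")
    aligner = _aligner(scheme)
    alignments = aligner.align(query.upper(), ref.upper())
    best = alignments[0]
    score = int(best.score)
    if score <= 0:
        return LocalAlignment(0, 0.0, "", "")
    counts = best.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / cols if cols else 0.0
    return LocalAlignment(score, float(identity), str(best[0]), str(best[1]))


def align_score(query: str, ref: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Optimal local alignment score only (no traceback; faster)."""
    if not query or not ref:
        raise ValueError("empty sequence")
    return int(_aligner(scheme).score(query.upper(), ref.upper()))


def assign_read(
    read: SequenceRead,
    references: dict[str, tuple[str, Lineage]],
    scheme: ScoringScheme = ScoringScheme(),
    min_score: int = 0,
) -> TaxonAssignment | None:
    """Assign ``read`` to the reference with the highest local alignment
    score; ties broken by lexicographically smallest reference id.

    Returns None when the best score falls below ``min_score`` (default 0:
    every read is assigned, mirroring a best-hit-only workflow).
    """
    if not references:
        raise ValueError("empty reference set")
    best_id: str | None = None
    best_score = -1
    for rid in sorted(references):
        s = align_score(read.bases, references[rid][0], scheme)
        if s > best_score:
            best_id, best_score = rid, s
    assert best_id is not None
    if best_score < min_score:
        return None
    full = local_align(read.bases, references[best_id][0], scheme)
    return TaxonAssignment(
        read_id=read.read_id,
        reference_id=best_id,
        lineage=references[best_id][1],
        score=full.score,
        percent_identity=full.identity,
        sample_id=read.sample_id,
    )


def assign_reads(
    reads,
    references: dict[str, tuple[str, Lineage]],
    scheme: ScoringScheme = ScoringScheme(),
    min_score: int = 0,
) -> list[TaxonAssignment]:
    out = []
    for read in reads:
        a = assign_read(read, references, scheme, min_score)
        if a is not None:
            out.append(a)
    return out


def remove_singletons(
    assignments: list[TaxonAssignment], scope: str = "dataset"
) -> list[TaxonAssignment]:
    """Drop assignments whose taxon (full lineage identity) is supported by
    exactly one read.

    ``scope`` is "dataset" (taxon counted across all samples, the default)
    or "sample" (counted within each sample separately).
    """
    if scope not in ("dataset", "sample"):
        raise ValueError(f"unknown scope {scope!r}")

    def key(a: TaxonAssignment):
        tax = a.lineage.to_string()
        return tax if scope == "dataset" else (a.sample_id, tax)

    counts = Counter(key(a) for a in assignments)
    return [a for a in assignments if counts[key(a)] > 1]
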
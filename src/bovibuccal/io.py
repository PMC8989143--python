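"""Readers and writers for the external formats shared by every pipeline stage.

Covers FASTQ (Phred+33 only), reference FASTA + taxonomy TSV with
SILVA-style rank-prefixed lineages, sample metadata TSV, and the
sample-by-taxon count tables.  All quality handling is fixed to the
Sanger Phred+33 convention; other encodings are rejected, never guessed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: canonical SILVA rank prefixes, domain to species
RANK_PREFIXES = ("d", "p", "c", "o", "f", "g", "s")
RANK_NAMES = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRead:
    """A single sequencing read with per-base Phred qualities."""

    read_id: str
    bases: str
    quals: list[int]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if not set(self.bases) <= VALID_BASES:
            bad = sorted(set(self.bases) - VALID_BASES)
            raise ValueError(f"read {self.read_id!r}: invalid bases {bad}")
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred quality outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Lineage:
    """A SILVA-style taxonomic lineage: ordered (rank prefix, name) pairs.

    Ranks must appear in canonical order d, p, c, o, f, g, s with gaps
    allowed only as a missing suffix (a lineage classified to family simply
    stops at ``f__``).  The original string is kept in ``raw``.
    """

    ranks: tuple[tuple[str, str], ...]
    raw: str = ""

    @classmethod
    def parse(cls, raw: str) -> "Lineage":
        tokens = [t.strip() for t in raw.strip().split(";") if t.strip()]
        pairs: list[tuple[str, str]] = []
        for tok in tokens:
            if len(tok) < 3 or tok[1:3] != "__" or tok[0] not in RANK_PREFIXES:
                raise FormatError(f"malformed lineage token {tok!r} in {raw!r}")
            pairs.append((tok[0], tok[3:]))
        # drop trailing empty names ("g__;s__" means unclassified below family)
        while pairs and not pairs[-1][1]:
            pairs.pop()
        if any(not name for _, name in pairs):
            raise FormatError(f"internal empty rank name in lineage {raw!r}")
        expected = RANK_PREFIXES[: len(pairs)]
        got = tuple(p for p, _ in pairs)
        if got != expected:
            raise FormatError(
                f"lineage ranks {got} are not a canonical prefix of "
                f"{RANK_PREFIXES}: {raw!r}"
            )
        return cls(ranks=tuple(pairs), raw=raw)

    @property
    def depth(self) -> int:
        return len(self.ranks)

    def name_at(self, rank: str) -> str | None:
        """Taxon name at ``rank`` ('d'..'s'), or None if unclassified there."""
        for prefix, name in self.ranks:
            if prefix == rank:
                return name
        return None

    def is_classified_at(self, rank: str) -> bool:
        return self.name_at(rank) is not None

    def to_string(self, rank: str | None = None) -> str:
        """Canonical string down to ``rank`` (default: full depth).

        Spaces in names are written as underscores so the string survives
        whitespace-delimited round trips.
        """
        upto = RANK_PREFIXES.index(rank) + 1 if rank else len(self.ranks)
        parts = [
            f"{p}__{n.replace(' ', '_')}" for p, n in self.ranks[:upto]
        ]
        return ";".join(parts)

    def table_key(self, rank: str) -> str:
        """Taxon identity used in count tables: the full lineage string down
        to ``rank``.  Reads unclassified at ``rank`` collapse to an
        ``<rank>__unclassified`` taxon nested under their deepest classified
        parent, so identically named leaves under different parents never
        collide."""
        if self.is_classified_at(rank):
            return self.to_string(rank)
        idx = RANK_PREFIXES.index(rank)
        parent = self.to_string() if self.ranks else ""
        missing = [f"{p}__unclassified" for p in RANK_PREFIXES[self.depth : idx + 1]]
        return ";".join(([parent] if parent else []) + missing)


class SampleType(str, Enum):
    BUCCAL = "buccal"
    RUMEN = "rumen"


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    sample_type: SampleType
    animal_id: str


# ---------------------------------------------------------------------------
# FASTQ

def _to_read(rec: SeqRecord, sample_id: str) -> SequenceRead:
    return SequenceRead(
        read_id=rec.id,
        bases=str(rec.seq).upper(),
        quals=list(rec.letter_annotations["phred_quality"]),
        sample_id=sample_id,
    )


def read_fastq(path: str | Path, sample_id: str | None = None) -> Iterator[SequenceRead]:
    """Stream reads from a Phred+33 FASTQ file.

    ``sample_id`` defaults to the file stem.  Malformed records raise
    :class:`FormatError` naming the failing record index.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    parser = SeqIO.parse(str(path), "fastq")
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"{path}: malformed FASTQ record {index}: {exc}") from exc
        yield _to_read(rec, sample_id)
        index += 1


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.quals)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Reference set

def read_reference(
    fasta: str | Path, taxonomy_tsv: str | Path
) -> dict[str, tuple[str, Lineage]]:
    """Load a reference FASTA plus an id<TAB>lineage taxonomy TSV.

    Every FASTA id must have exactly one taxonomy row and vice versa.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{fasta}: duplicate reference id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    lineages: dict[str, Lineage] = {}
    with open(taxonomy_tsv) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (lineno == 1 and row[0] in ("id", "reference_id")):
                continue
            if len(row) < 2:
                raise FormatError(f"{taxonomy_tsv}: line {lineno}: expected 2 columns")
            lineages[row[0]] = Lineage.parse(row[1])

    only_fasta = sorted(set(seqs) - set(lineages))
    only_tax = sorted(set(lineages) - set(seqs))
    if only_fasta or only_tax:
        raise FormatError(
            f"reference mismatch: ids only in FASTA {only_fasta}, "
            f"ids only in taxonomy {only_tax}"
        )
    return {rid: (seqs[rid], lineages[rid]) for rid in seqs}


def write_reference(
    references: dict[str, tuple[str, Lineage]],
    fasta: str | Path,
    taxonomy_tsv: str | Path,
) -> None:
    with open(fasta, "w") as fh:
        for rid in sorted(references):
            fh.write(f">{rid}\n{references[rid][0]}\n")
    with open(taxonomy_tsv, "w") as fh:
        for rid in sorted(references):
            fh.write(f"{rid}\t{references[rid][1].to_string()}\n")


# ---------------------------------------------------------------------------
# Sample metadata

_META_HEADER = ["sample_id", "sample_type", "animal_id"]


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row == _META_HEADER:
                continue
            if len(row) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            sid, stype, animal = row
            if sid in seen:
                raise FormatError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                out.append(SampleMetadata(sid, SampleType(stype), animal))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_sample_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_HEADER) + "\n")
        for m in metadata:
            fh.write(f"{m.sample_id}\t{m.sample_type.value}\t{m.animal_id}\n")


# ---------------------------------------------------------------------------
# Taxon tables (TaxonTable lives in bovibuccal.tables; imported lazily to
# keep the module dependency graph acyclic)

def write_taxon_table(table, path: str | Path, relabund_path: str | Path | None = None):
    """Write counts as TSV (taxa rows, sample columns) plus a parallel
    relative-abundance TSV (default: ``<path>.relabund.tsv``)."""
    path = Path(path)
    if relabund_path is None:
        relabund_path = path.with_suffix(path.suffix + ".relabund.tsv")
    table.counts.to_csv(path, sep="\t", index_label="taxon")
    table.relabund.to_csv(relabund_path, sep="\t", index_label="taxon", float_format="%.10g")


def read_taxon_table(path: str | Path, rank: str | None = None):
    import pandas as pd

    from .tables import TaxonTable

    counts = pd.read_csv(path, sep="\t", index_col="taxon", comment="#")
    counts.index = counts.index.astype(str)
    return TaxonTable(counts.astype(int), rank=rank)
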
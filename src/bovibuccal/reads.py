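"""Read-level processing: QC filtering and in-silico variable-region extraction.

The QC filter reproduces the NanoFilt-style criterion used for long
amplicon reads: keep a read iff its length is within an inclusive window
(default 1,300-1,600 bp) and its mean quality is at or above a Phred
threshold (default 9).  Mean quality is defined on the error-probability
scale, -10*log10(mean_i 10^(-Q_i/10)), which is how NanoFilt averages
qualities; the arithmetic mean of Phred values is biased upward because
the Phred scale is logarithmic.

Region extraction locates degenerate primer sites (IUPAC codes, a bounded
number of substitutions, no indels) on both strands and excises the
amplicon between a forward and a reverse primer, emulating in-silico PCR
on near full-length 16S reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import SequenceRead

# ---------------------------------------------------------------------------
# IUPAC machinery

#: IUPAC nucleotide codes as A/C/G/T bitmasks (A=1, C=2, G=4, T=8)
IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC degenerate codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([IUPAC_BITS[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r}") from exc


#: primers used for full-length (V1-V9) and internal (V3-V4) 16S amplicons
PRIMER_27F = "AGAGTTTGATCCTGGCTCAGA"
PRIMER_1525R = "AAGGAGGTGWTCCARCC"
PRIMER_341F = "CCTACGGGNGGCWGCAG"
PRIMER_805R = "GACTACHVGGGTATCTAATCC"


@dataclass(frozen=True)
class PrimerPattern:
    """A degenerate primer and its matching tolerance (substitutions only)."""

    name: str
    iupac_sequence: str
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        if not self.iupac_sequence:
            raise ValueError("empty primer sequence")
        _encode(self.iupac_sequence)  # validates letters
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class PrimerHit:
    offset: int
    strand: str  # '+' pattern as given, '-' reverse complement of pattern
    mismatches: int


def _scan(text_bits: np.ndarray, pattern: str, max_mm: int, strand: str) -> list[PrimerHit]:
    pat = _encode(pattern)
    k = len(pat)
    if k > len(text_bits):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(text_bits, k)
    mm = ((windows & pat) == 0).sum(axis=1)
    return [
        PrimerHit(int(off), strand, int(m))
        for off, m in enumerate(mm)
        if m <= max_mm
    ]


def find_primer(read_bases: str, primer: PrimerPattern) -> list[PrimerHit]:
    """All matches of ``primer`` in ``read_bases`` on both strands.

    A '+' hit is a window matching the pattern as given; a '-' hit is a
    window matching its reverse complement.  Offsets are always in read
    coordinates.  An IUPAC-compatible base pair (e.g. W against T) counts
    as a match; N in the read matches everything.  Hits are sorted by
    (mismatches, offset).
    """
    if not read_bases:
        raise ValueError("empty read")
    bits = _encode(read_bases)
    hits = _scan(bits, primer.iupac_sequence, primer.max_mismatch, "+")
    hits += _scan(bits, revcomp(primer.iupac_sequence), primer.max_mismatch, "-")
    hits.sort(key=lambda h: (h.mismatches, h.offset, h.strand))
    return hits


def extract_region(
    read: SequenceRead,
    fwd: PrimerPattern,
    rev: PrimerPattern,
    min_len: int,
    max_len: int,
    trim_primers: bool = False,
) -> SequenceRead | None:
    """Excise the amplicon between a forward and a reverse primer.

    Primers are given in amplicon orientation: the forward pattern is
    matched as-is, the reverse pattern as its reverse complement downstream
    of the forward hit.  If the read only matches in reverse orientation
    the result is reverse-complemented back to amplicon orientation.  The
    excised region includes both primer sites unless ``trim_primers``;
    its length must fall in [min_len, max_len].  Among candidate hit
    pairs the one with fewest total mismatches wins, ties broken by
    leftmost forward then rightmost reverse hit.  Returns None when no
    acceptable pair exists.
    """
    for orient in ("+", "-"):
        if orient == "+":
            seq, quals = read.bases, list(read.quals)
        else:
            seq, quals = revcomp(read.bases), list(read.quals)[::-1]
        fwd_hits = [h for h in find_primer(seq, fwd) if h.strand == "+"]
        rev_hits = [h for h in find_primer(seq, rev) if h.strand == "-"]
        if not fwd_hits or not rev_hits:
            continue
        best: tuple[int, int, int] | None = None  # (total_mm, f.offset, -r.offset)
        best_pair: tuple[PrimerHit, PrimerHit] | None = None
        for f in fwd_hits:
            for r in rev_hits:
                end = r.offset + len(rev.iupac_sequence)
                if end <= f.offset:
                    continue
                if not (min_len <= end - f.offset <= max_len):
                    continue
                key = (f.mismatches + r.mismatches, f.offset, -r.offset)
                if best is None or key < best:
                    best, best_pair = key, (f, r)
        if best_pair is None:
            continue
        f, r = best_pair
        start = f.offset + (len(fwd.iupac_sequence) if trim_primers else 0)
        end = r.offset + (0 if trim_primers else len(rev.iupac_sequence))
        if end <= start:
            continue
        return SequenceRead(
            read_id=read.read_id,
            bases=seq[start:end],
            quals=quals[start:end],
            sample_id=read.sample_id,
        )
    return None


# ---------------------------------------------------------------------------
# QC filter

@dataclass(frozen=True)
class ReadFilterConfig:
    min_mean_quality: float = 9.0
    min_length: int = 1300
    max_length: int = 1600

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass
class QCReport:
    n_input: int = 0
    n_retained: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_low_quality: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def mean_read_quality(quals: list[int]) -> float:
    """Phred-scaled mean error probability: -10*log10(mean 10^(-Q/10))."""
    if not quals:
        raise ValueError("empty quality list")
    p = np.power(10.0, -np.asarray(quals, dtype=float) / 10.0)
    return float(-10.0 * math.log10(float(p.mean())))


def filter_reads(
    reads, cfg: ReadFilterConfig = ReadFilterConfig()
) -> tuple[list[SequenceRead], QCReport]:
    """Keep reads with length in [min_length, max_length] (inclusive) and
    mean quality >= min_mean_quality.  Length is checked first, so a read
    failing both criteria is counted under its length reason."""
    report = QCReport()
    retained: list[SequenceRead] = []
    for read in reads:
        report.n_input += 1
        n = len(read)
        if n < cfg.min_length:
            report.n_too_short += 1
        elif n > cfg.max_length:
            report.n_too_long += 1
        elif mean_read_quality(read.quals) < cfg.min_mean_quality:
            report.n_low_quality += 1
        else:
            report.n_retained += 1
            retained.append(read)
    return retained, report


def subsample_reads(reads: list, n: int, seed: int) -> list:
    """Uniform sample of ``n`` reads without replacement, deterministic
    given ``seed``; n == len(reads) returns a permutation."""
    if n > len(reads):
        raise ValueError(f"cannot sample {n} from {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]
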
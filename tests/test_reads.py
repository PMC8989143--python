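import math

import numpy as np
import pytest
from bovibuccal.io import SequenceRead
from bovibuccal.reads import (
    IUPAC_BITS,
    PRIMER_341F,
    PRIMER_805R,
    PrimerPattern,
    ReadFilterConfig,
    extract_region,
    filter_reads,
    find_primer,
    mean_read_quality,
    revcomp,
    subsample_reads,
)


def _read(bases: str, q: int = 20, read_id: str = "r") -> SequenceRead:
    return SequenceRead(read_id, bases, [q] * len(bases))


class TestMeanReadQuality:
    def test_uniform_input_is_identity(self):
        assert mean_read_quality([9] * 50) == pytest.approx(9.0)
        assert mean_read_quality([0]) == pytest.approx(0.0)

    def test_error_probability_averaging(self):
        # probabilities 0.1 and 0.01 average to 0.055 -> 12.596 dB,
        # below the arithmetic Phred mean of 15
        assert mean_read_quality([10, 20]) == pytest.approx(
            -10 * math.log10(0.055), abs=1e-9
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_read_quality([])


class TestFilterReads:
    @pytest.mark.parametrize(
        "length,qual,kept",
        [
            (1300, 9, True),  # both boundaries inclusive
            (1600, 9, True),
            (1299, 40, False),
            (1601, 40, False),
            (1400, 8, False),
        ],
    )
    def test_boundaries(self, length, qual, kept):
        retained, rep = filter_reads([_read("A" * length, qual)])
        assert (len(retained) == 1) is kept
        assert rep.n_input == 1

    def test_matches_brute_force_rescan(self, rng):
        reads = []
        for i in range(500):
            n = int(rng.integers(1200, 1700))
            quals = [int(q) for q in rng.integers(2, 25, size=n)]
            reads.append(SequenceRead(f"r{i}", "A" * n, quals))
        cfg = ReadFilterConfig()
        retained, rep = filter_reads(reads, cfg)
        expected = [
            r
            for r in reads
            if 1300 <= len(r) <= 1600 and mean_read_quality(r.quals) >= 9.0
        ]
        assert retained == expected
        assert rep.n_retained == len(expected)
        assert rep.n_input == rep.n_retained + rep.n_too_short + rep.n_too_long + rep.n_low_quality

    def test_idempotent(self, rng):
        reads = []
        for i in range(80):
            n = int(rng.integers(1250, 1650))
            reads.append(SequenceRead(f"r{i}", "A" * n, [int(q) for q in rng.integers(3, 30, size=n)]))
        once, rep1 = filter_reads(reads)
        twice, rep2 = filter_reads(once)
        assert twice == once
        assert rep2.n_retained == rep2.n_input == rep1.n_retained


def _brute_force_hits(text: str, pattern: str, max_mm: int):
    def compat(base: str, code: str) -> bool:
        return bool(IUPAC_BITS[base] & IUPAC_BITS[code])

    out = []
    for pat, strand in [(pattern, "+"), (revcomp(pattern), "-")]:
        for off in range(len(text) - len(pat) + 1):
            mm = sum(
                0 if compat(text[off + i], pat[i]) else 1 for i in range(len(pat))
            )
            if mm <= max_mm:
                out.append((off, strand, mm))
    return sorted(out, key=lambda h: (h[2], h[0], h[1]))


class TestFindPrimer:
    def test_degenerate_exact_match(self):
        # N matches A, W matches T: zero mismatches against the pattern
        site = "CCTACGGGAGGCTGCAG"
        read = "TTTT" + site + "GGGG"
        hits = find_primer(read, PrimerPattern("341F", PRIMER_341F, max_mismatch=0))
        assert [(h.offset, h.strand, h.mismatches) for h in hits] == [(4, "+", 0)]

    def test_single_substitution_counted(self):
        site = "CCTACGGGAGGCTGCAG"
        mutated = "G" + site[1:]
        hits = find_primer("AA" + mutated, PrimerPattern("341F", PRIMER_341F, max_mismatch=1))
        assert hits and hits[0].mismatches == 1

    def test_matches_sliding_window_brute_force(self, rng):
        primer = PrimerPattern("805R", PRIMER_805R, max_mismatch=3)
        for _ in range(30):
            text = "".join(rng.choice(list("ACGT"), size=2000))
            got = [(h.offset, h.strand, h.mismatches) for h in find_primer(text, primer)]
            assert got == _brute_force_hits(text, primer.iupac_sequence, 3)


class TestExtractRegion:
    @pytest.fixture()
    def constructed(self, rng):
        fwd_site = "CCTACGGGAGGCTGCAG"  # one instantiation of 341F
        rev_site = revcomp("GACTACAAGGGTATCTAATCC")  # instantiated 805R, rc'd
        insert = "".join(rng.choice(list("ACGT"), size=420))
        pad5 = "".join(rng.choice(list("ACGT"), size=100))
        pad3 = "".join(rng.choice(list("ACGT"), size=150))
        bases = pad5 + fwd_site + insert + rev_site + pad3
        quals = list(np.arange(len(bases)) % 40 + 2)
        return SequenceRead("c1", bases, [int(q) for q in quals]), len(pad5)

    def test_constructed_fixture_excised_at_known_offsets(self, constructed):
        read, start = constructed
        fwd = PrimerPattern("341F", PRIMER_341F)
        rev = PrimerPattern("805R", PRIMER_805R)
        sub = extract_region(read, fwd, rev, min_len=400, max_len=500)
        assert sub is not None
        expected_len = 17 + 420 + 21
        assert len(sub) == expected_len
        assert sub.bases == read.bases[start : start + expected_len]
        assert sub.quals == read.quals[start : start + expected_len]

    def test_output_contains_forward_match_at_offset_zero(self, constructed):
        read, _ = constructed
        fwd = PrimerPattern("341F", PRIMER_341F)
        rev = PrimerPattern("805R", PRIMER_805R)
        sub = extract_region(read, fwd, rev, 400, 500)
        hits = [h for h in find_primer(sub.bases, fwd) if h.strand == "+"]
        assert hits and hits[0].offset == 0
        assert 400 <= len(sub) <= 500

    def test_missing_reverse_primer_gives_none(self, rng):
        bases = "".join(rng.choice(list("ACGT"), size=60)) + "CCTACGGGAGGCTGCAG" + "".join(
            rng.choice(list("ACGT"), size=500)
        )
        read = _read(bases)
        assert (
            extract_region(
                read, PrimerPattern("341F", PRIMER_341F), PrimerPattern("805R", PRIMER_805R), 50, 600
            )
            is None
        )

    def test_strand_symmetry(self, constructed):
        read, _ = constructed
        fwd = PrimerPattern("341F", PRIMER_341F)
        rev = PrimerPattern("805R", PRIMER_805R)
        flipped = SequenceRead("c1rc", revcomp(read.bases), read.quals[::-1])
        a = extract_region(read, fwd, rev, 400, 500)
        b = extract_region(flipped, fwd, rev, 400, 500)
        assert a is not None and b is not None
        assert a.bases == b.bases and a.quals == b.quals

    def test_trim_primers_removes_sites(self, constructed):
        read, start = constructed
        fwd = PrimerPattern("341F", PRIMER_341F)
        rev = PrimerPattern("805R", PRIMER_805R)
        sub = extract_region(read, fwd, rev, 300, 500, trim_primers=True)
        assert len(sub) == 420
        assert sub.bases == read.bases[start + 17 : start + 17 + 420]


class TestSubsample:
    def test_full_sample_is_permutation(self, rng):
        reads = [_read("ACGT", read_id=f"r{i}") for i in range(25)]
        out = subsample_reads(reads, 25, seed=3)
        assert sorted(r.read_id for r in out) == sorted(r.read_id for r in reads)

    def test_zero_and_overdraw(self):
        reads = [_read("ACGT")] * 4
        assert subsample_reads(reads, 0, seed=1) == []
        with pytest.raises(ValueError):
            subsample_reads(reads, 5, seed=1)

    def test_deterministic(self):
        reads = [_read("ACGT", read_id=f"r{i}") for i in range(30)]
        a = subsample_reads(reads, 10, seed=9)
        b = subsample_reads(reads, 10, seed=9)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_single_draw_frequencies_uniform(self):
        from scipy.stats import chisquare

        reads = [_read("ACGT", read_id=f"r{i}") for i in range(4)]
        counts = {f"r{i}": 0 for i in range(4)}
        for s in range(10_000):
            (pick,) = subsample_reads(reads, 1, seed=s)
            counts[pick.read_id] += 1
        assert chisquare(list(counts.values())).pvalue > 0.01
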
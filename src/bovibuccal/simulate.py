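"""Synthetic rumen/buccal amplicon data with known ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes, so every stage can be tested against a known answer:

* **Communities.**  Rumen and oral communities share some taxa and hold
  some exclusively; within each community taxon abundances are long-tailed
  (log-normal, then normalised), the shape typical of 16S profiles.
* **Buccal samples** are mixtures: a fraction ``rho`` of reads comes from
  the oral community and ``1 - rho`` from the rumen community.  ``rho``
  is the per-sample contamination ground truth.  Observed buccal swabs
  carry anywhere from a few percent to ~90% oral reads, so the default
  ``rho`` range is (0.05, 0.9).
* **Reads** are drawn from 16S-like templates (1,300-1,600 bp) built
  around the conserved primer sites 27F ... 341F ... 805R' ... 1525R'
  with random variable regions, then corrupted by an i.i.d. per-base
  error process at a 5% total rate (the figure usually quoted for
  nanopore single reads), split 2% substitutions, 1.5% insertions,
  1.5% deletions.  An inserted base is uniform random; a deletion drops
  the base.  Erroneous bases receive low Phred scores (uniform 3-12),
  correct bases moderate ones (uniform 10-30), so the mean-quality QC
  filter sees both passing and failing reads.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Lineage, SampleMetadata, SampleType, SequenceRead
from .reads import PRIMER_27F, PRIMER_341F, PRIMER_805R, PRIMER_1525R, IUPAC_BITS, revcomp

_BASES = "ACGT"
_BIT_TO_BASES = {
    code: [b for b in _BASES if IUPAC_BITS[b] & bits]
    for code, bits in IUPAC_BITS.items()
}


@dataclass(frozen=True)
class CommunityProfile:
    taxon_ids: tuple[str, ...]
    relative_abundances: np.ndarray
    label: str  # "rumen" or "oral"

    def __post_init__(self) -> None:
        ab = np.asarray(self.relative_abundances, dtype=float)
        if len(ab) != len(self.taxon_ids):
            raise ValueError("abundance/taxon length mismatch")
        if (ab < 0).any() or abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must be >= 0 and sum to 1")
        object.__setattr__(self, "relative_abundances", ab)

    def as_series(self) -> pd.Series:
        return pd.Series(self.relative_abundances, index=list(self.taxon_ids))


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.02
    insertion_rate: float = 0.015
    deletion_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.substitution_rate + self.insertion_rate + self.deletion_rate > 1:
            raise ValueError("total error rate exceeds 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    per_sample_contamination: dict[str, float] = field(default_factory=dict)
    per_read_source: dict[str, tuple[str, str]] = field(default_factory=dict)
    rumen_profile: CommunityProfile | None = None
    oral_profile: CommunityProfile | None = None


# ---------------------------------------------------------------------------
# Communities

def generate_profiles(
    n_shared: int,
    n_rumen_only: int,
    n_oral_only: int,
    lognormal_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[CommunityProfile, CommunityProfile]:
    """Paired rumen/oral community profiles over a partitioned taxon set.

    Taxa are named ``shared_NNN`` / ``rumen_NNN`` / ``oral_NNN``.  Each
    community's abundances are independent log-normal(0, sigma) draws over
    its support, normalised to 1; ``sigma = 0`` degenerates to a uniform
    profile.  The default sigma 1.5 gives the strongly long-tailed
    rank-abundance curves typical of rumen communities.
    """
    if min(n_shared, n_rumen_only, n_oral_only) < 0:
        raise ValueError("counts must be >= 0")
    if n_shared + n_rumen_only + n_oral_only == 0:
        raise ValueError("at least one taxon required")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    shared = tuple(f"shared_{i:03d}" for i in range(n_shared))
    rumen_only = tuple(f"rumen_{i:03d}" for i in range(n_rumen_only))
    oral_only = tuple(f"oral_{i:03d}" for i in range(n_oral_only))

    def draw(taxa: tuple[str, ...], label: str) -> CommunityProfile:
        ab = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(taxa))
        return CommunityProfile(taxa, ab / ab.sum(), label)

    rumen = draw(shared + rumen_only, "rumen")
    oral = draw(shared + oral_only, "oral")
    return rumen, oral


@dataclass
class SampleCounts:
    """Multinomial taxon counts for one sample, broken down by source."""

    counts: pd.Series  # total per taxon (union support)
    source_counts: pd.DataFrame  # taxa x {rumen, oral}
    rho: float


def generate_sample_counts(
    rumen: CommunityProfile,
    oral: CommunityProfile,
    rho: float,
    depth: int,
    seed: int = 0,
) -> SampleCounts:
    """Draw one sample's taxon counts from the mixture
    ``(1 - rho) * rumen + rho * oral`` at the given read depth.

    The number of oral-source reads is Binomial(depth, rho) and each
    source's reads are multinomial over its own profile, which is exactly
    the mixture multinomial but keeps per-source truth.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    union = sorted(set(rumen.taxon_ids) | set(oral.taxon_ids))
    r_vec = rumen.as_series().reindex(union, fill_value=0.0).to_numpy()
    o_vec = oral.as_series().reindex(union, fill_value=0.0).to_numpy()
    n_oral = int(rng.binomial(depth, rho))
    c_oral = rng.multinomial(n_oral, o_vec) if n_oral else np.zeros(len(union), dtype=int)
    c_rumen = (
        rng.multinomial(depth - n_oral, r_vec)
        if depth - n_oral
        else np.zeros(len(union), dtype=int)
    )
    source = pd.DataFrame({"rumen": c_rumen, "oral": c_oral}, index=union)
    return SampleCounts(source.sum(axis=1), source, rho)


# ---------------------------------------------------------------------------
# Reference templates

@dataclass(frozen=True)
class ReferenceTemplate:
    sequence: str
    v34_start: int  # start of the 341F site
    v34_end: int  # end (exclusive) of the 805R reverse-complement site


def _instantiate(iupac: str, rng: np.random.Generator) -> str:
    return "".join(
        choices[rng.integers(len(choices))] for choices in
        (_BIT_TO_BASES[c] for c in iupac)
    )


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def generate_references(
    taxon_ids, seed: int = 0
) -> dict[str, ReferenceTemplate]:
    """One 16S-like template per taxon: 27F + V1-V2 + 341F + V3-V4 +
    805R' + V5-V9 + 1525R' with random variable regions (total ~1,320-1,490
    bp, inside the 1,300-1,600 bp amplicon window).  Degenerate primer
    positions are instantiated per taxon.  Unrelated templates differ over
    ~95% of their variable positions, so references are well separated.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, ReferenceTemplate] = {}
    for tid in taxon_ids:
        v12 = _random_seq(int(rng.integers(280, 321)), rng)
        v34 = _random_seq(int(rng.integers(400, 441)), rng)
        v59 = _random_seq(int(rng.integers(550, 651)), rng)
        p27 = _instantiate(PRIMER_27F, rng)
        p341 = _instantiate(PRIMER_341F, rng)
        p805rc = revcomp(_instantiate(PRIMER_805R, rng))
        p1525rc = revcomp(_instantiate(PRIMER_1525R, rng))
        start = len(p27) + len(v12)
        end = start + len(p341) + len(v34) + len(p805rc)
        seq = p27 + v12 + p341 + v34 + p805rc + v59 + p1525rc
        out[tid] = ReferenceTemplate(seq, start, end)
    return out


_LINEAGE_POOL = [
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Rikenellaceae;g__Rikenellaceae_RC9_gut_group",
    "d__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;f__Ruminococcaceae;g__Ruminococcus",
    "d__Bacteria;p__Firmicutes;c__Clostridia;o__Christensenellales;f__Christensenellaceae;g__Christensenellaceae_R-7_group",
    "d__Bacteria;p__Firmicutes;c__Clostridia;o__Lachnospirales;f__Lachnospiraceae;g__Butyrivibrio",
]

_ORAL_LINEAGE_POOL = [
    "d__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus",
    "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Burkholderiales;f__Neisseriaceae;g__Neisseria",
    "d__Bacteria;p__Actinobacteriota;c__Actinobacteria;o__Actinomycetales;f__Actinomycetaceae;g__Actinomyces",
]


def scenario_lineages(taxon_ids) -> dict[str, Lineage]:
    """Deterministic SILVA-style lineages for generator taxa: oral-only taxa
    cycle through typical oral genera, all others through rumen genera."""
    out = {}
    for tid in taxon_ids:
        pool = _ORAL_LINEAGE_POOL if tid.startswith("oral") else _LINEAGE_POOL
        idx = sum(tid.encode()) % len(pool)
        out[tid] = Lineage.parse(f"{pool[idx]};s__{tid}")
    return out


# ---------------------------------------------------------------------------
# Reads

def _mutate(template: str, model: ErrorModel, rng: np.random.Generator) -> tuple[str, list[int]]:
    p_del = model.deletion_rate
    p_sub = model.substitution_rate
    p_ins = model.insertion_rate
    bases: list[str] = []
    errs: list[bool] = []
    u = rng.random(len(template))
    for base, x in zip(template, u):
        if x < p_del:
            continue
        if x < p_del + p_sub:
            others = [b for b in _BASES if b != base]
            bases.append(others[rng.integers(3)])
            errs.append(True)
        elif x < p_del + p_sub + p_ins:
            bases.append(base)
            errs.append(False)
            bases.append(_BASES[rng.integers(4)])
            errs.append(True)
        else:
            bases.append(base)
            errs.append(False)
    quals = [
        int(rng.integers(3, 13)) if e else int(rng.integers(10, 31)) for e in errs
    ]
    return "".join(bases), quals


def generate_reads(
    counts,
    references: dict[str, ReferenceTemplate] | dict[str, str],
    error_model: ErrorModel = ErrorModel(),
    sample_id: str = "S",
    id_start: int = 0,
) -> tuple[list[SequenceRead], dict[str, str]]:
    """Generate ``counts[taxon]`` error-bearing reads per taxon.

    Returns the reads and a read_id -> source taxon map.  Deterministic
    given ``error_model.seed``; read ids are ``<sample>_r<NNNNN>`` numbered
    from ``id_start``.
    """
    rng = np.random.default_rng(error_model.seed)
    items = counts.items() if hasattr(counts, "items") else counts
    reads: list[SequenceRead] = []
    truth: dict[str, str] = {}
    i = id_start
    for taxon, n in sorted(items):
        n = int(n)
        if n == 0:
            continue
        if taxon not in references:
            raise KeyError(f"no reference template for taxon {taxon!r}")
        tpl = references[taxon]
        seq = tpl.sequence if isinstance(tpl, ReferenceTemplate) else tpl
        for _ in range(n):
            bases, quals = _mutate(seq, error_model, rng)
            rid = f"{sample_id}_r{i:05d}"
            reads.append(SequenceRead(rid, bases, quals, sample_id))
            truth[rid] = taxon
            i += 1
    return reads, truth


# ---------------------------------------------------------------------------
# Whole-dataset scenario

@dataclass
class SimulatedDataset:
    reads: dict[str, list[SequenceRead]]
    metadata: list[SampleMetadata]
    references: dict[str, tuple[str, Lineage]]
    templates: dict[str, ReferenceTemplate]
    truth: SyntheticTruth


def simulate_dataset(
    n_buccal: int = 15,
    n_rumen: int = 5,
    n_shared: int = 24,
    n_rumen_only: int = 3,
    n_oral_only: int = 15,
    depth: int = 200,
    rho_range: tuple[float, float] = (0.05, 0.9),
    error_model: ErrorModel = ErrorModel(),
    lognormal_sigma: float = 1.5,
    seed: int = 0,
) -> SimulatedDataset:
    """A full synthetic study: paired buccal and rumen samples with reads.

    The default cohort (15 buccal + 5 rumen samples) and the 5-90%
    contamination range match a typical buccal-swab validation design;
    taxon counts keep the shared >> oral-only > rumen-only partition shape
    at desk scale.  Rumen samples have rho = 0.  Buccal samples are paired
    with animals A01.. (the first ``n_rumen`` animals also provide the
    rumen samples).
    """
    rng = np.random.default_rng(seed)
    rumen_prof, oral_prof = generate_profiles(
        n_shared, n_rumen_only, n_oral_only, lognormal_sigma, seed=int(rng.integers(2**31))
    )
    all_taxa = sorted(set(rumen_prof.taxon_ids) | set(oral_prof.taxon_ids))
    templates = generate_references(all_taxa, seed=int(rng.integers(2**31)))
    lineages = scenario_lineages(all_taxa)
    references = {t: (templates[t].sequence, lineages[t]) for t in all_taxa}

    truth = SyntheticTruth(rumen_profile=rumen_prof, oral_profile=oral_prof)
    reads: dict[str, list[SequenceRead]] = {}
    metadata: list[SampleMetadata] = []

    def one_sample(sid: str, stype: SampleType, animal: str, rho: float) -> None:
        sc = generate_sample_counts(
            rumen_prof, oral_prof, rho, depth, seed=int(rng.integers(2**31))
        )
        em = ErrorModel(
            error_model.substitution_rate,
            error_model.insertion_rate,
            error_model.deletion_rate,
            seed=int(rng.integers(2**31)),
        )
        r_reads, r_truth = generate_reads(
            sc.source_counts["rumen"], templates, em, sample_id=sid, id_start=0
        )
        em2 = ErrorModel(
            error_model.substitution_rate,
            error_model.insertion_rate,
            error_model.deletion_rate,
            seed=int(rng.integers(2**31)),
        )
        o_reads, o_truth = generate_reads(
            sc.source_counts["oral"], templates, em2, sample_id=sid,
            id_start=len(r_reads),
        )
        reads[sid] = r_reads + o_reads
        for rid, tax in r_truth.items():
            truth.per_read_source[rid] = (tax, "rumen")
        for rid, tax in o_truth.items():
            truth.per_read_source[rid] = (tax, "oral")
        truth.per_sample_contamination[sid] = rho
        metadata.append(SampleMetadata(sid, stype, animal))

    for i in range(n_buccal):
        rho = float(rng.uniform(*rho_range))
        one_sample(f"BS{i + 1:02d}", SampleType.BUCCAL, f"A{i + 1:02d}", rho)
    for i in range(n_rumen):
        one_sample(f"RU{i + 1:02d}", SampleType.RUMEN, f"A{i + 1:02d}", 0.0)

    return SimulatedDataset(reads, metadata, references, templates, truth)


def generate_partitioned_tables(
    n_buccal_only: int = 155,
    n_rumen_only: int = 23,
    n_shared: int = 241,
    n_ratio_exceeding: int = 40,
    ratio: float = 5.0,
    n_buccal_samples: int = 3,
    n_rumen_samples: int = 2,
    seed: int = 0,
):
    """Paired buccal/rumen count tables with a prescribed detection partition.

    Constructs, by design rather than by classification, a taxon universe of
    ``n_buccal_only`` taxa detected only in buccal samples, ``n_rumen_only``
    detected only in rumen samples, and ``n_shared`` detected in both of
    which exactly ``n_ratio_exceeding`` have maximum buccal relative
    abundance strictly greater than ``ratio`` times their maximum rumen
    relative abundance (placed at ~1.4x ``ratio``; the rest sit at ~0.1x
    ``ratio``, far from the boundary on either side).  The defaults mirror
    the partition sizes reported for a five-animal paired buccal/rumen
    comparison.  Returns ``(buccal TaxonTable, rumen TaxonTable)``.
    """
    from .tables import TaxonTable

    if n_ratio_exceeding > n_shared:
        raise ValueError("n_ratio_exceeding cannot exceed n_shared")
    rng = np.random.default_rng(seed)
    bo = [f"buccalonly_{i:03d}" for i in range(n_buccal_only)]
    ro = [f"rumenonly_{i:03d}" for i in range(n_rumen_only)]
    sh_hi = [f"shared_hi_{i:03d}" for i in range(n_ratio_exceeding)]
    sh_lo = [f"shared_lo_{i:03d}" for i in range(n_shared - n_ratio_exceeding)]
    universe = bo + ro + sh_hi + sh_lo

    # rumen: ordinary counts for rumen-only and low-ratio shared taxa, very
    # low counts for the taxa that must exceed the ratio in buccal samples
    # (so their buccal abundance can exceed ratio * max_rumen and still fit
    # inside one composition)
    rumen_counts = pd.DataFrame(0, index=universe, columns=[
        f"RU{i + 1:02d}" for i in range(n_rumen_samples)
    ])
    for col in rumen_counts.columns:
        rumen_counts.loc[ro + sh_lo, col] = rng.integers(10, 101, size=len(ro) + len(sh_lo))
        rumen_counts.loc[sh_hi, col] = rng.integers(1, 4, size=len(sh_hi))
    rumen = TaxonTable(rumen_counts, rank="s")
    rmax = rumen.relabund.max(axis=1)

    # buccal targets relative to the realised rumen maxima
    target = pd.Series(0.0, index=universe)
    target[sh_hi] = 1.4 * ratio * rmax[sh_hi]
    target[sh_lo] = 0.1 * ratio * rmax[sh_lo]
    rest = 1.0 - target.sum()
    if rest <= 0:
        raise ValueError("shared-taxon targets exceed one composition")
    w = rng.uniform(0.5, 1.5, size=len(bo))
    target[bo] = rest * w / w.sum()

    total = 2_000_000
    buccal_counts = pd.DataFrame(0, index=universe, columns=[
        f"BS{i + 1:02d}" for i in range(n_buccal_samples)
    ])
    for col in buccal_counts.columns:
        jitter = rng.uniform(0.99, 1.01, size=len(universe))
        buccal_counts[col] = np.maximum(
            np.rint(target.to_numpy() * jitter * total).astype(int),
            (target.to_numpy() > 0).astype(int),
        )
    return TaxonTable(buccal_counts, rank="s"), rumen


def two_population_tables(
    n_group1: int = 7,
    n_group2: int = 21,
    n_taxa: int = 20,
    depth: int = 10_000,
    effect: float = 3.0,
    concentration: float = 100.0,
    seed: int = 0,
):
    """Taxon tables with a planted two-community structure.

    Group 1 samples are Prevotella-dominant, group 2 Clostridiales-dominant:
    the first half of the taxa (Prevotella lineages) is up-weighted by
    ``effect`` in group 1, the second half (Clostridiales lineages) in
    group 2.  Per-sample profiles are Dirichlet-perturbed around the group
    profile (``concentration`` controls sample-to-sample noise) and counts
    are multinomial at ``depth``.  The default 7 + 21 split mirrors the
    cluster sizes commonly seen in a ~28-animal herd.

    Returns (TaxonTable, true labels aligned with the table's samples).
    """
    from .tables import TaxonTable

    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    half = n_taxa // 2
    prev = [
        f"d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
        f"f__Prevotellaceae;g__Prevotella;s__prevotella_sp_{i:02d}"
        for i in range(half)
    ]
    clos = [
        f"d__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;"
        f"f__Ruminococcaceae;g__Ruminococcus;s__clostridiales_sp_{i:02d}"
        for i in range(n_taxa - half)
    ]
    taxa = prev + clos
    base = rng.lognormal(0.0, 1.0, size=n_taxa)
    up = np.ones(n_taxa)
    up[:half] = effect
    prof1 = base * up
    prof1 /= prof1.sum()
    prof2 = base / up * effect  # up-weight the Clostridiales block instead
    prof2[:half] = base[:half]
    prof2 /= prof2.sum()

    cols, labels = {}, []
    for g, (n, prof) in enumerate([(n_group1, prof1), (n_group2, prof2)], start=1):
        for i in range(n):
            theta = rng.dirichlet(concentration * prof)
            sid = f"G{g}S{i + 1:02d}"
            cols[sid] = rng.multinomial(depth, theta)
            labels.append(g)
    counts = pd.DataFrame(cols, index=taxa)
    return TaxonTable(counts, rank="s"), labels
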
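# bovibuccal

Long-read 16S rRNA profiling of the bovine rumen microbiota from buccal
(cheek-swab) samples: a tested, reusable re-implementation of the full
computational path from raw nanopore-style amplicon reads to
contaminant-filtered community profiles, together with a synthetic-data
generator that provides ground truth for every stage.

## The problem

Rumen sampling through a cannula or stomach tube does not scale to herds,
so buccal swabs are used as a proxy: cattle ruminate, and regurgitated
material leaves a rumen-microbe signature in the mouth. The catch is that
swabs also carry genuine oral bacteria which must be identified and
removed before the profile can stand in for rumen contents. Full-length
(V1–V9) 16S amplicons sequenced on long-read platforms allow species-level
assignment despite a ~5% per-base error rate, because the alignment spans
many variable regions.

The pipeline stages are:

1. **Read QC** — keep reads with length in [1,300, 1,600] bp (inclusive)
   and mean quality ≥ 9, where mean quality is the Phred-scaled mean error
   probability, −10·log₁₀(mean 10^(−Qᵢ/10)).
2. **Taxonomy assignment** — exact affine-gap local alignment of each read
   against every reference under the mismatch-tolerant scheme
   *match +1, mismatch −1, gap of length k −(1 + k)*; the highest-scoring
   reference's SILVA-style lineage is assigned (ties → lexicographically
   smallest reference id), and taxa supported by a single read
   (singletons) are excluded.
3. **Table filters** — samples with < 5,000 assigned reads are dropped;
   taxa are "observed" when their relative abundance exceeds 0.1%
   (strictly) in enough samples; heat-map views use a > 1% mean-abundance
   cut.
4. **Oral-contaminant filter** — a taxon is putative oral bacteria if it
   is (rule 1) detected only in buccal samples, or (rule 2) shared but its
   maximum buccal relative abundance is more than 5× its maximum rumen
   relative abundance. Removing these taxa leaves a per-sample
   remaining-read fraction; heavily contaminated samples can be flagged.
5. **Community statistics** — Bray–Curtis dissimilarity
   (1 − 2·Σmin(u,v)/(Σu+Σv)) with principal coordinate analysis,
   Euclidean distances with Ward (D2) hierarchical clustering, Pearson
   correlation matrices with t-based p-values, Welch's t-test, and
   Dunnett's many-to-one comparison via Monte-Carlo sampling of the
   max-|t| null.
6. **Simulation** — log-normal rumen/oral communities, buccal samples as
   mixtures with contamination fraction ρ, and reads drawn from
   primer-structured 16S-like templates (27F…341F…805R′…1525R′) under an
   i.i.d. substitution/insertion/deletion error model with
   consistent Phred qualities — so QC, in-silico V3–V4 extraction,
   assignment and the oral filter are all testable against known truth.

## Worked example

```python
from bovibuccal import (simulate_dataset, filter_reads, assign_reads,
                        remove_singletons, build_table,
                        classify_oral_taxa, apply_oral_filter)

ds = simulate_dataset(n_buccal=3, n_rumen=2, n_shared=8, n_rumen_only=2,
                      n_oral_only=5, depth=40, seed=42)
assignments = []
for sid, reads in sorted(ds.reads.items()):
    kept, report = filter_reads(reads)
    assignments += assign_reads(kept, ds.references)
assignments = remove_singletons(assignments)
table = build_table(assignments, ds.metadata, rank="s")
correct = sum(a.reference_id == ds.truth.per_read_source[a.read_id][0]
              for a in assignments)
print(f"reads assigned to true source taxon: {correct}/{len(assignments)}")

buccal = table.subset_samples(["BS01", "BS02", "BS03"])
rumen = table.subset_samples(["RU01", "RU02"])
report = classify_oral_taxa(buccal, rumen)
filtered, removed = apply_oral_filter(buccal, report)
print(f"putative oral taxa: {len(report.putative_oral_taxa)} "
      f"(buccal-only {len(report.buccal_only_taxa)}, "
      f"flagged shared {len(report.flagged_shared_taxa)})")

oral = ds.truth.oral_profile.as_series()
exclusive = oral[[t for t in oral.index if t.startswith("oral")]].sum()
for sid in buccal.sample_ids:
    rho = ds.truth.per_sample_contamination[sid]
    print(f"{sid}: removable oral mass {rho * exclusive:.2f}, "
          f"removed fraction {removed[sid]:.2f}")
```

prints

```
reads assigned to true source taxon: 198/198
putative oral taxa: 3 (buccal-only 3, flagged shared 0)
BS01: removable oral mass 0.15, removed fraction 0.08
BS02: removable oral mass 0.05, removed fraction 0.10
BS03: removable oral mass 0.24, removed fraction 0.30
```

Despite 5% simulated per-base error, every read aligns best to its true
source template. The filter removes the three oral-exclusive taxa that
survived earlier filters; the removed-read fraction per buccal sample
tracks ρ × (oral-exclusive mass) — the portion of contamination the
two-rule filter *can* remove, since oral-source reads falling in shared
taxa are indistinguishable at table level — up to multinomial noise at
this small per-sample depth (40 reads). At depth 10⁴ the mean absolute
error of this recovery is below 0.03 (see the test suite).

A command-line interface mirrors the library
(`bovibuccal simulate|qc|extract-region|assign|table|oralfilter|stats|run`);
`bovibuccal run --config cfg.yaml --out-dir out/` executes every stage and
writes seed-stamped artifacts plus a `summary.json` with the complete
bookkeeping (reads in/out per filter, per-rank assigned fractions, the
oral-taxon partition, per-sample removed fractions, cluster labels).
Reruns with the same config and seed are byte-identical.

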
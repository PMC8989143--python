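# Methods

This note documents the models, conventions and numerical choices behind
`bovibuccal`, and what the synthetic-data tests do and do not establish
about real data.

## Read QC

A read is retained iff its length lies in the inclusive window
[`min_length`, `max_length`] (defaults 1,300 and 1,600 bp, the expected
size range of a V1–V9 amplicon) **and** its mean quality is at least
`min_mean_quality` (default Phred 9). Mean quality is defined on the
error-probability scale,

    Q̄ = −10 · log₁₀( (1/n) Σᵢ 10^(−Qᵢ/10) ),

not as the arithmetic mean of Phred values. The two differ whenever
qualities vary (the probability average is dominated by the worst bases,
so Q̄ ≤ arithmetic mean); the probability definition is the one used by
the standard long-read filtering tools, and we state it explicitly
because the arithmetic mean would silently retain more reads. Length is
checked before quality, so a read failing both is tallied under its
length reason in the QC report.

## Primer matching and in-silico region extraction

Primer sites are matched as IUPAC-degenerate patterns allowing
substitutions only (no indels), with a default tolerance of 3 mismatches.
A base matches a pattern position when their IUPAC sets intersect (so N
in a read matches everything, W matches A or T, and so on). Matches are
searched on both strands; a reverse-strand hit is a window matching the
reverse complement of the pattern, reported in read coordinates.

Substitution-only matching is a deliberate simplification: for 17–21-mer
primers at ~5% per-base error, most error events within a site are
substitutions, and indel-bearing sites are simply not recovered for that
read. This keeps the matcher exactly equivalent to a sliding-window
Hamming scan (which the tests exploit as a brute-force oracle) at the
cost of some sensitivity; the tolerance is a flag for users who want to
trade specificity for recovery.

Region extraction (e.g. V3–V4 from a V1–V9 read via 341F/805R) takes the
forward primer as-is and the reverse primer as its reverse complement
downstream; the excised sub-read runs from the start of the forward site
through the end of the reverse site, primers included (a `trim_primers`
flag removes them), and must fall within a length window. Among candidate
hit pairs the rule is: fewest total mismatches, then leftmost forward
hit, then rightmost reverse hit. If the read only matches in the reverse
orientation, the output is reverse-complemented back to amplicon
orientation (with qualities reversed), so extraction is strand-symmetric.

## Taxonomy assignment

Reads are assigned by exact affine-gap local alignment (Smith–Waterman
with Gotoh's gap recurrence) against every reference, under integer
scoring: +r per match, −q per mismatch, −(a + b·k) for a gap of length k,
defaults r = q = a = b = 1. This low-penalty scheme is the convention for
taxonomic read assignment of high-error long reads: it prioritises
finding the closest reference over alignment precision. `N` scores as a
mismatch against every base, including `N`.

Because the package targets desk-scale reference sets (tens to hundreds
of full-length 16S sequences), the exact dynamic programme is affordable
and replaces seed-and-extend heuristics entirely; there is no seeding,
banding, or E-value model. The DP engine is Biopython's `PairwiseAligner`
configured to this scheme (open = −(a+b), extend = −b, custom ACGTN
substitution matrix); the test suite verifies it against an independent
pure-Python Gotoh implementation by exhaustive fuzzing.

Per read, the highest-scoring reference wins; ties break to the
lexicographically smallest reference id so assignment is deterministic.
Percent identity is matches / aligned columns with gap columns counted in
the denominator. When several tracebacks are co-optimal in score, one is
reported; identity can differ slightly between co-optimal tracebacks and
should be read as descriptive, not canonical. A `min_score` threshold
(default 0, i.e. assign everything) is exposed because a best hit always
exists even for junk input.

Singleton exclusion drops taxa (full-lineage identity) supported by
exactly one assigned read. The default scope is the whole dataset;
per-sample scope is available.

## Tables and filters

Taxon identity in tables is the full lineage string down to the analysis
rank, never the bare leaf name, so identically named leaves under
different parents (e.g. several "uncultured" species) cannot collide.
Reads unclassified at the analysis rank collapse into an
`<rank>__unclassified` taxon nested under their deepest classified
parent.

Relative abundance is computed per sample from current counts and is
recomputed after every table-producing operation. Filter conventions:

* sample QC: strict less-than (a sample with exactly the minimum read
  count is retained); default 5,000 assigned reads;
* prevalence ("observed") filter: relative abundance strictly greater
  than the cutoff (default 0.1%) in at least `min_samples` samples;
* mean-abundance filter: arithmetic mean relative abundance strictly
  greater than the cutoff (default 1%).

Strictness follows the usual "greater than" phrasing of these filters.
Dropped taxa are preserved in a per-sample "other" count ledger so read
totals are conserved, and the order relative abundance → prevalence
filtering is fixed in the pipeline (abundances computed after singleton
removal, before prevalence filtering).

## Oral-contaminant classification

Given paired buccal and rumen tables over a shared (union) taxon
universe — normally the post-prevalence-filter observed set — each taxon
falls into exactly one of four classes:

1. **buccal-only** (putative oral): detected in at least one buccal
   sample, in no rumen sample;
2. **flagged shared** (putative oral): detected in both, and max buccal
   relative abundance strictly greater than `ratio_threshold` (default
   5) × max rumen relative abundance;
3. **rumen-only**: symmetric to 1;
4. **retained shared**: everything else detected; taxa detected in
   neither table also land here.

"Detected" means relative abundance strictly above
`presence_min_relabund` (default 0, i.e. any nonzero count). Rule 1 takes
precedence over rule 2, so the classes partition the universe. Maxima are
taken across samples; a paired-animal variant is not implemented — with
few reference animals the across-sample maximum is what the rule
operationally uses.

Applying the filter removes the putative oral taxa; the per-sample
removed-read fraction is the filter's contamination estimate. Note its
ceiling: oral-source reads that fall in *shared* taxa are
indistinguishable from rumen-source reads at table level, so the
removable contamination is ρ × (mass the oral community holds in taxa
outside the rumen support), not ρ itself. The parameter-recovery test is
therefore run with a disjoint oral community, where the two coincide.

Sample flagging: the reference workflow judged residual contamination
visually in an ordination. We substitute two explicit criteria: a
removed-fraction threshold (default 0.5), and an alternative
distance-based flag (mean Bray–Curtis to the rumen samples above a
quantile of rumen-to-rumen dissimilarities) for users who prefer a
composition-based judgement.

## Community statistics

* **Bray–Curtis**: 1 − 2·Σmin(u,v)/(Σu+Σv) on relative abundances
  (scipy's implementation); samples with zero reads are rejected rather
  than silently placed at distance 1.
* **PCoA**: classical metric scaling. B = −½·J·D²·J is eigendecomposed;
  coordinates use strictly positive eigenvalues only (tolerance
  10⁻¹² × the leading eigenvalue), negative eigenvalues — expected for
  Bray–Curtis — are reported but not corrected (no Cailliez/Lingoes),
  and proportion explained is relative to the sum of positive
  eigenvalues. On Euclidean-embeddable input the coordinates reproduce
  the distances to machine precision.
* **Ward clustering**: Lance–Williams Ward update on squared
  dissimilarities (the hclust `ward.D2` convention, scipy's `ward`),
  stated explicitly because "Ward's method" is ambiguous across
  implementations; a `ward.D`-compatible variant applies the recurrence
  to the dissimilarities as given (implemented as scipy's update on
  √d with squared heights). Dendrograms export to Newick with each
  internal node at half its merge height.
* **Pearson matrices**: r across samples on relative abundances, with
  two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df. Zero-variance taxa
  yield NaN — an undefined correlation is reported as missing, never as
  0. A display ordering by average-linkage clustering of 1−|r| is
  provided for corrplot-style figures.
* **Welch's t**: scipy's unequal-variance t-test with Satterthwaite df.
* **Dunnett's test**: per-comparison t statistics against the control use
  the pooled variance across all groups (df = N − k). Family-wise
  adjusted p is P(max|T| ≥ |tᵢ|) under a multivariate-t null with the
  comparisons' exact correlation ρᵢⱼ = λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)),
  evaluated by Monte Carlo (default 10⁵ draws, seeded, hence
  deterministic). At 10⁵ draws the MC standard error on a p-value near
  0.05 is ≈ 0.0007; tests compare against scipy's quadrature
  implementation at 0.01 tolerance. Tests run on raw relative abundances
  by default; any transformation is the caller's responsibility.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with every stage deterministic given its seed:

* **Communities**: rumen and oral profiles over partitioned taxon sets
  (shared / rumen-only / oral-only), abundances i.i.d. log-normal(0, σ)
  normalised per community. Default σ = 1.5 gives the strongly
  long-tailed rank-abundance shape typical of 16S profiles (top taxon a
  few tens of percent, a long tail under 1%); σ = 0 degenerates to
  uniform.
* **Buccal mixtures**: a buccal sample at contamination ρ draws
  Binomial(depth, ρ) oral-source reads and the rest rumen-source, each
  multinomially within its community — exactly the mixture multinomial,
  with per-source truth retained. The default ρ range (0.05, 0.9)
  matches the span of oral-read proportions observed in real buccal
  swabs; rumen samples have ρ = 0.
* **Templates**: per taxon, a 16S-like sequence
  27F + V1–V2 + 341F + V3–V4 + rc(805R) + V5–V9 + rc(1525R) with random
  variable regions (total ≈ 1,320–1,490 bp) and per-taxon instantiation
  of degenerate primer positions. Random variable regions make unrelated
  templates ~75% divergent — far cleaner separation than real 16S
  references, which matters for interpreting recovery rates (below).
* **Errors**: i.i.d. per base — substitution 2%, insertion 1.5%,
  deletion 1.5% (5% total, the figure usually quoted for nanopore single
  reads; the split weights substitutions slightly over either indel
  class). Insertions add a uniform random base, deletions drop the base.
  Erroneous emitted bases get Phred ~ U{3..12}, correct bases
  U{10..30}, so the realised qualities are consistent with the error
  process and the mean-quality filter sees both outcomes.
* **Scenario defaults**: 15 buccal + 5 rumen samples (a typical
  validation cohort), taxon partition 24 shared / 3 rumen-only /
  15 oral-only — preserving the shared ≫ oral-only > rumen-only shape of
  real paired comparisons at desk scale — and 200 reads/sample by
  default, with tests using smaller cohorts since exact all-pairs
  alignment dominates runtime.
* **Worked-example fixture**: `generate_partitioned_tables` constructs,
  by design, paired tables with exact partition counts (defaults
  155/23/241 with 40 ratio-exceeding shared taxa). Ratio-exceeding taxa
  are given very low rumen counts so that 1.4× ratio-threshold buccal
  targets fit inside one composition; non-exceeding shared taxa sit at
  0.1× the threshold. Both margins are far from the boundary, so ±1%
  count jitter cannot flip a class, and the classifier's output counts
  are seed-invariant.
* **Two-population tables**: a planted Prevotella-dominant vs
  Clostridiales-dominant structure (default 7 + 21 samples, 3-fold
  block up-weighting, Dirichlet concentration 100, depth 10⁴) for
  validating that Euclidean + Ward clustering recovers known community
  types.

**What passing tests show — and don't.** Ground-truth recovery here is
under idealised conditions: i.i.d. errors (no homopolymer bias, no
chimeras), near-orthogonal references, no PCR bias, and an oral
community either disjoint (for recovery tests) or log-normal independent
of the rumen community. Perfect assignment recovery on synthetic data
therefore does not predict species-level accuracy against a real
reference database of closely related sequences; what the tests do
establish is that each algorithmic step computes exactly what it claims
on data whose truth is known.

## Pipeline

`run_pipeline` chains simulate/load → QC → assignment → singleton
removal → species-level table → sample QC → prevalence filter → oral
classification and filtering → Bray–Curtis PCoA and Euclidean/Ward
clustering, writing per-stage artifacts and a `summary.json`. Every JSON
artifact embeds the seed and a hash of the scientific configuration
(paths excluded); TSV artifacts carry them in a leading `#` comment line
(skipped on read); Newick output carries no comment, by format. Stage
failures re-raise as `PipelineError` naming the stage. Reruns with the
same config and seed are byte-identical, which the test suite asserts
file-by-file.

## Known limitations

* Exact all-pairs alignment is O(reads × references × length²); the
  package is not meant for full-database scale (no seeding/banding by
  design).
* The error model has no homopolymer structure, the dominant real
  nanopore failure mode; QC and identity statistics on real data will be
  less favourable.
* The oral filter cannot remove oral-source reads in shared taxa (a
  property of the rule, not the implementation); removed-read fractions
  underestimate ρ whenever the oral community overlaps the rumen
  community.
* Dunnett assumes homoscedastic groups via the pooled variance, as the
  classical test does; strongly unequal variances call for a different
  procedure.
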
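"""End-to-end orchestration: simulate (or load) -> QC -> assign -> table ->
oral filter -> community statistics, with reproducible, seed-stamped
artifacts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import community, io, oralfilter, simulate, tables, taxonomy
from .reads import ReadFilterConfig, filter_reads
from .taxonomy import ScoringScheme


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One config drives every stage; each threshold has the conventional
    default (QC: Q>=9 and 1,300-1,600 bp; alignment costs 1/1/1/1;
    sample QC: >=5,000 assigned reads; observed: >0.1% relative abundance;
    oral rule: >5x max buccal/rumen ratio)."""

    seed: int = 0
    rank: str = "s"
    read_filter: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_score: int = 0
    table_filter: tables.TableFilterConfig = field(default_factory=tables.TableFilterConfig)
    oral: oralfilter.OralFilterConfig = field(default_factory=oralfilter.OralFilterConfig)
    cluster_k: int = 2
    #: kwargs for simulate.simulate_dataset (seed injected); None = load inputs
    simulate: dict | None = field(default_factory=dict)
    #: input paths when simulate is None: fastq (dir), metadata, ref_fasta, ref_taxonomy
    inputs: dict | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("inputs")  # paths are not part of the scientific configuration
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, typ in [
            ("read_filter", ReadFilterConfig),
            ("scoring", ScoringScheme),
            ("table_filter", tables.TableFilterConfig),
            ("oral", oralfilter.OralFilterConfig),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write per-stage artifacts plus ``summary.json``
    into ``out_dir``; returns the summary dict.

    The summary replicates the usual pipeline bookkeeping: total input
    reads, QC tallies, taxa-assigned read counts, per-rank assigned
    fractions, observed-taxa counts, the oral-taxon partition sizes and
    per-sample removed-read fractions.  Reruns with the same config and
    seed produce byte-identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config={cfg.config_hash()} seed={cfg.seed}"
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    # -- stage: data ---------------------------------------------------------
    try:
        if cfg.simulate is not None:
            ds = simulate.simulate_dataset(**cfg.simulate, seed=cfg.seed)
            reads_by_sample = ds.reads
            metadata = ds.metadata
            references = ds.references
            truth: simulate.SyntheticTruth | None = ds.truth
        else:
            if not cfg.inputs:
                raise ValueError("either simulate parameters or input paths required")
            metadata = io.read_sample_metadata(cfg.inputs["metadata"])
            references = io.read_reference(
                cfg.inputs["ref_fasta"], cfg.inputs["ref_taxonomy"]
            )
            fastq_dir = Path(cfg.inputs["fastq"])
            reads_by_sample = {
                m.sample_id: list(io.read_fastq(fastq_dir / f"{m.sample_id}.fastq"))
                for m in metadata
            }
            truth = None
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise PipelineError("data", exc) from exc

    summary["n_samples"] = len(metadata)
    summary["n_input_reads"] = sum(len(r) for r in reads_by_sample.values())
    if truth is not None:
        _write_json(
            {
                "per_sample_contamination": truth.per_sample_contamination,
                "per_read_source": {
                    rid: list(v) for rid, v in sorted(truth.per_read_source.items())
                },
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
            },
            out / "truth.json",
        )
        io.write_sample_metadata(metadata, out / "metadata.tsv")
        io.write_reference(references, out / "references.fasta", out / "references.tax.tsv")
        for sid, rr in sorted(reads_by_sample.items()):
            io.write_fastq(rr, out / f"{sid}.fastq")

    # -- stage: qc -----------------------------------------------------------
    try:
        retained: dict[str, list] = {}
        qc_reports = {}
        for sid in sorted(reads_by_sample):
            kept, rep = filter_reads(reads_by_sample[sid], cfg.read_filter)
            retained[sid] = kept
            qc_reports[sid] = rep.to_dict()
        _write_json(
            {"per_sample": qc_reports, "config_hash": cfg.config_hash(), "seed": cfg.seed},
            out / "qc_report.json",
        )
    except Exception as exc:
        raise PipelineError("qc", exc) from exc
    summary["n_reads_after_qc"] = sum(len(r) for r in retained.values())

    # -- stage: assign -------------------------------------------------------
    try:
        assignments = []
        for sid in sorted(retained):
            assignments.extend(
                taxonomy.assign_reads(retained[sid], references, cfg.scoring, cfg.min_score)
            )
        n_assigned = len(assignments)
        assignments = taxonomy.remove_singletons(assignments)
        adf = pd.DataFrame(
            [
                {
                    "read_id": a.read_id,
                    "sample_id": a.sample_id,
                    "reference_id": a.reference_id,
                    "lineage": a.lineage.to_string(),
                    "score": a.score,
                    "identity": round(a.percent_identity, 6),
                }
                for a in assignments
            ]
        )
        _write_tsv(adf, out / "assignments.tsv", stamp)
    except Exception as exc:
        raise PipelineError("assign", exc) from exc
    summary["n_taxa_assigned_reads"] = n_assigned
    summary["n_reads_after_singleton_removal"] = len(assignments)
    summary["per_rank_assigned_fraction"] = tables.per_rank_assigned_fractions(assignments)
    summary["mean_percent_identity"] = (
        round(float(pd.Series([a.percent_identity for a in assignments]).mean()), 6)
        if assignments
        else None
    )

    # -- stage: table --------------------------------------------------------
    try:
        table = tables.build_table(assignments, metadata, cfg.rank)
        table, excluded = tables.sample_qc(table, cfg.table_filter.min_assigned_reads)
        filt = tables.prevalence_filter(
            table, cfg.table_filter.min_relabund, cfg.table_filter.min_samples
        )
        observed = filt.table.drop_empty_taxa()
        _write_tsv(observed.counts, out / "taxon_table.tsv", stamp, index_label="taxon")
    except Exception as exc:
        raise PipelineError("table", exc) from exc
    summary["samples_excluded_low_reads"] = sorted(excluded)
    summary["n_taxa_observed"] = observed.shape[0]

    # -- stage: oralfilter ---------------------------------------------------
    try:
        types = {m.sample_id: m.sample_type for m in metadata}
        bsamp = [s for s in observed.sample_ids if types[s] is io.SampleType.BUCCAL]
        rsamp = [s for s in observed.sample_ids if types[s] is io.SampleType.RUMEN]
        buccal = observed.subset_samples(bsamp)
        rumen = observed.subset_samples(rsamp)
        report = oralfilter.classify_oral_taxa(buccal, rumen, cfg.oral)
        buccal_f, bfrac = oralfilter.apply_oral_filter(buccal, report)
        rumen_f, rfrac = oralfilter.apply_oral_filter(rumen, report)
        flagged = oralfilter.flag_contaminated_samples(
            bfrac, cfg.oral.contamination_flag_threshold
        )
        rep = report.to_dict()
        rep.update({"config_hash": cfg.config_hash(), "seed": cfg.seed})
        _write_json(rep, out / "oral_filter_report.json")
        _write_tsv(buccal_f.counts, out / "buccal_filtered.tsv", stamp, index_label="taxon")
    except Exception as exc:
        raise PipelineError("oralfilter", exc) from exc
    summary["oral_partition"] = {
        "buccal_only": len(report.buccal_only_taxa),
        "flagged_shared": len(report.flagged_shared_taxa),
        "rumen_only": len(report.rumen_only_taxa),
        "retained_shared": len(report.retained_taxa),
        "putative_oral": len(report.putative_oral_taxa),
    }
    summary["per_sample_removed_fraction"] = {
        s: round(float(f), 6) for s, f in sorted({**bfrac.to_dict(), **rfrac.to_dict()}.items())
    }
    summary["flagged_samples"] = sorted(flagged)

    # -- stage: stats --------------------------------------------------------
    try:
        universe = sorted(set(buccal_f.taxa) | set(rumen_f.taxa))
        combined = tables.TaxonTable(
            pd.concat(
                [
                    buccal_f.counts.reindex(universe, fill_value=0),
                    rumen_f.counts.reindex(universe, fill_value=0),
                ],
                axis=1,
            ),
            rank=cfg.rank,
        )
        nonempty = [s for s in combined.sample_ids if combined.sample_totals()[s] > 0]
        combined = combined.subset_samples(nonempty)
        bc = community.bray_curtis(combined)
        ord_res = community.pcoa(bc)
        _write_tsv(bc.to_frame(), out / "braycurtis.tsv", stamp, index_label="sample")
        _write_tsv(ord_res.to_frame(), out / "pcoa.tsv", stamp, index_label="sample")
        eu = community.euclidean(combined)
        k = min(cfg.cluster_k, len(combined.sample_ids))
        clus = community.ward_cluster(eu, k=k)
        (out / "dendrogram.nwk").write_text(clus.to_newick() + "\n")
    except Exception as exc:
        raise PipelineError("stats", exc) from exc
    summary["cluster_labels"] = {
        s: int(l) for s, l in zip(clus.ids, clus.labels)
    }
    summary["pcoa_proportion_explained"] = [
        round(float(p), 6) for p in ord_res.proportion_explained[:3]
    ]

    _write_json(summary, out / "summary.json")
    return summary
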
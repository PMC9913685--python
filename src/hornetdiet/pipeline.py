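"""End-to-end orchestration: QC → search → classify → profile.

One config (YAML or dict) drives the whole chain and a single seed derives
every module's randomness, so a rerun with the same config and seed
reproduces every artefact byte-for-byte.  A machine-readable stage log
records how many reads enter and leave each stage per sample; read
accounting must balance (reads in = kept + removed per rule) and is
asserted at run time.

Samples in which no reads survive QC are marked failed and the run
continues — partial amplification success is the norm for gut-content
samples, not an error.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import diet_profile, lca_classify, read_qc, reference_search, taxonomy

logger = logging.getLogger("hornetdiet")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Configuration or input problem that prevents the run from starting."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``samples`` maps sample id → {"fastq": path, "nest_id": ..., "platform":
    ...}; ``hit_tables`` (optional) maps sample id → an externally produced
    BLAST outfmt-6 table, used instead of the internal search when
    ``use_external_hits`` is set.
    """

    samples: dict
    refdb: str
    refmap: str
    nodes: str
    outdir: str
    seed: int = 0
    use_external_hits: bool = False
    hit_tables: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    hit_filter: dict = field(default_factory=dict)
    threshold: dict = field(default_factory=dict)
    consolidate_scope: str = "sample"
    relabel: dict = field(default_factory=dict)
    focal_taxon: str | None = None
    host_taxid: str | None = None
    exclude_host_from_most_abundant: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("refdb", "refmap", "nodes"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise PipelineError(f"config path {key} does not exist: {p}")
        if not self.samples:
            raise PipelineError("config lists no samples")
        for sid, meta in self.samples.items():
            if "platform" not in meta:
                raise PipelineError(f"sample {sid!r} has no platform tag")
            if not Path(meta["fastq"]).exists():
                raise PipelineError(
                    f"sample {sid!r} fastq does not exist: {meta['fastq']}"
                )
            if self.use_external_hits and sid not in self.hit_tables:
                raise PipelineError(f"sample {sid!r} has no external hit table")


def _qc_params(cfg: RunConfig) -> read_qc.QCParams:
    return read_qc.QCParams(**cfg.qc)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full chain; returns the stage log (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logging.basicConfig(
        level=logging.INFO, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )

    tax = taxonomy.load_taxonomy(cfg.nodes)
    refmap = taxonomy.load_refmap(cfg.refmap, tax)
    refdb = reference_search.load_fasta(cfg.refdb)
    unknown_refs = set(refdb) - set(refmap)
    if unknown_refs:
        raise PipelineError(f"references missing from refmap: {sorted(unknown_refs)}")

    qc_params = _qc_params(cfg)
    scoring = reference_search.ScoringParams(**cfg.scoring)
    hfp = lca_classify.HitFilterParams(**cfg.hit_filter)
    tp = diet_profile.ThresholdParams(**cfg.threshold)

    stage_log: dict = {"samples": {}, "failed_samples": [], "seed": cfg.seed}
    assignments_by_sample: dict[str, list] = {}
    sample_meta: dict[str, tuple[str, str]] = {}

    for sid, meta in cfg.samples.items():
        logger.info("sample %s: QC", sid)
        platform = meta["platform"]
        sample_meta[sid] = (meta.get("nest_id", "nest?"), platform)
        raw = list(read_qc.read_fastq(meta["fastq"], platform))

        trimmed = []
        n_reject_primer = 0
        for r in raw:
            t = read_qc.trim_primers(r, qc_params)
            if t is None:
                n_reject_primer += 1
            else:
                trimmed.append(t)
        kept, report = read_qc.filter_reads(trimmed, qc_params)
        read_qc.write_fastq(kept, outdir / f"{sid}.trimmed.fastq")
        read_qc.write_qc_report(report, outdir / f"{sid}.qc_report.tsv")

        log = {
            "reads_in": len(raw),
            "primer_rejected": n_reject_primer,
            "after_trim": len(trimmed),
            "too_short": report.removed_too_short,
            "too_long": report.removed_too_long,
            "low_quality": report.removed_low_quality,
            "after_qc": report.n_kept,
        }
        assert log["reads_in"] == log["primer_rejected"] + log["after_trim"]
        assert (
            log["after_trim"]
            == log["after_qc"] + log["too_short"] + log["too_long"] + log["low_quality"]
        )

        if not kept:
            logger.warning("sample %s: no reads survived QC; marked failed", sid)
            stage_log["failed_samples"].append(sid)
            stage_log["samples"][sid] = log
            assignments_by_sample[sid] = []
            continue

        if cfg.use_external_hits:
            hits = reference_search.read_hit_table(cfg.hit_tables[sid])
        else:
            logger.info("sample %s: search (%d reads)", sid, len(kept))
            hits = reference_search.search_reads(kept, refdb, scoring)
            reference_search.write_hit_table(hits, outdir / f"{sid}.hits.tsv")
        log["n_hits"] = len(hits)

        read_lens = {r.read_id: len(r) for r in kept}
        assigned, provenance = lca_classify.classify_sample(
            hits, read_lens, tax, refmap, hfp
        )
        lca_classify.write_assignments(assigned, tax, outdir / f"{sid}.assignments.tsv")
        with open(outdir / f"{sid}.provenance.tsv", "w") as fh:
            fh.write("read_id\tn_hits_in\tn_hits_filtered\tlabel\trank\n")
            for row in provenance:
                fh.write(
                    f"{row['read_id']}\t{row['n_hits_in']}\t"
                    f"{row['n_hits_filtered']}\t{row['label']}\t{row['rank']}\n"
                )
        log["assigned"] = sum(1 for a in assigned if a.resolved)
        log["unresolved"] = sum(1 for a in assigned if not a.resolved)
        assert log["assigned"] + log["unresolved"] == log["after_qc"]
        assignments_by_sample[sid] = assigned
        stage_log["samples"][sid] = log

    matrix = diet_profile.build_matrix(assignments_by_sample, sample_meta)
    diet_profile.write_matrix(matrix, outdir / "matrix_raw.tsv", form="wide")

    thresholded = diet_profile.apply_threshold(matrix, tp)
    consolidated = diet_profile.consolidate_ranks(
        thresholded, tax, scope=cfg.consolidate_scope
    )
    if cfg.relabel:
        consolidated = diet_profile.relabel(consolidated, cfg.relabel)
    diet_profile.write_matrix(consolidated, outdir / "matrix_filtered.tsv", form="wide")
    diet_profile.write_matrix(consolidated, outdir / "matrix_filtered_long.tsv", form="long")

    summaries = diet_profile.nest_summaries(
        consolidated.drop_empty_taxa(),
        tax,
        focal_taxon=cfg.focal_taxon,
        host_taxid=cfg.host_taxid,
        exclude_host_from_most_abundant=cfg.exclude_host_from_most_abundant,
    )
    summaries["nest_summary"].to_csv(outdir / "nest_summary.tsv", sep="\t", index=False)
    summaries["taxon_percent"].to_csv(outdir / "taxon_percent.tsv", sep="\t")
    summaries["sample_richness"].to_csv(outdir / "sample_richness.tsv", sep="\t")
    summaries["incidence"].to_csv(outdir / "incidence.tsv", sep="\t")

    stage_log["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "stage_log.json", "w") as fh:
        json.dump(stage_log, fh, indent=2)
    logger.info("pipeline finished in %.1fs", stage_log["runtime_s"])
    return stage_log
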
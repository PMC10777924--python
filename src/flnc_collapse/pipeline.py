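"""End-to-end orchestration: simulate -> merge -> collapse -> classify ->
events -> quant, with a JSON summary report whose percentages are all
recomputable from the emitted stage files."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import classify as _classify
from . import collapse as _collapse
from . import events as _events
from . import flnc_merge as _merge
from . import io as _io
from . import quant_de as _quant
from . import synthetic_data as _sim
from .models import FLNCRead, ReferenceAnnotation, TranscriptModel
from .report import ratio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds; round-trips through JSON."""

    out_dir: str = "flnc_out"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate=False)
    annotation_gtf: Optional[str] = None
    flnc_bed: Optional[str] = None
    pid_tsv: Optional[str] = None
    counts_tsv: Optional[str] = None
    design_tsv: Optional[str] = None
    short_read_junctions_bed: Optional[str] = None
    # simulation parameters
    n_genes: int = 60
    reads_per_isoform: int = 6
    p_degraded: float = 0.15
    p_novel_isoform: float = 0.05
    p_novel_gene: float = 0.05
    p_fusion: float = 0.02
    p_apa: float = 0.10
    apa_sites_per_gene: int = 2
    n_replicates: int = 4
    frac_de: float = 0.1
    lfc_magnitude: float = 2.0
    count_dispersion: float = 0.1
    baseline_mean: float = 100.0
    # thresholds
    low_pid_threshold: float = _merge.DEFAULT_LOW_PID_THRESHOLD
    overlap_fraction: float = _collapse.DEFAULT_OVERLAP_FRACTION
    junction_wobble: int = 0
    min_isoform_support: int = 2
    apa_window: int = _events.DEFAULT_APA_WINDOW
    apa_min_support: int = 2
    fusion_min_partner_overlap: float = _events.DEFAULT_MIN_PARTNER_OVERLAP
    fusion_min_reads: int = 1
    fusion_min_gap: Optional[int] = _events.DEFAULT_FUSION_MIN_GAP
    full_length_mode: str = "all"
    locus_length_measure: str = "exonic"
    de_lfc_threshold: float = _quant.DE_LFC_THRESHOLD
    de_padj_threshold: float = _quant.DE_PADJ_THRESHOLD
    high_expression_fpkm: float = _quant.HIGH_EXPRESSION_FPKM

    def __post_init__(self) -> None:
        if not 0.0 < self.low_pid_threshold < 100.0:
            raise ValueError("low_pid_threshold must be in (0, 100)")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in (0, 1)")
        if self.junction_wobble < 0:
            raise ValueError("junction_wobble must be >= 0")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_inputs(
    cfg: PipelineConfig,
) -> Tuple[ReferenceAnnotation, List[FLNCRead], pd.DataFrame, Dict[str, str]]:
    out = cfg.out_dir
    if cfg.simulate:
        ann = _sim.simulate_annotation(n_genes=cfg.n_genes, seed=cfg.seed)
        reads = _sim.simulate_flnc(
            ann,
            reads_per_isoform=cfg.reads_per_isoform,
            p_degraded=cfg.p_degraded,
            p_novel_isoform=cfg.p_novel_isoform,
            p_novel_gene=cfg.p_novel_gene,
            p_fusion=cfg.p_fusion,
            p_apa=cfg.p_apa,
            apa_sites_per_gene=cfg.apa_sites_per_gene,
            seed=cfg.seed + 1,
        )
        design = _sim.default_design(cfg.n_replicates)
        sim_counts = _sim.simulate_counts(
            ann,
            design,
            baseline_mean=cfg.baseline_mean,
            dispersion=cfg.count_dispersion,
            frac_de=cfg.frac_de,
            lfc_magnitude=cfg.lfc_magnitude,
            seed=cfg.seed + 2,
        )
        counts = sim_counts.counts
        _io.write_gtf(ann, os.path.join(out, "annotation.gtf"))
        _io.write_bed12(reads, os.path.join(out, "flnc.bed"))
        _io.write_pid_tsv(reads, os.path.join(out, "pid.tsv"))
        _io.write_truth_tsv(reads, os.path.join(out, "truth.tsv"))
        _io.write_counts_tsv(counts, os.path.join(out, "counts.tsv"))
        _io.write_design_tsv(design, os.path.join(out, "design.tsv"))
        return ann, reads, counts, design
    for name in ("annotation_gtf", "flnc_bed", "counts_tsv", "design_tsv"):
        path = getattr(cfg, name)
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"required input {name} missing: {path}")
    ann = _io.read_gtf(cfg.annotation_gtf)
    pid = _io.read_pid_tsv(cfg.pid_tsv) if cfg.pid_tsv else None
    reads = _io.reads_from_bed12(cfg.flnc_bed, pid=pid)
    counts = _io.read_counts_tsv(cfg.counts_tsv)
    design = _io.read_design_tsv(cfg.design_tsv)
    missing = set(counts.columns) - set(design)
    if missing:
        raise ValueError(f"design does not cover samples: {sorted(missing)}")
    return ann, reads, counts, design


def _assign_read_gene(
    read: FLNCRead, ann: ReferenceAnnotation, overlap_fraction: float
) -> Optional[str]:
    """Best same-strand span-overlap gene for a non-chimeric read."""
    b = read.blocks[0]
    best, best_frac = None, 0.0
    for g in ann.genes:
        if g.chrom != b.chrom or g.strand != b.strand:
            continue
        ov = max(0, min(b.end, g.end) - max(b.start, g.start))
        shorter = min(b.end - b.start, g.end - g.start)
        frac = ov / shorter if shorter else 0.0
        if frac >= overlap_fraction and frac > best_frac:
            best, best_frac = g.id, frac
    return best


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run every stage and return the summary report (also written to disk)."""
    _io.ensure_dir(cfg.out_dir)
    cfg.to_json(os.path.join(cfg.out_dir, "config.json"))
    ann, reads, counts, design = _load_inputs(cfg)
    report: Dict[str, object] = {"seed": cfg.seed}

    # ---- merge stage
    merged, pid_report = _merge.merge_libraries(reads)
    mapping_report = _merge.classify_mapping(
        merged,
        low_pid_threshold=cfg.low_pid_threshold,
        n_unmapped=pid_report.n_excluded,
    )
    pid_report.to_frame().to_csv(
        os.path.join(cfg.out_dir, "pid_comparison.tsv"), sep="\t", index=False
    )
    mapping_report.to_frame().to_csv(
        os.path.join(cfg.out_dir, "mapping_report.tsv"), sep="\t", index=False
    )
    report["pid_categories"] = dict(pid_report.counts)
    report["pid_total"] = pid_report.total
    report["pid_improved_percent"] = (
        ratio(pid_report.counts["pre_lt_post"], pid_report.total)
        if pid_report.total
        else 0.0
    )
    report["mapping_classes"] = dict(mapping_report.counts)
    report["mapping_denominator"] = mapping_report.denominator
    report["high_quality_percent"] = (
        ratio(mapping_report.counts["high_quality"], mapping_report.denominator)
        if mapping_report.denominator
        else 0.0
    )
    report["low_pid_percent"] = (
        ratio(mapping_report.counts["low_pid"], mapping_report.denominator)
        if mapping_report.denominator
        else 0.0
    )

    # ---- collapse stage
    linear = [r for r in reads if not r.is_chimeric]
    transcripts = [r.to_transcript() for r in linear]
    annotated_junctions = _collapse.annotated_junction_set(ann)
    short_read_junctions = frozenset()
    if cfg.short_read_junctions_bed:
        short_read_junctions = frozenset(
            (b.chrom, b.strand, s, e)
            for _, b in _io.read_bed12(cfg.short_read_junctions_bed)
            for s, e in [(b.start, b.end)]
        )
    loci, calls = _collapse.collapse_reads(
        transcripts,
        annotated_junctions=annotated_junctions,
        short_read_junctions=short_read_junctions,
        overlap_fraction=cfg.overlap_fraction,
        wobble=cfg.junction_wobble,
        min_support=cfg.min_isoform_support,
    )
    retained = [c for c in calls if c.retained]
    report["n_loci"] = len(loci)
    report["n_isoforms_retained"] = len(retained)
    report["n_isoforms_redundant"] = sum(1 for c in calls if c.redundant)
    report["n_isoforms_false_positive"] = sum(1 for c in calls if c.false_positive)

    # ---- classify stage
    classified = _classify.classify_isoforms(
        retained,
        loci,
        ann,
        full_length_mode=cfg.full_length_mode,
        overlap_fraction=cfg.overlap_fraction,
    )
    _classify.classification_frame(classified).to_csv(
        os.path.join(cfg.out_dir, "isoform_classification.tsv"), sep="\t", index=False
    )
    multi_exon = [c for c in classified if c.full_length is not None]
    n_fl = sum(1 for c in multi_exon if c.full_length)
    report["n_multi_exon_isoforms"] = len(multi_exon)
    report["n_full_length_isoforms"] = n_fl
    report["full_length_isoform_percent"] = (
        ratio(n_fl, len(multi_exon)) if multi_exon else 0.0
    )
    index = _classify._RefIndex(ann)
    multi_exon_reads = [t for t in transcripts if t.n_exons >= 2]
    n_fl_reads = sum(
        1
        for t in multi_exon_reads
        if _classify.full_length_status(t, ann, cfg.full_length_mode, _index=index)
    )
    report["n_multi_exon_reads"] = len(multi_exon_reads)
    report["n_full_length_reads"] = n_fl_reads
    report["full_length_read_percent"] = (
        ratio(n_fl_reads, len(multi_exon_reads)) if multi_exon_reads else 0.0
    )
    report["novelty"] = {
        label: sum(1 for c in classified if c.novelty == label)
        for label in ("known", "novel_isoform", "novel_gene")
    }
    report["categories"] = {
        cat: sum(1 for c in classified if c.category == cat)
        for cat in _classify.CATEGORIES
    }
    lengths = _classify.locus_lengths(retained, measure=cfg.locus_length_measure)
    bins = _classify.length_bin_report(lengths)
    bins.to_csv(os.path.join(cfg.out_dir, "length_bins.tsv"), sep="\t", index=False)
    ref_lengths = _classify.locus_lengths(
        [
            _collapse.IsoformCall(
                id=iso.id,
                locus_id=g.id,
                chrom=g.chrom,
                strand=g.strand,
                exons=iso.exons,
                flnc_support=1,
            )
            for g in ann.genes
            for iso in g.isoforms
        ],
        measure=cfg.locus_length_measure,
    )
    report["length_bins"] = {
        row["bin"]: {"count": int(row["count"]), "percent": row["percent"]}
        for _, row in bins.iterrows()
    }
    report["reference_length_bins"] = {
        row["bin"]: {"count": int(row["count"]), "percent": row["percent"]}
        for _, row in _classify.length_bin_report(ref_lengths).iterrows()
    }

    # ---- events stage
    as_events: List[_events.ASEvent] = []
    retained_by_locus: Dict[str, List] = {}
    for c in retained:
        retained_by_locus.setdefault(c.locus_id, []).append(c)
    for locus_id, isoforms in sorted(retained_by_locus.items()):
        if len(isoforms) >= 2:
            as_events.extend(_events.detect_as_events(isoforms, locus_id))
    pd.DataFrame(
        [
            {
                "type": e.type,
                "locus_id": e.locus_id,
                "isoform_a": e.isoform_a,
                "isoform_b": e.isoform_b,
                "region": ",".join(map(str, e.region)),
            }
            for e in as_events
        ],
        columns=["type", "locus_id", "isoform_a", "isoform_b", "region"],
    ).to_csv(os.path.join(cfg.out_dir, "as_events.tsv"), sep="\t", index=False)
    summary = _events.as_summary(as_events)
    summary.to_csv(os.path.join(cfg.out_dir, "as_summary.tsv"), sep="\t", index=False)
    report["as_events_total"] = len(as_events)
    report["as_types"] = {
        row["type"]: {"count": int(row["count"]), "percent": row["percent"]}
        for _, row in summary.iterrows()
    }

    reads_by_gene: Dict[str, List[FLNCRead]] = {}
    for r in linear:
        gid = _assign_read_gene(r, ann, cfg.overlap_fraction)
        if gid is not None:
            reads_by_gene.setdefault(gid, []).append(r)
    apa_rows = []
    n_apa_genes = 0
    n_gt5 = 0
    for gid in sorted(reads_by_gene):
        clusters = _events.detect_apa(
            gid,
            _events.reads_three_prime_ends(reads_by_gene[gid]),
            cluster_window=cfg.apa_window,
            min_support=cfg.apa_min_support,
        )
        if _events.gene_has_apa(clusters):
            n_apa_genes += 1
            if len(clusters) > 5:
                n_gt5 += 1
        for cl in clusters:
            apa_rows.append(
                {"gene": cl.gene_id, "site": cl.site, "support": cl.support}
            )
    pd.DataFrame(apa_rows, columns=["gene", "site", "support"]).to_csv(
        os.path.join(cfg.out_dir, "apa_sites.tsv"), sep="\t", index=False
    )
    report["apa_genes"] = n_apa_genes
    report["apa_genes_gt5_sites"] = n_gt5

    fusions = _events.detect_fusion(
        reads,
        ann,
        min_partner_overlap=cfg.fusion_min_partner_overlap,
        min_reads=cfg.fusion_min_reads,
        min_gap=cfg.fusion_min_gap,
    )
    pd.DataFrame(
        [
            {
                "partner_5prime": f.partner_5prime,
                "partner_3prime": f.partner_3prime,
                "kind": f.kind,
                "n_reads": len(f.read_ids),
            }
            for f in fusions
        ],
        columns=["partner_5prime", "partner_3prime", "kind", "n_reads"],
    ).to_csv(os.path.join(cfg.out_dir, "fusions.tsv"), sep="\t", index=False)
    report["fusions"] = {
        "total": len(fusions),
        "intrachromosomal": sum(1 for f in fusions if f.kind == "intrachromosomal"),
        "interchromosomal": sum(1 for f in fusions if f.kind == "interchromosomal"),
    }

    # ---- quant stage
    tx_lengths = _quant.transcript_lengths(ann).reindex(counts.index)
    tx_lengths = tx_lengths.fillna(1_000.0)  # unannotated rows get a nominal length
    fpkm_tx = _quant.fpkm(counts, tx_lengths)
    fpkm_tx.to_csv(os.path.join(cfg.out_dir, "fpkm.tsv"), sep="\t", index_label="feature_id")
    classes = _quant.expression_classes(
        fpkm_tx, design, high_threshold=cfg.high_expression_fpkm
    )
    pd.DataFrame(
        [
            {"set": k, "n": len(v) if isinstance(v, set) else v}
            for k, v in list(classes["venn"].items())
        ],
        columns=["set", "n"],
    ).to_csv(os.path.join(cfg.out_dir, "expression_classes.tsv"), sep="\t", index=False)
    report["venn"] = classes["venn"]
    report["highly_expressed_per_sample"] = {
        s: len(v) for s, v in classes["highly_expressed"].items()
    }

    gene_counts, gene_lengths = _quant.gene_level_counts(counts, ann)
    tissues = sorted(set(design.values()))
    de_summary: Dict[str, Dict[str, int]] = {}
    for i in range(len(tissues)):
        for j in range(i + 1, len(tissues)):
            pair = (tissues[i], tissues[j])
            name = f"{pair[0]}_vs_{pair[1]}"
            dei = _quant.nb_test(
                counts,
                design,
                pair,
                lfc_threshold=cfg.de_lfc_threshold,
                padj_threshold=cfg.de_padj_threshold,
            )
            deg = _quant.nb_test(
                gene_counts,
                design,
                pair,
                lfc_threshold=cfg.de_lfc_threshold,
                padj_threshold=cfg.de_padj_threshold,
            )
            dei.to_csv(
                os.path.join(cfg.out_dir, f"de_isoform_{name}.tsv"),
                sep="\t",
                index_label="feature_id",
            )
            deg.to_csv(
                os.path.join(cfg.out_dir, f"de_gene_{name}.tsv"),
                sep="\t",
                index_label="feature_id",
            )
            de_summary[name] = {
                "DEG": int(deg["is_de"].sum()),
                "DEI": int(dei["is_de"].sum()),
            }
    report["de"] = de_summary

    logger.info(
        "thresholds: low_pid=%s overlap=%s wobble=%s apa_window=%s de_lfc=%s de_padj=%s",
        cfg.low_pid_threshold,
        cfg.overlap_fraction,
        cfg.junction_wobble,
        cfg.apa_window,
        cfg.de_lfc_threshold,
        cfg.de_padj_threshold,
    )
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
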
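"""Readers and writers for the plain-text formats used by the pipeline.

GTF records are emitted 1-based inclusive; BED12 keeps the 0-based half-open
convention.  Both round-trip losslessly against the in-memory models.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .models import (
    AlignmentBlock,
    FLNCRead,
    GeneModel,
    ReferenceAnnotation,
    TranscriptModel,
    TruthLabel,
)

# ---------------------------------------------------------------------------
# GTF


def write_gtf(ann: ReferenceAnnotation, path: str) -> None:
    lines: List[str] = []
    for gene in ann.genes:
        attrs = f'gene_id "{gene.id}";'
        lines.append(
            "\t".join(
                [
                    gene.chrom,
                    "flnc_collapse",
                    "gene",
                    str(gene.start + 1),
                    str(gene.end),
                    ".",
                    gene.strand,
                    ".",
                    attrs,
                ]
            )
        )
        for iso in gene.isoforms:
            tattrs = f'gene_id "{gene.id}"; transcript_id "{iso.id}";'
            lines.append(
                "\t".join(
                    [
                        iso.chrom,
                        "flnc_collapse",
                        "transcript",
                        str(iso.start + 1),
                        str(iso.end),
                        ".",
                        iso.strand,
                        ".",
                        tattrs,
                    ]
                )
            )
            for start, end in iso.exons:
                lines.append(
                    "\t".join(
                        [
                            iso.chrom,
                            "flnc_collapse",
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            iso.strand,
                            ".",
                            tattrs,
                        ]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _parse_gtf_attrs(field: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str) -> ReferenceAnnotation:
    gene_meta: Dict[str, Tuple[str, str]] = {}
    gene_order: List[str] = []
    tx_exons: Dict[str, List[Tuple[int, int]]] = {}
    tx_meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    tx_order: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.split("\t")
            a = _parse_gtf_attrs(attrs)
            if feature == "gene":
                gid = a["gene_id"]
                gene_meta[gid] = (chrom, strand)
                gene_order.append(gid)
            elif feature == "transcript":
                tid = a["transcript_id"]
                tx_meta[tid] = (a["gene_id"], chrom, strand)
                tx_order.append(tid)
                tx_exons.setdefault(tid, [])
            elif feature == "exon":
                tid = a["transcript_id"]
                if tid not in tx_meta:
                    tx_meta[tid] = (a["gene_id"], chrom, strand)
                    tx_order.append(tid)
                tx_exons.setdefault(tid, []).append((int(start) - 1, int(end)))
    genes: Dict[str, List[TranscriptModel]] = {g: [] for g in gene_order}
    for tid in tx_order:
        gid, chrom, strand = tx_meta[tid]
        exons = sorted(tx_exons[tid])
        genes.setdefault(gid, []).append(
            TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=tuple(exons))
        )
        if gid not in gene_meta:
            gene_meta[gid] = (chrom, strand)
            gene_order.append(gid)
    return ReferenceAnnotation(
        genes=tuple(
            GeneModel(
                id=gid,
                chrom=gene_meta[gid][0],
                strand=gene_meta[gid][1],
                isoforms=tuple(genes[gid]),
            )
            for gid in gene_order
        )
    )


# ---------------------------------------------------------------------------
# BED12


def _block_to_bed_fields(name: str, block: AlignmentBlock) -> str:
    start = block.start
    end = block.end
    sizes = ",".join(str(e - s) for s, e in block.exons)
    starts = ",".join(str(s - start) for s, _ in block.exons)
    return "\t".join(
        [
            block.chrom,
            str(start),
            str(end),
            name,
            "0",
            block.strand,
            str(start),
            str(end),
            "0,0,0",
            str(len(block.exons)),
            sizes + ",",
            starts + ",",
        ]
    )


def write_bed12(reads: Sequence[FLNCRead], path: str) -> None:
    """One BED12 line per alignment block; fusion halves get /1 and /2 suffixes."""
    lines: List[str] = []
    for read in reads:
        if read.is_chimeric:
            for i, block in enumerate(read.blocks, start=1):
                lines.append(_block_to_bed_fields(f"{read.id}/{i}", block))
        else:
            lines.append(_block_to_bed_fields(read.id, read.blocks[0]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _bed_line_to_block(line: str) -> Tuple[str, AlignmentBlock]:
    fields = line.split("\t")
    chrom = fields[0]
    start = int(fields[1])
    name = fields[3]
    strand = fields[5]
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
    return name, AlignmentBlock(chrom=chrom, strand=strand, exons=exons)


def read_bed12(path: str) -> List[Tuple[str, AlignmentBlock]]:
    """Return (name, block) pairs in file order; names keep any /1 /2 suffix."""
    out: List[Tuple[str, AlignmentBlock]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(_bed_line_to_block(line))
    return out


def reads_from_bed12(
    path: str,
    pid: Optional[pd.DataFrame] = None,
    truth: Optional[pd.DataFrame] = None,
) -> List[FLNCRead]:
    """Reassemble FLNCRead objects from a BED12 file plus optional side tables."""
    blocks: Dict[str, List[Tuple[int, AlignmentBlock]]] = {}
    order: List[str] = []
    for name, block in read_bed12(path):
        base, _, suffix = name.partition("/")
        idx = int(suffix) if suffix else 1
        if base not in blocks:
            order.append(base)
        blocks.setdefault(base, []).append((idx, block))
    pid_map: Dict[str, Tuple[Optional[float], Optional[float]]] = {}
    if pid is not None:
        for row in pid.itertuples():
            pre = None if pd.isna(row.pid_pre) else float(row.pid_pre)
            post = None if pd.isna(row.pid_post) else float(row.pid_post)
            pid_map[row.read_id] = (pre, post)
    truth_map: Dict[str, TruthLabel] = {}
    if truth is not None:
        for row in truth.itertuples():
            truth_map[row.read_id] = TruthLabel(
                phenomenon=row.phenomenon,
                source_transcript=None
                if pd.isna(row.source_transcript)
                else str(row.source_transcript),
                apa_site=None if pd.isna(row.apa_site) else int(row.apa_site),
            )
    reads: List[FLNCRead] = []
    for base in order:
        parts = tuple(b for _, b in sorted(blocks[base]))
        pre, post = pid_map.get(base, (None, None))
        reads.append(
            FLNCRead(
                id=base,
                blocks=parts,
                pid_pre=pre,
                pid_post=post,
                truth=truth_map.get(base),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# TSV side tables


def write_pid_tsv(reads: Sequence[FLNCRead], path: str) -> None:
    rows = [
        {"read_id": r.id, "pid_pre": r.pid_pre, "pid_post": r.pid_post} for r in reads
    ]
    pd.DataFrame(rows, columns=["read_id", "pid_pre", "pid_post"]).to_csv(
        path, sep="\t", index=False
    )


def read_pid_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(reads: Sequence[FLNCRead], path: str) -> None:
    rows = []
    for r in reads:
        t = r.truth
        rows.append(
            {
                "read_id": r.id,
                "phenomenon": t.phenomenon if t else "",
                "source_transcript": t.source_transcript if t else None,
                "apa_site": t.apa_site if t else None,
            }
        )
    pd.DataFrame(
        rows, columns=["read_id", "phenomenon", "source_transcript", "apa_site"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_design_tsv(design: Mapping[str, str], path: str) -> None:
    pd.DataFrame(
        {"sample": list(design.keys()), "tissue": list(design.values())}
    ).to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["tissue"]))


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
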
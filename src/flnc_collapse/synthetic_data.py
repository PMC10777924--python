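"""Synthetic reference annotations, FLNC read sets, and count matrices.

Every generator is deterministic for a fixed seed (sub-generators are spawned
from a single :class:`numpy.random.SeedSequence`), and every read carries a
:class:`~flnc_collapse.models.TruthLabel` so downstream stages can be scored
against planted ground truth.  No nucleotide sequences are produced — the
pipeline operates purely on coordinates and PID summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    AlignmentBlock,
    FLNCRead,
    GeneModel,
    ReferenceAnnotation,
    TranscriptModel,
    TruthLabel,
)

GENES_PER_CHROM = 25
MIN_READ_LENGTH = 50  # 5'-degradation never removes the last 50 exonic bases
APA_SITE_SPACING = 200  # planted alternative poly(A) sites, bp apart


@dataclass(frozen=True)
class PidModel:
    """Truncated-normal model for pre-/post-correction percent identity."""

    mean_pre: float = 98.5
    mean_post: float = 99.2
    sd: float = 0.8
    frac_unchanged: float = 0.45
    frac_unmapped_pre: float = 0.002
    frac_unmapped_post: float = 0.001


@dataclass
class SimulatedCounts:
    counts: pd.DataFrame  # transcripts x samples, integer
    design: Dict[str, str]  # sample -> tissue
    truth_lfc: pd.DataFrame  # transcripts x tissue pairs ("A_vs_B" = log2 B/A)
    dispersion: pd.Series  # per-transcript alpha


def _rng_children(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Annotation


def _gene_isoforms(
    gene_id: str,
    chrom: str,
    strand: str,
    template: Tuple[Tuple[int, int], ...],
    n_iso: int,
    rng: np.random.Generator,
) -> Tuple[TranscriptModel, ...]:
    """Derive n_iso distinct isoforms from a gene's exon template.

    The first isoform is the full template; further isoforms skip one internal
    exon each, then fall back to sliding a donor site into its intron.
    """
    chains: List[Tuple[Tuple[int, int], ...]] = [template]
    internal = list(range(1, len(template) - 1))
    rng.shuffle(internal)
    for idx in internal:
        if len(chains) >= n_iso:
            break
        chains.append(template[:idx] + template[idx + 1 :])
    shift = 6
    j = 0
    while len(chains) < n_iso and len(template) >= 2:
        left = template[j % (len(template) - 1)]
        right = template[j % (len(template) - 1) + 1]
        intron_len = right[0] - left[1]
        if shift < intron_len - 3:
            variant = list(template)
            variant[j % (len(template) - 1)] = (left[0], left[1] + shift)
            chains.append(tuple(variant))
        j += 1
        shift += 6
        if shift > 60:  # give up gracefully on tiny genes
            break
    return tuple(
        TranscriptModel(id=f"{gene_id}.t{i + 1}", chrom=chrom, strand=strand, exons=chain)
        for i, chain in enumerate(chains[:n_iso])
    )


def simulate_annotation(
    n_genes: int,
    exons_per_isoform: Tuple[int, int] = (2, 8),
    isoforms_per_gene: Tuple[int, int] = (1, 3),
    seed: int = 0,
    antisense_fraction: float = 0.0,
) -> ReferenceAnnotation:
    """Generate a toy annotation with non-overlapping genes on a few chromosomes.

    ``antisense_fraction`` of genes are instead placed overlapping the previous
    gene on the opposite strand.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if exons_per_isoform[0] > exons_per_isoform[1] or exons_per_isoform[0] < 1:
        raise ValueError("exons_per_isoform range is empty or invalid")
    if isoforms_per_gene[0] > isoforms_per_gene[1] or isoforms_per_gene[0] < 1:
        raise ValueError("isoforms_per_gene range is empty or invalid")
    rng = np.random.default_rng(seed)
    genes: List[GeneModel] = []
    cursor = 10_000
    prev: Optional[GeneModel] = None
    for g in range(n_genes):
        chrom = f"chr{g // GENES_PER_CHROM + 1}"
        if g % GENES_PER_CHROM == 0:
            cursor = 10_000
            prev = None
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(exons_per_isoform[0], exons_per_isoform[1] + 1))
        antisense = (
            prev is not None
            and antisense_fraction > 0
            and rng.random() < antisense_fraction
        )
        if antisense:
            start = prev.start + int(rng.integers(0, max(1, (prev.end - prev.start) // 2)))
            strand = "-" if prev.strand == "+" else "+"
        else:
            start = cursor + int(rng.integers(20_000, 50_000))
        exons: List[Tuple[int, int]] = []
        pos = start
        for e in range(n_ex):
            length = int(rng.integers(120, 400))
            exons.append((pos, pos + length))
            pos += length
            if e < n_ex - 1:
                pos += int(rng.integers(300, 2_000))
        gene_id = f"gene{g + 1:04d}"
        n_iso = int(rng.integers(isoforms_per_gene[0], isoforms_per_gene[1] + 1))
        isoforms = _gene_isoforms(gene_id, chrom, strand, tuple(exons), n_iso, rng)
        gene = GeneModel(id=gene_id, chrom=chrom, strand=strand, isoforms=isoforms)
        genes.append(gene)
        if not antisense:
            cursor = gene.end
            prev = gene
    return ReferenceAnnotation(genes=tuple(genes))


# ---------------------------------------------------------------------------
# FLNC reads


def _truncate_5prime(iso: TranscriptModel, rng: np.random.Generator) -> Tuple[Tuple[int, int], ...]:
    """Remove a random 5' portion of the exonic sequence (strand-aware)."""
    total = iso.exonic_length
    max_cut = total - MIN_READ_LENGTH
    if max_cut < 1:
        return iso.exons
    cut = int(rng.integers(1, max_cut + 1))
    tx_order = list(iso.exons) if iso.strand == "+" else list(reversed(iso.exons))
    out: List[Tuple[int, int]] = []
    remaining = cut
    trimmed = False
    for s, e in tx_order:
        if not trimmed:
            length = e - s
            if remaining >= length:
                remaining -= length
                continue
            if iso.strand == "+":
                out.append((s + remaining, e))
            else:
                out.append((s, e - remaining))
            trimmed = True
        else:
            out.append((s, e))
    return tuple(sorted(out))


def _novel_isoform_exons(
    iso: TranscriptModel, forbidden: frozenset, rng: np.random.Generator
) -> Optional[Tuple[Tuple[int, int], ...]]:
    """Shift one splice site into its intron, avoiding annotated coordinates."""
    if iso.n_exons < 2:
        return None
    order = list(range(iso.n_exons - 1))
    rng.shuffle(order)
    for j in order:
        left = iso.exons[j]
        right = iso.exons[j + 1]
        intron_len = right[0] - left[1]
        for delta in rng.permutation(np.arange(5, min(40, intron_len - 2))):
            side = rng.random() < 0.5
            if side:
                cand = left[1] + int(delta)
                if cand not in forbidden and cand < right[0] - 1:
                    exons = list(iso.exons)
                    exons[j] = (left[0], cand)
                    return tuple(exons)
            else:
                cand = right[0] - int(delta)
                if cand not in forbidden and cand > left[1] + 1:
                    exons = list(iso.exons)
                    exons[j + 1] = (cand, right[1])
                    return tuple(exons)
    return None


def _intergenic_gaps(ann: ReferenceAnnotation, margin: int = 2_000) -> List[Tuple[str, int, int]]:
    gaps: List[Tuple[str, int, int]] = []
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        prev_end = 1_000
        for g in gs:
            if g.start - prev_end > 2 * margin + 1_000:
                gaps.append((chrom, prev_end + margin, g.start - margin))
            prev_end = max(prev_end, g.end)
        gaps.append((chrom, prev_end + margin, prev_end + margin + 50_000))
    return gaps


def _plant_novel_genes(
    ann: ReferenceAnnotation, n: int, rng: np.random.Generator
) -> List[TranscriptModel]:
    gaps = _intergenic_gaps(ann)
    out: List[TranscriptModel] = []
    for k in range(n):
        chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
        width = hi - lo
        e1 = int(rng.integers(150, 300))
        intron = int(rng.integers(400, 1_200))
        e2 = int(rng.integers(150, 300))
        need = e1 + intron + e2
        if width <= need + 10:
            start = lo
        else:
            start = lo + int(rng.integers(0, width - need))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(
            TranscriptModel(
                id=f"novelgene{k + 1:03d}.t1",
                chrom=chrom,
                strand=strand,
                exons=((start, start + e1), (start + e1 + intron, start + e1 + intron + e2)),
            )
        )
    return out


def _fusion_blocks(
    gene_a: GeneModel, gene_b: GeneModel
) -> Tuple[AlignmentBlock, AlignmentBlock]:
    iso_a = gene_a.isoforms[0]
    iso_b = gene_b.isoforms[0]
    ha = max(1, iso_a.n_exons // 2)
    hb = max(1, iso_b.n_exons // 2)
    exons_a = iso_a.exons[:ha] if gene_a.strand == "+" else iso_a.exons[-ha:]
    exons_b = iso_b.exons[-hb:] if gene_b.strand == "+" else iso_b.exons[:hb]
    return (
        AlignmentBlock(chrom=gene_a.chrom, strand=gene_a.strand, exons=exons_a),
        AlignmentBlock(chrom=gene_b.chrom, strand=gene_b.strand, exons=exons_b),
    )


def planted_apa_sites(gene: GeneModel, apa_sites_per_gene: int) -> List[int]:
    """Planted poly(A) sites for a gene: the annotated 3'-most end plus
    ``apa_sites_per_gene - 1`` sites spaced downstream of it."""
    if gene.strand == "+":
        base = gene.end
        extra = [base + APA_SITE_SPACING * k for k in range(1, apa_sites_per_gene)]
    else:
        base = gene.start
        extra = [max(1, base - APA_SITE_SPACING * k) for k in range(1, apa_sites_per_gene)]
    return [base] + extra


def _apa_shift(iso: TranscriptModel, site: int) -> Tuple[Tuple[int, int], ...]:
    exons = list(iso.exons)
    if iso.strand == "+":
        s, _ = exons[-1]
        exons[-1] = (s, max(site, s + 1))
    else:
        _, e = exons[0]
        exons[0] = (min(site, e - 1), e)
    return tuple(exons)


def simulate_flnc(
    ann: ReferenceAnnotation,
    reads_per_isoform: int,
    p_degraded: float = 0.0,
    p_novel_isoform: float = 0.0,
    p_novel_gene: float = 0.0,
    p_fusion: float = 0.0,
    p_apa: float = 0.0,
    apa_sites_per_gene: int = 1,
    pid_model: PidModel = PidModel(),
    seed: int = 0,
) -> List[FLNCRead]:
    """Simulate aligned FLNC reads with planted phenomena.

    Each read draws exactly one phenomenon; the remainder probability yields a
    clean full-length copy of its source isoform.  Novel-gene and fusion reads
    are drawn from small planted pools so that repeated reads support the same
    planted event.
    """
    probs = {
        "degraded_5prime": p_degraded,
        "novel_isoform": p_novel_isoform,
        "novel_gene": p_novel_gene,
        "fusion": p_fusion,
        "apa_shifted": p_apa,
    }
    for name, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} probability {p} outside [0, 1]")
    if sum(probs.values()) > 1.0 + 1e-12:
        raise ValueError("phenomenon probabilities must sum to <= 1")
    if reads_per_isoform > 0 and len(ann) == 0:
        raise ValueError("cannot simulate reads from an empty annotation")
    if reads_per_isoform < 0:
        raise ValueError("reads_per_isoform must be >= 0")
    if apa_sites_per_gene < 1:
        raise ValueError("apa_sites_per_gene must be >= 1")

    rng_struct, rng_pheno, rng_pid = _rng_children(seed, 3)

    annotated_sites = frozenset(
        c for iso in ann.transcripts for j in iso.junctions for c in j
    )
    n_novel_pool = max(1, round(p_novel_gene * len(ann.genes))) if p_novel_gene > 0 else 0
    novel_pool = _plant_novel_genes(ann, n_novel_pool, rng_struct)
    n_fusion_pool = max(1, round(p_fusion * len(ann.genes))) if p_fusion > 0 else 0
    fusion_pool: List[Tuple[GeneModel, GeneModel]] = []
    if n_fusion_pool and len(ann.genes) >= 2:
        for _ in range(n_fusion_pool):
            ia, ib = rng_struct.choice(len(ann.genes), size=2, replace=False)
            fusion_pool.append((ann.genes[int(ia)], ann.genes[int(ib)]))

    names = list(probs)
    pvec = np.array([probs[n] for n in names])
    p_full = 1.0 - pvec.sum()

    reads: List[FLNCRead] = []
    apa_cache: Dict[str, List[int]] = {}
    counter = 0
    for gene in ann.genes:
        for iso in gene.isoforms:
            for _ in range(reads_per_isoform):
                counter += 1
                rid = f"read{counter:06d}"
                u = rng_pheno.random()
                acc = p_full
                phenomenon = "full_length"
                for name, p in zip(names, pvec):
                    if u < acc:
                        break
                    acc += p
                    phenomenon = name
                truth_kwargs: Dict[str, object] = {"source_transcript": iso.id}
                blocks: Tuple[AlignmentBlock, ...]
                if phenomenon == "degraded_5prime":
                    exons = _truncate_5prime(iso, rng_pheno)
                    if exons == iso.exons:
                        phenomenon = "full_length"
                    blocks = (
                        AlignmentBlock(chrom=iso.chrom, strand=iso.strand, exons=exons),
                    )
                elif phenomenon == "novel_isoform":
                    exons = _novel_isoform_exons(iso, annotated_sites, rng_pheno)
                    if exons is None:
                        phenomenon = "full_length"
                        exons = iso.exons
                    blocks = (
                        AlignmentBlock(chrom=iso.chrom, strand=iso.strand, exons=exons),
                    )
                elif phenomenon == "novel_gene":
                    tpl = novel_pool[int(rng_pheno.integers(0, len(novel_pool)))]
                    truth_kwargs["source_transcript"] = tpl.id
                    blocks = (
                        AlignmentBlock(chrom=tpl.chrom, strand=tpl.strand, exons=tpl.exons),
                    )
                elif phenomenon == "fusion":
                    ga, gb = fusion_pool[int(rng_pheno.integers(0, len(fusion_pool)))]
                    truth_kwargs["source_transcript"] = f"{ga.id}--{gb.id}"
                    blocks = _fusion_blocks(ga, gb)
                elif phenomenon == "apa_shifted":
                    if apa_sites_per_gene < 2:
                        phenomenon = "full_length"
                        blocks = (
                            AlignmentBlock(
                                chrom=iso.chrom, strand=iso.strand, exons=iso.exons
                            ),
                        )
                    else:
                        if gene.id not in apa_cache:
                            apa_cache[gene.id] = planted_apa_sites(gene, apa_sites_per_gene)
                        site = apa_cache[gene.id][
                            int(rng_pheno.integers(1, apa_sites_per_gene))
                        ]
                        truth_kwargs["apa_site"] = site
                        blocks = (
                            AlignmentBlock(
                                chrom=iso.chrom,
                                strand=iso.strand,
                                exons=_apa_shift(iso, site),
                            ),
                        )
                else:
                    blocks = (
                        AlignmentBlock(chrom=iso.chrom, strand=iso.strand, exons=iso.exons),
                    )

                unmapped_pre = rng_pid.random() < pid_model.frac_unmapped_pre
                unmapped_post = (not unmapped_pre) and (
                    rng_pid.random() < pid_model.frac_unmapped_post
                )
                pid_pre = None
                pid_post = None
                if not unmapped_pre:
                    pid_pre = round(
                        float(
                            np.clip(
                                rng_pid.normal(pid_model.mean_pre, pid_model.sd), 50, 100
                            )
                        ),
                        2,
                    )
                if not unmapped_post:
                    if pid_pre is not None and rng_pid.random() < pid_model.frac_unchanged:
                        pid_post = pid_pre
                    else:
                        pid_post = round(
                            float(
                                np.clip(
                                    rng_pid.normal(pid_model.mean_post, pid_model.sd),
                                    50,
                                    100,
                                )
                            ),
                            2,
                        )
                reads.append(
                    FLNCRead(
                        id=rid,
                        blocks=blocks,
                        pid_pre=pid_pre,
                        pid_post=pid_post,
                        truth=TruthLabel(phenomenon=phenomenon, **truth_kwargs),
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    ann: ReferenceAnnotation,
    design: Mapping[str, str],
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    frac_de: float = 0.1,
    lfc_magnitude: float = 2.0,
    seed: int = 0,
) -> SimulatedCounts:
    """NB count matrix over all annotated transcripts with planted fold-changes.

    A planted-DE transcript has its mean multiplied by ``2**(+-lfc_magnitude)``
    in one randomly chosen tissue; ``truth_lfc`` records, per ordered tissue
    pair ``A_vs_B``, ``log2(mean_B / mean_A)``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    tissues = sorted(set(design.values()))
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    for t in tissues:
        if sum(1 for v in design.values() if v == t) < 2:
            raise ValueError(f"tissue {t} needs at least two replicates")
    rng = np.random.default_rng(seed)
    transcripts = [iso.id for iso in ann.transcripts]
    n = len(transcripts)
    samples = list(design.keys())

    base = baseline_mean * np.exp2(rng.normal(0.0, 1.0, size=n))
    mult = np.zeros((n, len(tissues)))  # log2 multipliers
    n_de = int(round(frac_de * n))
    de_rows = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    for i in de_rows:
        t = int(rng.integers(0, len(tissues)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mult[i, t] = sign * lfc_magnitude

    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        t_idx = tissues.index(design[sample])
        mu = base * np.exp2(mult[:, t_idx])
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))

    pairs = {}
    for a in range(len(tissues)):
        for b in range(a + 1, len(tissues)):
            pairs[f"{tissues[a]}_vs_{tissues[b]}"] = mult[:, b] - mult[:, a]
    return SimulatedCounts(
        counts=pd.DataFrame(counts, index=transcripts, columns=samples),
        design=dict(design),
        truth_lfc=pd.DataFrame(pairs, index=transcripts),
        dispersion=pd.Series(dispersion, index=transcripts, name="alpha"),
    )


def default_design(n_replicates: int = 4, tissues: Sequence[str] = ("TF", "SF", "VF")) -> Dict[str, str]:
    """Three-tissue design: ``{tissue}{replicate} -> tissue``."""
    return {f"{t}{r + 1}": t for t in tissues for r in range(n_replicates)}
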
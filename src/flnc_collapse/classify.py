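"""Isoform classification: full-length status, novelty, structural categories.

Categories (checked in order, first match wins):

* A — junction chain identical to a reference isoform
* B — chain is a contiguous proper sub-chain of a reference chain
* C — chain strictly contains a complete reference chain
* D — shares >=1 junction with a reference isoform, neither sub nor super
* E — exonic overlap with a same-strand reference isoform, 0 shared junctions
* F — novel locus (intergenic, or antisense to all overlapping genes)
* G — within an annotated same-strand gene's span but no exonic overlap

A multi-exon isoform is *full-length* when its donor-site set covers the
complete donor-site set of at least one annotated isoform on the same
chromosome and strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from .collapse import DEFAULT_OVERLAP_FRACTION, _overlap
from .models import GeneModel, IsoformCall, Locus, ReferenceAnnotation, TranscriptModel

CATEGORIES = ("A", "B", "C", "D", "E", "F", "G")

LENGTH_BINS = (
    ("<1K", 0, 1_000),
    ("1-2K", 1_000, 2_000),
    ("2-3K", 2_000, 3_000),
    (">=3K", 3_000, None),
)


@dataclass
class ClassifiedIsoform:
    isoform: IsoformCall
    full_length: Optional[bool]  # None for single-exon isoforms
    novelty: str  # known | novel_isoform | novel_gene
    category: str  # A..G
    matched_reference: Optional[str] = None


class _RefIndex:
    """Per chrom/strand reference lookups used by every classification rule."""

    def __init__(self, ann: ReferenceAnnotation) -> None:
        self.ann = ann
        self.genes_by_chrom: Dict[str, List[GeneModel]] = defaultdict(list)
        self.iso_by_cs: Dict[Tuple[str, str], List[TranscriptModel]] = defaultdict(list)
        for g in ann.genes:
            self.genes_by_chrom[g.chrom].append(g)
            for iso in g.isoforms:
                self.iso_by_cs[(g.chrom, g.strand)].append(iso)


def _span_overlap_fraction(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = _overlap(a, b)
    shorter = min(a[1] - a[0], b[1] - b[0])
    return ov / shorter if shorter > 0 else 0.0


def full_length_status(
    isoform: IsoformCall | TranscriptModel,
    ref: ReferenceAnnotation,
    mode: str = "all",
    _index: Optional[_RefIndex] = None,
) -> Optional[bool]:
    """True iff the isoform's donors cover a reference isoform's donor set.

    ``mode='all'`` requires the complete donor set of some annotated isoform;
    ``mode='any'`` accepts a single shared donor.  Single-exon isoforms return
    None (not applicable).
    """
    t = isoform.as_transcript() if isinstance(isoform, IsoformCall) else isoform
    if t.n_exons < 2:
        return None
    index = _index or _RefIndex(ref)
    donors = t.donor_sites
    for ref_iso in index.iso_by_cs.get((t.chrom, t.strand), []):
        ref_donors = ref_iso.donor_sites
        if not ref_donors:
            continue
        if mode == "all" and ref_donors <= donors:
            return True
        if mode == "any" and ref_donors & donors:
            return True
    return False


def call_novel_gene(
    locus: Locus,
    ref: ReferenceAnnotation,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    _index: Optional[_RefIndex] = None,
) -> bool:
    """Novel iff <20% span overlap with every annotated gene, or >=20% overlap
    only with opposite-strand genes."""
    index = _index or _RefIndex(ref)
    for gene in index.genes_by_chrom.get(locus.chrom, []):
        if gene.strand != locus.strand:
            continue
        if _span_overlap_fraction(locus.span, gene.span) >= overlap_fraction:
            return False
    return True


def call_novel_isoform(
    isoform: IsoformCall | TranscriptModel,
    ref: ReferenceAnnotation,
    _index: Optional[_RefIndex] = None,
) -> bool:
    """Novel iff any splice site of the isoform is absent from the annotated
    splice sites on its chromosome and strand."""
    t = isoform.as_transcript() if isinstance(isoform, IsoformCall) else isoform
    index = _index or _RefIndex(ref)
    annotated = set()
    for ref_iso in index.iso_by_cs.get((t.chrom, t.strand), []):
        annotated.update(ref_iso.splice_sites)
    return any(c not in annotated for c in t.splice_sites)


def _is_subchain(sub: Tuple, full: Tuple) -> bool:
    """Contiguous sub-sequence check over junction chains."""
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def _exonic_overlap(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]) -> bool:
    return any(_overlap(ea, eb) > 0 for ea in a for eb in b)


def categorize_structure(
    isoform: IsoformCall,
    ref: ReferenceAnnotation,
    locus_is_novel: bool,
    _index: Optional[_RefIndex] = None,
) -> Tuple[str, Optional[str]]:
    """Assign one of categories A-G; returns (category, matched reference id)."""
    index = _index or _RefIndex(ref)
    t = isoform.as_transcript()
    chain = t.junctions
    ref_isos = index.iso_by_cs.get((t.chrom, t.strand), [])
    overlapping = [r for r in ref_isos if _overlap(t.span, r.span) > 0]

    if chain:
        for r in overlapping:
            if r.junctions == chain:
                return "A", r.id
        for r in overlapping:
            if _is_subchain(chain, r.junctions):
                return "B", r.id
        for r in overlapping:
            if r.junctions and _is_subchain(r.junctions, chain):
                return "C", r.id
        cset = set(chain)
        for r in overlapping:
            if cset & set(r.junctions):
                return "D", r.id
    for r in overlapping:
        if not (set(chain) & set(r.junctions)) and _exonic_overlap(t.exons, r.exons):
            return "E", r.id
    if locus_is_novel:
        return "F", None
    # same-strand annotated gene covers the isoform but no exon is shared
    for gene in index.genes_by_chrom.get(t.chrom, []):
        if gene.strand == t.strand and _overlap(t.span, gene.span) > 0:
            return "G", gene.id
    return "F", None


def classify_isoforms(
    isoforms: Sequence[IsoformCall],
    loci: Sequence[Locus],
    ref: ReferenceAnnotation,
    full_length_mode: str = "all",
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> List[ClassifiedIsoform]:
    """Classify every retained isoform for full-length status, novelty, and
    structural category."""
    index = _RefIndex(ref)
    locus_by_id = {l.id: l for l in loci}
    novel_locus: Dict[str, bool] = {
        l.id: call_novel_gene(l, ref, overlap_fraction, _index=index) for l in loci
    }
    out: List[ClassifiedIsoform] = []
    for iso in isoforms:
        is_novel_locus = novel_locus[iso.locus_id]
        if is_novel_locus:
            novelty = "novel_gene"
        elif call_novel_isoform(iso, ref, _index=index):
            novelty = "novel_isoform"
        else:
            novelty = "known"
        category, matched = categorize_structure(
            iso, ref, is_novel_locus, _index=index
        )
        out.append(
            ClassifiedIsoform(
                isoform=iso,
                full_length=full_length_status(iso, ref, full_length_mode, _index=index),
                novelty=novelty,
                category=category,
                matched_reference=matched,
            )
        )
    return out


def classification_frame(classified: Sequence[ClassifiedIsoform]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "isoform_id": c.isoform.id,
                "locus_id": c.isoform.locus_id,
                "category": c.category,
                "novelty": c.novelty,
                "full_length": c.full_length,
                "matched_reference": c.matched_reference,
                "flnc_support": c.isoform.flnc_support,
            }
            for c in classified
        ]
    )


def length_bin_report(lengths: Sequence[int]) -> pd.DataFrame:
    """Bin lengths into <1K / 1-2K / 2-3K / >=3K with counts and percentages."""
    from .report import ratio

    total = len(lengths)
    rows = []
    for name, lo, hi in LENGTH_BINS:
        n = sum(1 for x in lengths if x >= lo and (hi is None or x < hi))
        rows.append(
            {
                "bin": name,
                "count": n,
                "percent": ratio(n, total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def locus_lengths(
    isoforms: Sequence[IsoformCall], measure: str = "exonic"
) -> List[int]:
    """Length of each locus: its longest isoform, exonic length or genomic span."""
    best: Dict[str, int] = {}
    for iso in isoforms:
        length = (
            iso.exonic_length if measure == "exonic" else iso.span[1] - iso.span[0]
        )
        best[iso.locus_id] = max(best.get(iso.locus_id, 0), length)
    return [best[k] for k in sorted(best)]
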
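"""Locus clustering, isoform collapse, and redundancy / false-positive filters.

Two aligned transcripts belong to the same locus when they map in the same
direction, their genomic spans overlap by more than 20% of the shorter span,
and at least one exon pair overlaps by more than 20% of the shorter exon.
Loci are the connected components (single-linkage closure) of that relation.
Within a locus, reads sharing an identical internal junction chain collapse
into one isoform spanning the widest observed ends.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .models import (
    IsoformCall,
    Junction,
    Locus,
    ReferenceAnnotation,
    TranscriptModel,
)

DEFAULT_OVERLAP_FRACTION = 0.20

JunctionKey = Tuple[str, str, int, int]  # (chrom, strand, intron_start, intron_end)


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def same_locus(
    a: TranscriptModel,
    b: TranscriptModel,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> bool:
    """Same mapping direction, >20% span overlap, and >20% overlap in >=1 exon.

    Overlap fractions are taken over the shorter of the two features.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    span_ov = _overlap(a.span, b.span)
    shorter_span = min(a.end - a.start, b.end - b.start)
    if span_ov <= overlap_fraction * shorter_span:
        return False
    for ea in a.exons:
        for eb in b.exons:
            ov = _overlap(ea, eb)
            if ov > overlap_fraction * min(ea[1] - ea[0], eb[1] - eb[0]):
                return True
    return False


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def assign_loci(
    transcripts: Sequence[TranscriptModel],
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> List[Locus]:
    """Partition transcripts into loci (connected components of same_locus).

    Locus ids are deterministic: loci sorted by (chrom, start, strand) get
    sequential ids ``locus000001`` onward.
    """
    n = len(transcripts)
    uf = _UnionFind(n)
    by_group: Dict[Tuple[str, str], List[int]] = defaultdict(list)
    for i, t in enumerate(transcripts):
        by_group[(t.chrom, t.strand)].append(i)
    for indices in by_group.values():
        indices.sort(key=lambda i: transcripts[i].start)
        # sweep: only transcripts whose spans overlap can satisfy the relation
        active: List[int] = []
        for i in indices:
            t = transcripts[i]
            active = [j for j in active if transcripts[j].end > t.start]
            for j in active:
                if same_locus(t, transcripts[j], overlap_fraction):
                    uf.union(i, j)
            active.append(i)
    components: Dict[int, List[int]] = defaultdict(list)
    for i in range(n):
        components[uf.find(i)].append(i)
    loci: List[Locus] = []
    for members in components.values():
        ms = [transcripts[i] for i in members]
        loci.append(
            Locus(
                id="",
                chrom=ms[0].chrom,
                strand=ms[0].strand,
                span=(min(m.start for m in ms), max(m.end for m in ms)),
                members=tuple(sorted(ms, key=lambda m: (m.start, m.end, m.id))),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    for k, locus in enumerate(loci, start=1):
        locus.id = f"locus{k:06d}"
    return loci


def _canonical_sites(
    members: Sequence[TranscriptModel], wobble: int
) -> Dict[int, int]:
    """Map each observed splice-site coordinate to a cluster representative.

    Sites within ``wobble`` bp (single linkage) share a representative (the
    smallest coordinate of the cluster).  With wobble=0 this is the identity.
    """
    sites = sorted({c for m in members for j in m.junctions for c in j})
    mapping: Dict[int, int] = {}
    if not sites:
        return mapping
    rep = sites[0]
    prev = sites[0]
    for s in sites:
        if s - prev > wobble:
            rep = s
        mapping[s] = rep
        prev = s
    return mapping


def collapse_to_isoforms(locus: Locus, wobble: int = 0) -> List[IsoformCall]:
    """Merge locus members sharing an identical internal junction chain.

    The merged isoform spans the widest observed ends; internal exons follow
    the shared junction chain.  Single-exon members merge by containment
    closure.
    """
    members = locus.members
    if not members:
        return []
    site_map = _canonical_sites(members, wobble) if wobble > 0 else None

    def chain_of(m: TranscriptModel) -> Tuple[Junction, ...]:
        if site_map is None:
            return m.junctions
        return tuple((site_map[l], site_map[r]) for l, r in m.junctions)

    groups: Dict[Tuple[Junction, ...], List[TranscriptModel]] = defaultdict(list)
    singles: List[TranscriptModel] = []
    for m in members:
        if m.n_exons == 1:
            singles.append(m)
        else:
            groups[chain_of(m)].append(m)

    merged: List[Tuple[Tuple[Tuple[int, int], ...], List[TranscriptModel]]] = []
    for chain, ms in groups.items():
        start = min(m.start for m in ms)
        end = max(m.end for m in ms)
        exons: List[Tuple[int, int]] = [(start, chain[0][0])]
        for i in range(len(chain) - 1):
            exons.append((chain[i][1], chain[i + 1][0]))
        exons.append((chain[-1][1], end))
        merged.append((tuple(exons), ms))

    if singles:
        singles.sort(key=lambda m: (m.start, m.end, m.id))
        uf = _UnionFind(len(singles))
        for i in range(len(singles)):
            for j in range(i + 1, len(singles)):
                a, b = singles[i], singles[j]
                if (a.start <= b.start and b.end <= a.end) or (
                    b.start <= a.start and a.end <= b.end
                ):
                    uf.union(i, j)
        comp: Dict[int, List[TranscriptModel]] = defaultdict(list)
        for i, m in enumerate(singles):
            comp[uf.find(i)].append(m)
        for ms in comp.values():
            span = (min(m.start for m in ms), max(m.end for m in ms))
            merged.append(((span,), ms))

    merged.sort(key=lambda t: (t[0][0][0], t[0][-1][1], t[0]))
    calls: List[IsoformCall] = []
    for k, (exons, ms) in enumerate(merged, start=1):
        calls.append(
            IsoformCall(
                id=f"{locus.id}.i{k}",
                locus_id=locus.id,
                chrom=locus.chrom,
                strand=locus.strand,
                exons=exons,
                flnc_support=len(ms),
                member_reads=tuple(m.id for m in ms),
            )
        )
    return calls


def _is_5prime_truncation(short: IsoformCall, long: IsoformCall) -> bool:
    """True iff short's chain is a 5'-truncated contiguous sub-chain of long's
    chain (strand-aware) and short's span lies inside long's span."""
    cs, cl = short.junctions, long.junctions
    if cs == cl:
        # same chain: redundant iff same 3' end but a shorter 5' terminal exon
        if short.strand == "+":
            return short.span[1] == long.span[1] and short.span[0] > long.span[0]
        return short.span[0] == long.span[0] and short.span[1] < long.span[1]
    if len(cs) >= len(cl):
        return False
    if not (long.span[0] <= short.span[0] and short.span[1] <= long.span[1]):
        return False
    if short.strand == "+":
        # 5' truncation removes leading (genomic-left) junctions
        k = len(cl) - len(cs)
        if cs != cl[k:]:
            return False
        # short must start within long's exon preceding its first junction
        return short.span[0] >= cl[k - 1][1]
    # '-' strand: 5' truncation removes trailing (genomic-right) junctions
    k = len(cs)
    if cs != cl[:k]:
        return False
    return short.span[1] <= cl[k][0]


def filter_redundant(isoforms: Sequence[IsoformCall]) -> List[IsoformCall]:
    """Flag isoforms whose chain is a 5'-truncated sub-chain of another isoform
    of the locus; absorbed support is added to the absorbing isoform."""
    ordered = sorted(
        isoforms, key=lambda i: (len(i.junctions), i.exonic_length), reverse=True
    )
    for iso in ordered:
        if iso.redundant:
            continue
        for other in ordered:
            if other is iso or other.redundant:
                continue
            if _is_5prime_truncation(iso, other):
                iso.redundant = True
                iso.absorbed_into = other.id
                other.flnc_support += iso.flnc_support
                other.member_reads = other.member_reads + iso.member_reads
                break
    return list(isoforms)


def junction_keys(t: TranscriptModel | IsoformCall) -> List[JunctionKey]:
    return [(t.chrom, t.strand, l, r) for l, r in t.junctions]


def annotated_junction_set(ann: ReferenceAnnotation) -> FrozenSet[JunctionKey]:
    return frozenset(k for iso in ann.transcripts for k in junction_keys(iso))


def filter_false_positive(
    isoform: IsoformCall,
    annotated_junctions: FrozenSet[JunctionKey] = frozenset(),
    short_read_junctions: FrozenSet[JunctionKey] = frozenset(),
    min_support: int = 2,
) -> bool:
    """Flag single-read isoforms lacking junction evidence as false positives.

    Retained iff support >= min_support, or every junction of the chain is
    present in the annotated or short-read evidence set.  Returns the flag and
    records it on the isoform.
    """
    if isoform.flnc_support >= min_support:
        isoform.false_positive = False
    else:
        evidence = annotated_junctions | short_read_junctions
        isoform.false_positive = not all(k in evidence for k in junction_keys(isoform))
    return isoform.false_positive


def collapse_reads(
    transcripts: Sequence[TranscriptModel],
    annotated_junctions: FrozenSet[JunctionKey] = frozenset(),
    short_read_junctions: FrozenSet[JunctionKey] = frozenset(),
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    wobble: int = 0,
    min_support: int = 2,
) -> Tuple[List[Locus], List[IsoformCall]]:
    """Full collapse stage: loci -> isoforms -> redundancy -> false positives."""
    loci = assign_loci(transcripts, overlap_fraction)
    calls: List[IsoformCall] = []
    for locus in loci:
        isoforms = collapse_to_isoforms(locus, wobble=wobble)
        filter_redundant(isoforms)
        for iso in isoforms:
            if not iso.redundant:
                filter_false_positive(
                    iso, annotated_junctions, short_read_junctions, min_support
                )
        calls.extend(isoforms)
    return loci, calls
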
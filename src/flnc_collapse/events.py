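"""Alternative splicing, alternative polyadenylation, and fusion detection.

AS events are typed from pairwise isoform comparison.  Within the genomic
interval both isoforms cover, the introns unique to either isoform are grouped
into connected components by interval overlap; each component is matched
against the canonical patterns:

* ES  — one isoform has intron (d,a); the other has introns (d,s),(t,a),
        i.e. it includes an exon (s,t) the first one skips
* IR  — one isoform's intron lies entirely inside the other's exon
* AD  — two introns sharing the acceptor, differing at the donor (strand-aware)
* AA  — two introns sharing the donor, differing at the acceptor
* MEE — (d,s1),(t1,a) vs (d,s2),(t2,a) with disjoint middle exons
* complex — any other difference component
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import FLNCRead, GeneModel, IsoformCall, ReferenceAnnotation, TranscriptModel

AS_TYPES = ("ES", "AA", "AD", "IR", "MEE", "complex")

DEFAULT_APA_WINDOW = 24
DEFAULT_MIN_PARTNER_OVERLAP = 0.5
DEFAULT_FUSION_MIN_GAP = 10_000


@dataclass(frozen=True)
class ASEvent:
    type: str
    locus_id: str
    isoform_a: str
    isoform_b: str
    region: Tuple[int, ...]  # coordinates of the variable region

    @property
    def key(self) -> Tuple[str, Tuple[int, ...]]:
        """Deduplication key: event type + variable-region coordinates."""
        return (self.type, self.region)


@dataclass(frozen=True)
class APACluster:
    gene_id: str
    site: int  # representative coordinate (most-supported end)
    support: int
    n_sites_in_gene: int = 0


@dataclass(frozen=True)
class FusionCall:
    partner_5prime: str
    partner_3prime: str
    kind: str  # intrachromosomal | interchromosomal
    read_ids: Tuple[str, ...]


# ---------------------------------------------------------------------------
# Alternative splicing


def _classify_component(
    ux: List[Tuple[int, int]],
    uy: List[Tuple[int, int]],
    strand: str,
) -> Tuple[str, Tuple[int, ...]]:
    """Type one difference component given each isoform's unique introns."""
    # orient so the side with fewer introns comes first
    if len(ux) > len(uy):
        ux, uy = uy, ux
    if len(ux) == 0 and len(uy) == 1:
        return "IR", tuple(uy[0])
    if len(ux) == 1 and len(uy) == 1:
        (l1, r1), (l2, r2) = ux[0], uy[0]
        if r1 == r2 and l1 != l2:
            # shared genomic-right boundary: donor on '+' differs -> AD
            t = "AD" if strand == "+" else "AA"
            return t, (min(l1, l2), max(l1, l2), r1)
        if l1 == l2 and r1 != r2:
            t = "AA" if strand == "+" else "AD"
            return t, (l1, min(r1, r2), max(r1, r2))
        return "complex", tuple(sorted({l1, r1, l2, r2}))
    if len(ux) == 1 and len(uy) == 2:
        (d, a) = ux[0]
        (d1, s), (t, a1) = sorted(uy)
        if d1 == d and a1 == a and s < t:
            return "ES", (s, t)
        return "complex", tuple(sorted({d, a, d1, s, t, a1}))
    if len(ux) == 2 and len(uy) == 2:
        (d1, s1), (t1, a1) = sorted(ux)
        (d2, s2), (t2, a2) = sorted(uy)
        if d1 == d2 and a1 == a2 and s1 < t1 and s2 < t2:
            if t1 <= s2 or t2 <= s1:  # middle exons disjoint
                return "MEE", tuple(sorted((s1, t1, s2, t2)))
        return "complex", tuple(sorted({d1, s1, t1, a1, d2, s2, t2, a2}))
    coords = sorted({c for j in ux + uy for c in j})
    return "complex", tuple(coords)


def pairwise_as_events(
    a: TranscriptModel | IsoformCall,
    b: TranscriptModel | IsoformCall,
    locus_id: str = "",
) -> List[ASEvent]:
    """All typed AS events between two isoforms of the same locus."""
    ta = a.as_transcript() if isinstance(a, IsoformCall) else a
    tb = b.as_transcript() if isinstance(b, IsoformCall) else b
    lo = max(ta.start, tb.start)
    hi = min(ta.end, tb.end)
    if hi <= lo:
        return []
    ja = {j for j in ta.junctions if lo <= j[0] and j[1] <= hi}
    jb = {j for j in tb.junctions if lo <= j[0] and j[1] <= hi}
    ua = sorted(ja - jb)
    ub = sorted(jb - ja)
    if not ua and not ub:
        return []
    # junctions crossing the common-span boundary leave no shared flanking
    # context; regions they touch are excluded from event calling
    masked = [
        (max(j[0], lo), min(j[1], hi))
        for t in (ta, tb)
        for j in t.junctions
        if j[0] < hi and j[1] > lo and not (lo <= j[0] and j[1] <= hi)
    ]
    # connected components of the unique introns under interval overlap
    tagged = sorted([(j, "a") for j in ua] + [(j, "b") for j in ub])
    components: List[List[Tuple[Tuple[int, int], str]]] = []
    cur: List[Tuple[Tuple[int, int], str]] = []
    cur_end = -1
    for j, side in tagged:
        if cur and j[0] >= cur_end:
            components.append(cur)
            cur = []
            cur_end = -1
        cur.append((j, side))
        cur_end = max(cur_end, j[1])
    if cur:
        components.append(cur)
    events: List[ASEvent] = []
    for comp in components:
        span = (min(j[0] for j, _ in comp), max(j[1] for j, _ in comp))
        if any(m[0] < span[1] and m[1] > span[0] for m in masked):
            continue
        ux = [j for j, side in comp if side == "a"]
        uy = [j for j, side in comp if side == "b"]
        etype, region = _classify_component(ux, uy, ta.strand)
        events.append(
            ASEvent(
                type=etype,
                locus_id=locus_id,
                isoform_a=ta.id,
                isoform_b=tb.id,
                region=region,
            )
        )
    return events


def detect_as_events(
    isoforms: Sequence[TranscriptModel | IsoformCall], locus_id: str = ""
) -> List[ASEvent]:
    """Pairwise AS events over a locus, deduplicated by type + variable region."""
    items = sorted(
        isoforms,
        key=lambda i: (i.id if isinstance(i, TranscriptModel) else i.id),
    )
    seen: Set[Tuple[str, Tuple[int, ...]]] = set()
    events: List[ASEvent] = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            for ev in pairwise_as_events(items[i], items[j], locus_id):
                if ev.key not in seen:
                    seen.add(ev.key)
                    events.append(ev)
    return events


def as_summary(events: Sequence[ASEvent]) -> pd.DataFrame:
    from .report import ratio

    total = len(events)
    rows = []
    for t in AS_TYPES:
        n = sum(1 for e in events if e.type == t)
        rows.append({"type": t, "count": n, "percent": ratio(n, total) if total else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Alternative polyadenylation


def detect_apa(
    gene_id: str,
    three_prime_ends: Sequence[int],
    cluster_window: int = DEFAULT_APA_WINDOW,
    min_support: int = 2,
) -> List[APACluster]:
    """Cluster read 3' ends by single linkage within ``cluster_window``.

    Clusters supported by fewer than ``min_support`` reads are dropped; the
    representative site is the most frequent end of the cluster (smallest on
    ties).
    """
    if not three_prime_ends:
        return []
    ends = sorted(three_prime_ends)
    clusters: List[List[int]] = [[ends[0]]]
    for e in ends[1:]:
        if e - clusters[-1][-1] <= cluster_window:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    kept = [c for c in clusters if len(c) >= min_support]
    out = []
    for c in kept:
        freq: Dict[int, int] = defaultdict(int)
        for e in c:
            freq[e] += 1
        site = min(sorted(freq), key=lambda s: (-freq[s], s))
        out.append(
            APACluster(gene_id=gene_id, site=site, support=len(c), n_sites_in_gene=len(kept))
        )
    return out


def gene_has_apa(clusters: Sequence[APACluster]) -> bool:
    return len(clusters) >= 2


def reads_three_prime_ends(reads: Iterable[FLNCRead]) -> List[int]:
    """Strand-aware 3' terminal genomic coordinate of each non-chimeric read."""
    out = []
    for r in reads:
        if r.is_chimeric:
            continue
        b = r.blocks[0]
        out.append(b.end if b.strand == "+" else b.start)
    return out


# ---------------------------------------------------------------------------
# Fusion


def _best_partner(
    block, genes: Sequence[GeneModel], min_overlap: float
) -> Optional[GeneModel]:
    best = None
    best_frac = 0.0
    blen = block.end - block.start
    for g in genes:
        if g.chrom != block.chrom:
            continue
        ov = max(0, min(block.end, g.end) - max(block.start, g.start))
        frac = ov / blen if blen else 0.0
        if frac >= min_overlap and frac > best_frac:
            best = g
            best_frac = frac
    return best


def detect_fusion(
    reads: Sequence[FLNCRead],
    ann: ReferenceAnnotation,
    min_partner_overlap: float = DEFAULT_MIN_PARTNER_OVERLAP,
    min_reads: int = 1,
    min_gap: Optional[int] = DEFAULT_FUSION_MIN_GAP,
) -> List[FusionCall]:
    """Call fusions from chimeric reads whose halves map inside two genes.

    ``min_gap`` (when not None) requires intrachromosomal partner spans to be
    separated by at least that many bp, guarding against read-through
    artifacts.
    """
    by_pair: Dict[Tuple[str, str], List[str]] = defaultdict(list)
    gene_by_id = {g.id: g for g in ann.genes}
    for read in reads:
        if not read.is_chimeric:
            continue
        g5 = _best_partner(read.blocks[0], ann.genes, min_partner_overlap)
        g3 = _best_partner(read.blocks[1], ann.genes, min_partner_overlap)
        if g5 is None or g3 is None or g5.id == g3.id:
            continue
        if g5.chrom == g3.chrom and min_gap is not None:
            gap = max(g5.start, g3.start) - min(g5.end, g3.end)
            if gap < min_gap:
                continue
        by_pair[(g5.id, g3.id)].append(read.id)
    calls: List[FusionCall] = []
    for (a, b), rids in sorted(by_pair.items()):
        if len(rids) < min_reads:
            continue
        kind = (
            "intrachromosomal"
            if gene_by_id[a].chrom == gene_by_id[b].chrom
            else "interchromosomal"
        )
        calls.append(
            FusionCall(partner_5prime=a, partner_3prime=b, kind=kind, read_ids=tuple(rids))
        )
    return calls
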
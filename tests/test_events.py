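from __future__ import annotations

import itertools

import numpy as np
import pytest

from flnc_collapse import events as ev
from flnc_collapse import synthetic_data as sim
from flnc_collapse.models import AlignmentBlock, FLNCRead, TranscriptModel
from .conftest import make_tx


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate typed AS templates directly from exon lists


def _clipped_junctions(t, lo, hi):
    return [j for j in t.junctions if j[0] >= lo and j[1] <= hi]


def oracle_pair_events(ta: TranscriptModel, tb: TranscriptModel):
    """Independent enumeration of ES/AA/AD/IR/MEE templates plus a complex
    count, using per-base painting for the component tally."""
    lo, hi = max(ta.start, tb.start), min(ta.end, tb.end)
    if hi <= lo:
        return set(), 0
    ja = _clipped_junctions(ta, lo, hi)
    jb = _clipped_junctions(tb, lo, hi)
    ua = [j for j in ja if j not in jb]
    ub = [j for j in jb if j not in ja]
    uni = ua + ub
    masked = []
    for t in (ta, tb):
        for j in t.junctions:
            if j[0] < hi and j[1] > lo and not (lo <= j[0] and j[1] <= hi):
                masked.append((max(j[0], lo), min(j[1], hi)))

    def exclusive(window, members):
        if any(m[0] < window[1] and m[1] > window[0] for m in masked):
            return False
        return not any(
            o
            for o in uni
            if o not in members and o[0] < window[1] and o[1] > window[0]
        )

    typed = set()
    for X, Y, ux, uy in ((ta, tb, ua, ub), (tb, ta, ub, ua)):
        # ES: X skips exon (s,t) that Y includes between shared outer ends
        for (d, a) in ux:
            for (d1, s) in uy:
                for (t, a1) in uy:
                    if d1 == d and a1 == a and s < t and (s, t) in Y.exons:
                        if exclusive((d, a), [(d, a), (d1, s), (t, a1)]):
                            typed.add(("ES", (s, t)))
        # IR: X's intron fully inside one of Y's exons
        for (d, a) in ux:
            for (u, v) in Y.exons:
                if u <= d and a <= v and exclusive((d, a), [(d, a)]):
                    typed.add(("IR", (d, a)))
    # AD/AA: single intron pair sharing one boundary
    for (l1, r1) in ua:
        for (l2, r2) in ub:
            if r1 == r2 and l1 != l2:
                window = (min(l1, l2), r1)
                if exclusive(window, [(l1, r1), (l2, r2)]):
                    t = "AD" if ta.strand == "+" else "AA"
                    typed.add((t, (min(l1, l2), max(l1, l2), r1)))
            if l1 == l2 and r1 != r2:
                window = (l1, max(r1, r2))
                if exclusive(window, [(l1, r1), (l2, r2)]):
                    t = "AA" if ta.strand == "+" else "AD"
                    typed.add((t, (l1, min(r1, r2), max(r1, r2))))
    # MEE: two consecutive unique introns per side, shared outer ends,
    # disjoint middle exons
    for (d1, s1), (t1, a1) in itertools.combinations(sorted(ua), 2):
        for (d2, s2), (t2, a2) in itertools.combinations(sorted(ub), 2):
            if d1 == d2 and a1 == a2 and s1 < t1 and s2 < t2:
                if (s1, t1) in ta.exons and (s2, t2) in tb.exons:
                    if (t1 <= s2 or t2 <= s1) and exclusive(
                        (d1, a1), [(d1, s1), (t1, a1), (d2, s2), (t2, a2)]
                    ):
                        typed.add(("MEE", tuple(sorted((s1, t1, s2, t2)))))
    # component tally by painting unique-intron coverage
    n_components = 0
    if uni:
        # paint at 2x resolution so touching (non-overlapping) introns stay apart
        offset = 2 * min(j[0] for j in uni)
        length = 2 * max(j[1] for j in uni) - offset
        paint = np.zeros(length, dtype=bool)
        for l, r in uni:
            paint[2 * l - offset : 2 * r - 1 - offset] = True
        edges = np.diff(np.concatenate([[0], paint.view(np.int8), [0]]))
        starts = (np.flatnonzero(edges == 1) + offset) // 2
        ends = (np.flatnonzero(edges == -1) + offset + 1) // 2
        for s, e in zip(starts, ends):
            if not any(m[0] < e and m[1] > s for m in masked):
                n_components += 1
    n_complex = n_components - len(typed)
    return typed, n_complex


def random_transcript(rng, tid, strand="+"):
    n_sites = int(rng.integers(1, 5)) * 2
    sites = sorted(rng.choice(np.arange(10, 1990, 10), size=n_sites, replace=False))
    exons = tuple((int(sites[i]), int(sites[i + 1])) for i in range(0, n_sites, 2))
    return TranscriptModel(id=tid, chrom="chr1", strand=strand, exons=exons)


class TestPairwiseEvents:
    def test_exon_skipping(self):
        a = make_tx("a", [(0, 100), (200, 300), (400, 500)])
        b = make_tx("b", [(0, 100), (400, 500)])
        events = ev.pairwise_as_events(a, b)
        assert [(e.type, e.region) for e in events] == [("ES", (200, 300))]

    def test_intron_retention(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 300)])
        events = ev.pairwise_as_events(a, b)
        assert [(e.type, e.region) for e in events] == [("IR", (100, 200))]

    def test_alternative_donor_plus_strand(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 120), (200, 300)])
        events = ev.pairwise_as_events(a, b)
        assert [e.type for e in events] == ["AD"]

    def test_alternative_acceptor_plus_strand(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 100), (220, 300)])
        events = ev.pairwise_as_events(a, b)
        assert [e.type for e in events] == ["AA"]

    def test_donor_acceptor_labels_swap_on_minus_strand(self):
        a = make_tx("a", [(0, 100), (200, 300)], strand="-")
        b = make_tx("b", [(0, 120), (200, 300)], strand="-")
        assert [e.type for e in ev.pairwise_as_events(a, b)] == ["AA"]

    def test_mutually_exclusive_exons(self):
        a = make_tx("a", [(0, 100), (200, 300), (600, 700)])
        b = make_tx("b", [(0, 100), (400, 500), (600, 700)])
        events = ev.pairwise_as_events(a, b)
        assert [(e.type, e.region) for e in events] == [("MEE", (200, 300, 400, 500))]

    def test_single_isoform_no_events(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        assert ev.detect_as_events([a]) == []

    def test_agreement_with_brute_force_oracle(self):
        """Exact agreement with the template-enumeration oracle on random pairs."""
        rng = np.random.default_rng(99)
        checked_types = 0
        for trial in range(400):
            a = random_transcript(rng, "a")
            b = random_transcript(rng, "b")
            got = ev.pairwise_as_events(a, b)
            got_typed = {(e.type, e.region) for e in got if e.type != "complex"}
            got_complex = sum(1 for e in got if e.type == "complex")
            want_typed, want_complex = oracle_pair_events(a, b)
            assert got_typed == want_typed, f"trial {trial}: {a.exons} vs {b.exons}"
            assert got_complex == want_complex, f"trial {trial}"
            checked_types += len(want_typed)
        assert checked_types > 50  # the generator must actually exercise patterns

    def test_agreement_on_simulated_loci(self, sim_annotation):
        for gene in sim_annotation.genes:
            for a, b in itertools.combinations(gene.isoforms, 2):
                got = ev.pairwise_as_events(a, b)
                got_typed = {(e.type, e.region) for e in got if e.type != "complex"}
                want_typed, want_complex = oracle_pair_events(a, b)
                assert got_typed == want_typed
                assert sum(1 for e in got if e.type == "complex") == want_complex

    def test_event_order_invariance(self, sim_annotation):
        genes = [g for g in sim_annotation.genes if len(g.isoforms) >= 2]
        assert genes
        for g in genes:
            fwd = ev.detect_as_events(list(g.isoforms))
            rev = ev.detect_as_events(list(reversed(g.isoforms)))
            assert {e.key for e in fwd} == {e.key for e in rev}
            assert len(fwd) == len(rev)


class TestDetectApa:
    def test_manual_clustering_example(self):
        ends = [1000, 1000, 1000, 1500, 1500, 2000]
        clusters = ev.detect_apa("g", ends, cluster_window=30, min_support=2)
        assert [(c.site, c.support) for c in clusters] == [(1000, 3), (1500, 2)]
        assert all(c.n_sites_in_gene == 2 for c in clusters)
        assert ev.gene_has_apa(clusters)

    def test_single_site_not_apa(self):
        clusters = ev.detect_apa("g", [1200] * 5)
        assert len(clusters) == 1
        assert not ev.gene_has_apa(clusters)

    def test_no_reads(self):
        assert ev.detect_apa("g", []) == []

    def test_min_support_invariant(self):
        rng = np.random.default_rng(3)
        ends = list(rng.integers(0, 10_000, size=200))
        for c in ev.detect_apa("g", ends, cluster_window=24, min_support=2):
            assert c.support >= 2

    def test_single_linkage_chaining(self):
        # consecutive ends 10 apart chain into one cluster under window 10
        clusters = ev.detect_apa("g", [100, 110, 120, 130], cluster_window=10)
        assert len(clusters) == 1 and clusters[0].support == 4

    def test_planted_apa_recovery(self, sim_annotation):
        reads = sim.simulate_flnc(
            sim_annotation,
            reads_per_isoform=8,
            p_apa=0.4,
            apa_sites_per_gene=2,
            seed=51,
        )
        by_gene = {}
        for r in reads:
            gid = r.truth.source_transcript.rsplit(".", 1)[0]
            by_gene.setdefault(gid, []).append(r)
        n_checked = 0
        for gene in sim_annotation.genes:
            planted = {
                r.truth.apa_site
                for r in by_gene.get(gene.id, [])
                if r.truth.apa_site is not None
            }
            ends = ev.reads_three_prime_ends(by_gene.get(gene.id, []))
            clusters = ev.detect_apa(gene.id, ends, cluster_window=24, min_support=2)
            sites = {c.site for c in clusters}
            # every planted alternative site with >=2 supporting reads recovered
            supported = {
                s
                for s in planted
                if sum(1 for r in by_gene[gene.id] if r.truth.apa_site == s) >= 2
            }
            assert supported <= sites
            if supported:
                n_checked += 1
                assert ev.gene_has_apa(clusters)
        assert n_checked > 5


class TestDetectFusion:
    def fusion_read(self, rid, blocks):
        return FLNCRead(id=rid, blocks=blocks)

    def test_interchromosomal_call(self, toy_annotation):
        read = self.fusion_read(
            "f1",
            (
                AlignmentBlock("chr1", "+", ((1000, 1200),)),
                AlignmentBlock("chr2", "+", ((5000, 5300),)),
            ),
        )
        calls = ev.detect_fusion([read], toy_annotation)
        assert len(calls) == 1
        assert calls[0].partner_5prime == "geneA"
        assert calls[0].partner_3prime == "geneC"
        assert calls[0].kind == "interchromosomal"

    def test_same_gene_no_call(self, toy_annotation):
        read = self.fusion_read(
            "f1",
            (
                AlignmentBlock("chr1", "+", ((1000, 1200),)),
                AlignmentBlock("chr1", "+", ((3000, 3300),)),
            ),
        )
        assert ev.detect_fusion([read], toy_annotation) == []

    def test_intrachromosomal_call(self, toy_annotation):
        read = self.fusion_read(
            "f1",
            (
                AlignmentBlock("chr1", "+", ((1000, 1200),)),
                AlignmentBlock("chr1", "-", ((50_000, 50_400),)),
            ),
        )
        calls = ev.detect_fusion([read], toy_annotation)
        assert len(calls) == 1 and calls[0].kind == "intrachromosomal"

    def test_min_gap_guard(self, toy_annotation):
        read = self.fusion_read(
            "f1",
            (
                AlignmentBlock("chr1", "+", ((1000, 1200),)),
                AlignmentBlock("chr1", "-", ((50_000, 50_400),)),
            ),
        )
        # partners ~46 kb apart: blocked when min_gap exceeds that
        assert ev.detect_fusion([read], toy_annotation, min_gap=100_000) == []
        assert len(ev.detect_fusion([read], toy_annotation, min_gap=None)) == 1

    def test_unassignable_block_skipped(self, toy_annotation):
        read = self.fusion_read(
            "f1",
            (
                AlignmentBlock("chr1", "+", ((1000, 1200),)),
                AlignmentBlock("chr9", "+", ((5000, 5300),)),
            ),
        )
        assert ev.detect_fusion([read], toy_annotation) == []

    def test_planted_fusion_recovery(self, sim_annotation):
        """Recall 1.0 and no false calls when planted chimeras are the only ones."""
        reads = sim.simulate_flnc(
            sim_annotation, reads_per_isoform=6, p_fusion=0.05, seed=61
        )
        calls = ev.detect_fusion(reads, sim_annotation, min_gap=None)
        truth_pairs = {
            tuple(r.truth.source_transcript.split("--"))
            for r in reads
            if r.truth.phenomenon == "fusion"
        }
        called_pairs = {(c.partner_5prime, c.partner_3prime) for c in calls}
        assert called_pairs == truth_pairs
        truth_reads = {r.id for r in reads if r.truth.phenomenon == "fusion"}
        called_reads = {rid for c in calls for rid in c.read_ids}
        assert called_reads == truth_reads
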
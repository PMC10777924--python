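"""Core domain types shared by every pipeline stage.

All coordinates are 0-based half-open genome intervals.  Splice junctions are
represented as intron intervals ``(donor_side_end, acceptor_side_start)`` in
genomic orientation; strand-aware donor/acceptor accessors are provided on
:class:`TranscriptModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple

Exon = Tuple[int, int]
Junction = Tuple[int, int]

VALID_STRANDS = ("+", "-")

PHENOMENA = (
    "full_length",
    "degraded_5prime",
    "novel_isoform",
    "novel_gene",
    "fusion",
    "apa_shifted",
)


def _check_exons(exons: Sequence[Exon]) -> Tuple[Exon, ...]:
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValueError("exon list must be non-empty")
    prev_end = None
    for start, end in exons:
        if end <= start:
            raise ValueError(f"exon ({start}, {end}) has non-positive length")
        if prev_end is not None and start < prev_end:
            raise ValueError("exons must be sorted and non-overlapping")
        prev_end = end
    return exons


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on one chromosome and strand."""

    id: str
    chrom: str
    strand: str
    exons: Tuple[Exon, ...]

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        object.__setattr__(self, "exons", _check_exons(self.exons))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def junctions(self) -> Tuple[Junction, ...]:
        """Intron intervals in genomic order (left exon end, right exon start)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def donor_sites(self) -> frozenset:
        """5' splice-site coordinates (strand-aware)."""
        if self.strand == "+":
            return frozenset(j[0] for j in self.junctions)
        return frozenset(j[1] for j in self.junctions)

    @property
    def acceptor_sites(self) -> frozenset:
        """3' splice-site coordinates (strand-aware)."""
        if self.strand == "+":
            return frozenset(j[1] for j in self.junctions)
        return frozenset(j[0] for j in self.junctions)

    @property
    def splice_sites(self) -> frozenset:
        return frozenset(c for j in self.junctions for c in j)

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GeneModel:
    id: str
    chrom: str
    strand: str
    isoforms: Tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "isoforms", tuple(self.isoforms))
        for iso in self.isoforms:
            if iso.chrom != self.chrom or iso.strand != self.strand:
                raise ValueError(
                    f"isoform {iso.id} disagrees with gene {self.id} on chrom/strand"
                )

    @property
    def start(self) -> int:
        return min(i.start for i in self.isoforms)

    @property
    def end(self) -> int:
        return max(i.end for i in self.isoforms)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def union_exon_length(self) -> int:
        """Length of the union of all isoform exons (used as gene length)."""
        intervals = sorted(e for iso in self.isoforms for e in iso.exons)
        total = 0
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        return total


@dataclass(frozen=True)
class ReferenceAnnotation:
    genes: Tuple[GeneModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        seen = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id}")
            seen.add(g.id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    @property
    def transcripts(self) -> Tuple[TranscriptModel, ...]:
        return tuple(iso for g in self.genes for iso in g.isoforms)

    def gene_of(self, transcript_id: str) -> GeneModel:
        for g in self.genes:
            if any(i.id == transcript_id for i in g.isoforms):
                return g
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned segment of a read (a full exon chain)."""

    chrom: str
    strand: str
    exons: Tuple[Exon, ...]

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        object.__setattr__(self, "exons", _check_exons(self.exons))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class TruthLabel:
    """Generation-time ground truth attached to a simulated read."""

    phenomenon: str
    source_transcript: Optional[str] = None
    apa_site: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phenomenon not in PHENOMENA:
            raise ValueError(f"unknown phenomenon {self.phenomenon!r}")


@dataclass(frozen=True)
class FLNCRead:
    """One full-length non-chimeric read: alignment, PID pair, truth label.

    ``blocks`` has one element for ordinary reads and two for chimeric
    (fusion) reads, ordered 5' half first in read coordinates.
    """

    id: str
    blocks: Tuple[AlignmentBlock, ...]
    pid_pre: Optional[float] = None
    pid_post: Optional[float] = None
    has_polya: bool = True
    truth: Optional[TruthLabel] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if len(self.blocks) not in (1, 2):
            raise ValueError("a read has one alignment block, or two if chimeric")
        for pid in (self.pid_pre, self.pid_post):
            if pid is not None and not (0.0 <= pid <= 100.0):
                raise ValueError(f"PID {pid} outside [0, 100]")

    @property
    def is_chimeric(self) -> bool:
        return len(self.blocks) == 2

    def to_transcript(self) -> TranscriptModel:
        """View a non-chimeric read as a transcript model for collapsing."""
        if self.is_chimeric:
            raise ValueError(f"read {self.id} is chimeric")
        b = self.blocks[0]
        return TranscriptModel(id=self.id, chrom=b.chrom, strand=b.strand, exons=b.exons)


@dataclass
class Locus:
    """A connected cluster of same-direction overlapping transcripts."""

    id: str
    chrom: str
    strand: str
    span: Tuple[int, int]
    members: Tuple[TranscriptModel, ...] = ()

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass
class IsoformCall:
    """A collapsed isoform with support bookkeeping and filter flags."""

    id: str
    locus_id: str
    chrom: str
    strand: str
    exons: Tuple[Exon, ...]
    flnc_support: int
    member_reads: Tuple[str, ...] = ()
    junction_support: frozenset = frozenset()
    redundant: bool = False
    false_positive: bool = False
    absorbed_into: Optional[str] = None

    @property
    def retained(self) -> bool:
        return not self.redundant and not self.false_positive

    def as_transcript(self) -> TranscriptModel:
        return TranscriptModel(
            id=self.id, chrom=self.chrom, strand=self.strand, exons=self.exons
        )

    @property
    def junctions(self) -> Tuple[Junction, ...]:
        return self.as_transcript().junctions

    @property
    def span(self) -> Tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)
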
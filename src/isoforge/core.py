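"""Shared genomic data model.

Coordinate convention: all internal coordinates are 0-based, half-open
``[start, end)``.  GFF3 I/O converts to/from the 1-based closed dialect,
BED12 is natively 0-based half-open.

The central currency of the package is :class:`TranscriptModel` — an
oriented chain of non-overlapping exon blocks on one chromosome.  Splice
structure is summarised by :class:`SpliceChain`, the ordered list of
introns in transcription direction; two multi-exon transcripts are "the
same isoform" exactly when their splice chains are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

__all__ = [
    "GenomeInterval",
    "TranscriptModel",
    "SpliceChain",
    "AlignmentRecord",
    "Gene",
    "Annotation",
    "overlap_fraction",
    "extract_junctions",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval.

    ``strand`` may be "+", "-" or "." (unstranded); transcripts must be
    stranded, "." is reserved for strand-agnostic windows (e.g. the
    regions used for methylation pooling).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_fraction(
    a: GenomeInterval,
    b: GenomeInterval,
    denominator: Literal["a", "b", "shorter"] = "shorter",
) -> float:
    """Overlap of ``a`` and ``b`` as a fraction of the chosen denominator.

    Returns 0.0 for disjoint intervals.  Raises if the intervals sit on
    different chromosomes — callers are expected to pre-filter.
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"overlap_fraction across chromosomes: {a.chrom} vs {b.chrom}"
        )
    inter = a.intersection_length(b)
    if denominator == "a":
        denom = a.length
    elif denominator == "b":
        denom = b.length
    elif denominator == "shorter":
        denom = min(a.length, b.length)
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown denominator {denominator!r}")
    return inter / denom


@dataclass(frozen=True)
class SpliceChain:
    """Ordered introns of a transcript, in transcription direction.

    Each intron is the half-open genomic interval ``(start, end)``.  The
    donor is the intron boundary adjacent to the upstream exon in
    transcription direction: ``start`` on "+", ``end`` on "-".
    """

    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.introns)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.introns)

    @property
    def is_empty(self) -> bool:
        return not self.introns

    def donor_positions(self) -> tuple[int, ...]:
        if self.strand == "+":
            return tuple(s for s, _ in self.introns)
        return tuple(e for _, e in self.introns)

    def acceptor_positions(self) -> tuple[int, ...]:
        if self.strand == "+":
            return tuple(e for _, e in self.introns)
        return tuple(s for s, _ in self.introns)

    def sites(self) -> tuple[int, ...]:
        """All splice-site boundary positions, genomically sorted."""
        out: list[int] = []
        for s, e in self.introns:
            out.extend((s, e))
        return tuple(sorted(out))


@dataclass(frozen=True)
class TranscriptModel:
    """An oriented exon-block chain on a chromosome."""

    id: str
    gene_id: str
    exons: tuple[GenomeInterval, ...]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        if strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: must be stranded")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != chrom or ex.strand != strand:
                raise ValueError(
                    f"transcript {self.id}: exons span chrom/strand boundaries"
                )
            if ex.start <= prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons unsorted or introns empty"
                )
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span_length(self) -> int:
        return self.exons[-1].end - self.exons[0].start

    def splice_chain(self) -> SpliceChain:
        return extract_junctions(self)

    def splice_sites(self) -> tuple[int, ...]:
        return self.splice_chain().sites()

    def first_exon(self) -> GenomeInterval:
        """5'-most exon in transcription direction."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def introns(self) -> tuple[GenomeInterval, ...]:
        return tuple(
            GenomeInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )


def extract_junctions(t: TranscriptModel) -> SpliceChain:
    """One intron per adjacent exon pair, ordered in transcription direction.

    Single-exon transcripts yield an empty chain.
    """
    genomic = tuple(
        (a.end, b.start) for a, b in zip(t.exons, t.exons[1:])
    )
    if t.strand == "-":
        genomic = tuple(reversed(genomic))
    return SpliceChain(t.chrom, t.strand, genomic)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned segment of a long read.

    ``pid`` is percent identity (100 x matches / aligned columns), carried
    as metadata from the upstream aligner.  ``coverage`` is the fraction
    of the read covered by this segment (query-fraction convention).
    Reads whose alignment splits across distant loci appear as several
    records sharing ``read_id`` with distinct ``segment_index``.
    """

    read_id: str
    blocks: TranscriptModel
    pid: float
    coverage: float
    segment_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pid <= 100.0:
            raise ValueError(f"pid out of range: {self.pid}")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"coverage out of range: {self.coverage}")


@dataclass
class Gene:
    """An annotated locus: interval plus its transcript models."""

    id: str
    interval: GenomeInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "coding"
    family: str | None = None


class Annotation:
    """A gene/transcript collection with overlap indexes."""

    def __init__(self, genes: Sequence[Gene]):
        from intervaltree import IntervalTree

        self.genes: list[Gene] = sorted(
            genes, key=lambda g: (g.interval.chrom, g.interval.start, g.id)
        )
        self._by_id = {g.id: g for g in self.genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.interval.chrom, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def get(self, gene_id: str) -> Gene | None:
        return self._by_id.get(gene_id)

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes for t in g.transcripts]

    def genes_overlapping(
        self, interval: GenomeInterval, strand: str | None = None
    ) -> list[Gene]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        if strand is not None:
            hits = [g for g in hits if g.interval.strand == strand]
        return sorted(hits, key=lambda g: (g.interval.start, g.id))

    def transcripts_overlapping(
        self, interval: GenomeInterval, strand: str | None = None
    ) -> list[TranscriptModel]:
        out = []
        for g in self.genes_overlapping(interval):
            for t in g.transcripts:
                if strand is not None and t.strand != strand:
                    continue
                if t.interval.overlaps(interval):
                    out.append(t)
        return out

    def intron_set(self) -> set[tuple[str, int, int]]:
        """All annotated introns as (chrom, start, end) keys."""
        out: set[tuple[str, int, int]] = set()
        for t in self.transcripts:
            for s, e in t.splice_chain().introns:
                out.add((t.chrom, s, e))
        return out
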
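"""Extraction and classification of alternative-splicing events.

For every pair of multi-exon isoforms at a locus, both splice chains
are projected onto the genome over their common span; maximal runs of
sites present in only one of the two chains, delimited by shared sites
(or by the common span boundaries), form the variation units.  Units
are deduplicated locus-wide by (flanks, variant chains), so the same
cassette exon seen in many isoform pairs counts once.

Each unit is matched against the five basic templates — exon skipping
(ES), intron retention (IR), alternative donor (AD), alternative
acceptor (AA) and mutually exclusive exons (MEE) — or labelled
``complex``.  A coordinate-free canonical code (donor "^", acceptor
"-", sites renumbered in transcription direction) identifies the
event's structural model; distinct codes are distinct "models".

Transcript termini act as sentinels: a unit whose delimiting boundary
is a shared terminus is closed; a boundary where the two termini
differ leaves the unit open-ended, and open-ended units only qualify
for the basic types where the template tolerates it (the non-variable
side of AD/AA).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .core import SpliceChain, TranscriptModel

__all__ = [
    "ASEvent",
    "pair_events",
    "extract_events",
    "classify_event",
    "model_code",
    "chromosome_correlation",
    "BASIC_TYPES",
]

DONOR = "^"
ACCEPTOR = "-"
BASIC_TYPES = ("ES", "IR", "AD", "AA", "MEE")

Site = tuple[int, str]  # (genomic position, role symbol)


def _chain_sites(chain: SpliceChain) -> set[Site]:
    out: set[Site] = set()
    for s, e in chain.introns:
        if chain.strand == "+":
            out.add((s, DONOR))
            out.add((e, ACCEPTOR))
        else:
            out.add((e, DONOR))
            out.add((s, ACCEPTOR))
    return out


@dataclass(frozen=True)
class ASEvent:
    """A variation unit between two splice-chain variants of one locus."""

    locus_id: str
    chrom: str
    strand: str
    flank_left: Site | None       # genomic-left delimiter; None = open
    flank_right: Site | None
    variant_a: tuple[Site, ...]   # genomic order
    variant_b: tuple[Site, ...]
    type: str = "unclassified"

    @property
    def key(self) -> tuple:
        return (
            self.flank_left,
            self.flank_right,
            frozenset((self.variant_a, self.variant_b)),
        )

    @property
    def open_ended(self) -> bool:
        return self.flank_left is None or self.flank_right is None


SENTINEL_START = "["
SENTINEL_END = "]"


def pair_events(
    t1: TranscriptModel, t2: TranscriptModel, locus_id: str = ""
) -> list[ASEvent]:
    """Variation units between one pair of multi-exon transcripts."""
    if t1.chrom != t2.chrom or t1.strand != t2.strand:
        raise ValueError("paired transcripts must share chromosome and strand")
    i1, i2 = t1.interval, t2.interval
    lo, hi = max(i1.start, i2.start), min(i1.end, i2.end)
    if lo >= hi:
        return []
    s1 = {s for s in _chain_sites(t1.splice_chain()) if lo < s[0] < hi}
    s2 = {s for s in _chain_sites(t2.splice_chain()) if lo < s[0] < hi}
    shared = s1 & s2
    merged = sorted(s1 | s2)

    left_closed = i1.start == i2.start
    right_closed = i1.end == i2.end
    left_sentinel: Site | None = (lo, SENTINEL_START) if left_closed else None
    right_sentinel: Site | None = (hi, SENTINEL_END) if right_closed else None

    events: list[ASEvent] = []
    run: list[Site] = []
    prev_flank = left_sentinel

    def flush(right_flank: Site | None) -> None:
        nonlocal run, prev_flank
        if run:
            va = tuple(s for s in run if s in s1)
            vb = tuple(s for s in run if s in s2)
            if va != vb:
                events.append(
                    ASEvent(
                        locus_id=locus_id,
                        chrom=t1.chrom,
                        strand=t1.strand,
                        flank_left=prev_flank,
                        flank_right=right_flank,
                        variant_a=va,
                        variant_b=vb,
                    )
                )
        run = []

    for site in merged:
        if site in shared:
            flush(site)
            prev_flank = site
        else:
            run.append(site)
    flush(right_sentinel)
    return [replace(e, type=classify_event(e)) for e in events]


def _transcription_order(sites: Sequence[Site], strand: str) -> tuple[Site, ...]:
    return tuple(sites) if strand == "+" else tuple(reversed(sites))


def _roles(sites: Sequence[Site]) -> tuple[str, ...]:
    return tuple(r for _, r in sites)


def classify_event(e: ASEvent) -> str:
    """Template match against the five basic models; else "complex"."""
    va = _transcription_order(e.variant_a, e.strand)
    vb = _transcription_order(e.variant_b, e.strand)
    # flanks in transcription direction
    if e.strand == "+":
        up_closed, down_closed = e.flank_left is not None, e.flank_right is not None
    else:
        up_closed, down_closed = e.flank_right is not None, e.flank_left is not None
    both_closed = up_closed and down_closed

    ra, rb = _roles(va), _roles(vb)
    internal_exon = (ACCEPTOR, DONOR)
    intron = (DONOR, ACCEPTOR)

    if both_closed:
        if (ra, rb) in (((), internal_exon), (internal_exon, ())):
            return "ES"
        if (ra, rb) in (((), intron), (intron, ())):
            return "IR"
        if ra == internal_exon and rb == internal_exon:
            ea = (min(p for p, _ in va), max(p for p, _ in va))
            eb = (min(p for p, _ in vb), max(p for p, _ in vb))
            if ea[1] <= eb[0] or eb[1] <= ea[0]:
                return "MEE"
            return "complex"
    if ra == (DONOR,) and rb == (DONOR,) and down_closed:
        return "AD"
    if ra == (ACCEPTOR,) and rb == (ACCEPTOR,) and up_closed:
        return "AA"
    return "complex"


def model_code(e: ASEvent) -> str:
    """Canonical coordinate-free code for the event's structure.

    Sites from both variants are pooled, renumbered 1..n in
    transcription direction, and written with their role symbol (donor
    "^", acceptor "-"); an empty variant is "0".  The two variant
    strings are joined by "," with the lexicographically smaller first,
    making the code invariant to genomic position, strand and pair
    order.
    """
    pooled = sorted(set(e.variant_a) | set(e.variant_b))
    ordered = _transcription_order(pooled, e.strand)
    number = {site: i + 1 for i, site in enumerate(ordered)}

    def chain_str(sites: Sequence[Site]) -> str:
        ts = _transcription_order(sites, e.strand)
        return "".join(f"{number[s]}{s[1]}" for s in ts) or "0"

    a, b = chain_str(e.variant_a), chain_str(e.variant_b)
    return ",".join(sorted((a, b)))


def extract_events(
    locus_isoforms: Sequence[TranscriptModel], locus_id: str | None = None
) -> list[ASEvent]:
    """All deduplicated variation units among a locus's multi-exon isoforms."""
    multi = [t for t in locus_isoforms if t.n_exons >= 2]
    if len(multi) < 2:
        return []
    if locus_id is None:
        locus_id = multi[0].gene_id
    seen: dict[tuple, ASEvent] = {}
    for t1, t2 in combinations(sorted(multi, key=lambda t: t.id), 2):
        for ev in pair_events(t1, t2, locus_id=locus_id):
            seen.setdefault(ev.key, ev)
    return sorted(
        seen.values(),
        key=lambda ev: (
            ev.variant_a[0][0] if ev.variant_a else ev.variant_b[0][0],
            ev.type,
        ),
    )


def events_for_annotation(
    isoforms_by_locus: Mapping[str, Sequence[TranscriptModel]]
) -> list[ASEvent]:
    out: list[ASEvent] = []
    for locus_id in sorted(isoforms_by_locus):
        out.extend(extract_events(isoforms_by_locus[locus_id], locus_id))
    return out


def type_counts(events: Iterable[ASEvent]) -> dict[str, int]:
    counts = {t: 0 for t in BASIC_TYPES}
    counts["complex"] = 0
    for e in events:
        counts[e.type] = counts.get(e.type, 0) + 1
    return counts


def chromosome_correlation(
    genes_per_chrom: Mapping[str, int], events_per_chrom: Mapping[str, int]
) -> float | None:
    """Pearson r between per-chromosome gene and AS-event counts.

    Returns None (reported as missing) when fewer than 3 chromosomes or
    when either vector has zero variance.
    """
    from scipy import stats

    chroms = sorted(set(genes_per_chrom) | set(events_per_chrom))
    if len(chroms) < 3:
        raise ValueError("chromosome correlation needs >= 3 chromosomes")
    x = [genes_per_chrom.get(c, 0) for c in chroms]
    y = [events_per_chrom.get(c, 0) for c in chroms]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r)
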
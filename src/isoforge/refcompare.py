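"""Comparison of collapsed isoforms against a reference annotation.

Full-length status grades a multi-exon isoform by how its splice-site
set relates to same-locus reference transcripts, from strictest to
weakest: same first and last splice sites; the reference's first and
last sites contained in the isoform's site set; same first site; the
reference's first site contained.  Because 3' integrity is guaranteed
by poly(A)-primed library construction, the full-length flag only
requires the "with 5' end" grade or better.

Novel genes are loci overlapping no annotated gene by 20% of the gene
span, or overlapping only antisense; novel isoforms at known loci are
called on a changed terminal 3' splice site or on a new intron/exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import Annotation, GenomeInterval, TranscriptModel, overlap_fraction

__all__ = [
    "FL_CATEGORIES",
    "NoveltyCall",
    "fl_status",
    "is_full_length",
    "call_novel_gene",
    "call_novel_isoform",
]

# ordered weakest -> strictest
FL_CATEGORIES = ["none", "with_5p", "same_5p", "with_5p3p", "same_5p3p"]
NOVEL_GENE_OVERLAP = 0.20


def _first_last_sites(t: TranscriptModel) -> tuple[int, int]:
    """(first, last) splice-site positions in transcription direction."""
    sites = t.splice_sites()
    if t.strand == "+":
        return sites[0], sites[-1]
    return sites[-1], sites[0]


def fl_status(
    isoform: TranscriptModel, ref_transcripts: Sequence[TranscriptModel]
) -> str:
    """Best (strictest) full-length category over same-locus references.

    Single-exon isoforms and references contribute no splice sites and
    grade "none".
    """
    if isoform.n_exons < 2:
        return "none"
    iso_sites = set(isoform.splice_sites())
    iso_first, iso_last = _first_last_sites(isoform)
    best = 0
    for ref in ref_transcripts:
        if ref.n_exons < 2 or ref.strand != isoform.strand or ref.chrom != isoform.chrom:
            continue
        ref_first, ref_last = _first_last_sites(ref)
        if iso_first == ref_first and iso_last == ref_last:
            grade = 4
        elif ref_first in iso_sites and ref_last in iso_sites:
            grade = 3
        elif iso_first == ref_first:
            grade = 2
        elif ref_first in iso_sites:
            grade = 1
        else:
            grade = 0
        best = max(best, grade)
    return FL_CATEGORIES[best]


def is_full_length(category: str) -> bool:
    return FL_CATEGORIES.index(category) >= FL_CATEGORIES.index("with_5p")


@dataclass(frozen=True)
class NoveltyCall:
    level: str                      # known_isoform | novel_isoform | novel_gene
    reasons: frozenset[str]


def call_novel_gene(
    locus_interval: GenomeInterval, annotation: Annotation
) -> NoveltyCall:
    """Novel when no annotated gene is hit by >= 20% of its span on the
    same strand (antisense-only overlap is still novel)."""
    best_same = 0.0
    best_anti = 0.0
    for gene in annotation.genes_overlapping(locus_interval):
        frac = overlap_fraction(locus_interval, gene.interval, denominator="b")
        if gene.interval.strand == locus_interval.strand:
            best_same = max(best_same, frac)
        else:
            best_anti = max(best_anti, frac)
    if best_same >= NOVEL_GENE_OVERLAP:
        return NoveltyCall("known_isoform", frozenset())
    reasons = set()
    if best_anti >= NOVEL_GENE_OVERLAP:
        reasons.add("antisense")
    else:
        reasons.add("low_overlap")
    return NoveltyCall("novel_gene", frozenset(reasons))


def call_novel_isoform(
    isoform: TranscriptModel, ref_transcripts: Sequence[TranscriptModel]
) -> NoveltyCall:
    """Novel-isoform call at a known locus.

    Novel iff the terminal 3' splice site differs from every reference
    transcript's, or the isoform carries an intron or exon absent from
    all of them (a retained reference intron inside an isoform exon
    counts as a new exon).
    """
    refs = [
        r
        for r in ref_transcripts
        if r.chrom == isoform.chrom and r.strand == isoform.strand
    ]
    if isoform.n_exons < 2:
        # no splice structure to compare; single-exon novelty is decided
        # at gene level
        return NoveltyCall("known_isoform", frozenset())
    iso_introns = set(isoform.splice_chain().introns)
    ref_introns = {i for r in refs for i in r.splice_chain().introns}
    ref_exons = [e for r in refs for e in r.exons]

    reasons: set[str] = set()

    _, iso_last = _first_last_sites(isoform)
    ref_lasts = {
        _first_last_sites(r)[1] for r in refs if r.n_exons >= 2
    }
    if ref_lasts and iso_last not in ref_lasts:
        reasons.add("changed_3p_last_site")

    if iso_introns - ref_introns:
        reasons.add("new_intron_or_exon")
    else:
        for ex in isoform.exons:
            retained = any(
                ex.contains(GenomeInterval(isoform.chrom, s, e, isoform.strand))
                for s, e in ref_introns
            )
            exon_overlap = any(ex.overlaps(re) for re in ref_exons)
            if retained or not exon_overlap:
                reasons.add("new_intron_or_exon")
                break

    if reasons:
        return NoveltyCall("novel_isoform", frozenset(reasons))
    return NoveltyCall("known_isoform", frozenset())
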
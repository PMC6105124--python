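"""ORF-length filtering and positional classification of lncRNA candidates.

A candidate passes the coding filter when its longest forward-frame ORF
is at most 100 amino acids (start codon counted, stop codon required
and excluded).  Candidates are then placed relative to protein-coding
annotation into five positional classes, evaluated in priority order:
sense (exonic overlap, same strand), antisense (exonic overlap,
opposite strand), intronic (inside a coding gene with no exonic
overlap), bidirectional (transcription start within a window of a
coding TSS on the opposite strand, head-to-head), else intergenic.

External coding-potential models and homology screens are out of band:
``apply_external_screen`` accepts a precomputed keep/drop list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import Annotation, GenomeInterval, TranscriptModel

__all__ = [
    "LncRNAParams",
    "LncRNACandidate",
    "longest_orf",
    "classify_position",
    "evaluate_candidates",
    "apply_external_screen",
    "transcript_sequence",
    "POSITION_CLASSES",
]

POSITION_CLASSES = ("sense", "antisense", "intronic", "bidirectional", "intergenic")
STOP_CODONS = {"TAA", "TAG", "TGA"}
MAX_ORF_AA = 100

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LncRNAParams:
    max_orf_aa: int = MAX_ORF_AA
    bidirectional_window: int = 1000


@dataclass
class LncRNACandidate:
    transcript: TranscriptModel
    sequence: str
    longest_orf_aa: int
    passes_orf_filter: bool
    position_class: str


def longest_orf(seq: str) -> int:
    """Length (aa) of the longest ATG..stop ORF over the three forward frames.

    The stop codon is required and excluded from the length; the start
    codon is counted.  Sequences without a complete ORF return 0.
    Reverse-strand frames are not scanned: transcript sequences arrive
    already oriented.
    """
    s = seq.upper()
    if set(s) - set("ACGTN"):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"non-ACGTN symbols in sequence: {bad}")
    best = 0
    n = len(s)
    for frame in range(3):
        i = frame
        open_starts: list[int] = []
        while i + 3 <= n:
            codon = s[i : i + 3]
            if codon == "ATG" and not open_starts:
                open_starts.append(i)
            elif codon in STOP_CODONS and open_starts:
                best = max(best, (i - open_starts[0]) // 3)
                open_starts = []
            i += 3
    return best


def transcript_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced sequence in transcription orientation."""
    chrom_seq = genome[t.chrom]
    s = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return reverse_complement(s) if t.strand == "-" else s


def _tss(t: TranscriptModel) -> int:
    return t.interval.start if t.strand == "+" else t.interval.end


def classify_position(
    candidate: TranscriptModel,
    annotation: Annotation,
    params: LncRNAParams = LncRNAParams(),
) -> str:
    """Position of a candidate relative to coding genes (priority order)."""
    iv = candidate.interval
    coding_genes = [
        g for g in annotation.genes_overlapping(iv) if g.biotype == "coding"
    ]
    coding_transcripts = [t for g in coding_genes for t in g.transcripts]

    def exonic_overlap(strand_match: bool) -> bool:
        for t in coding_transcripts:
            if (t.strand == candidate.strand) != strand_match:
                continue
            for ex in t.exons:
                if any(ce.overlaps(ex) for ce in candidate.exons):
                    return True
        return False

    if exonic_overlap(strand_match=True):
        return "sense"
    if exonic_overlap(strand_match=False):
        return "antisense"
    for g in coding_genes:
        if g.interval.contains(iv):
            return "intronic"
    # bidirectional: head-to-head promoters within the window, no overlap
    tss = _tss(candidate)
    for g in annotation.genes:
        if g.biotype != "coding" or g.interval.chrom != iv.chrom:
            continue
        if g.interval.strand == candidate.strand:
            continue
        for t in g.transcripts or [None]:
            gene_tss = (
                g.interval.start if g.interval.strand == "+" else g.interval.end
            )
            if abs(tss - gene_tss) <= params.bidirectional_window:
                return "bidirectional"
    return "intergenic"


def evaluate_candidates(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    annotation: Annotation,
    params: LncRNAParams = LncRNAParams(),
) -> list[LncRNACandidate]:
    out = []
    for t in transcripts:
        seq = transcript_sequence(t, genome)
        orf = longest_orf(seq)
        out.append(
            LncRNACandidate(
                transcript=t,
                sequence=seq,
                longest_orf_aa=orf,
                passes_orf_filter=orf <= params.max_orf_aa,
                position_class=classify_position(t, annotation, params),
            )
        )
    return out


def apply_external_screen(
    candidates: Sequence[LncRNACandidate], keep_ids: Iterable[str] | None
) -> list[LncRNACandidate]:
    """Hook for external homology / coding-potential screens.

    ``keep_ids`` is a precomputed whitelist (e.g. from a BLAST run done
    elsewhere); None means no screen and everything is kept.
    """
    if keep_ids is None:
        return list(candidates)
    keep = set(keep_ids)
    return [c for c in candidates if c.transcript.id in keep]
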
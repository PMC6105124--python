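"""Fusion-transcript detection from multi-segment long-read alignments.

A read whose spliced alignment splits across distant annotated loci is
a fusion candidate.  A call requires all five criteria:

(i)   segments map to two or more annotated loci;
(ii)  each locus receives at least ``min_locus_fraction`` of the read;
(iii) the combined aligned fraction reaches ``min_combined_coverage``;
(iv)  every locus pair is at least ``min_distance_bp`` apart (nearest
      gene boundaries; inter-chromosomal pairs count as apart);
(v)   at least ``min_support`` short reads span the fusion junction(s).

Calls sharing an identical precursor locus set group into fusion loci.
The family analysis flags calls whose precursor genes all share a gene-
family label; genes without a family label drop the call from the
denominator, mirroring the exclusion of unannotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .core import AlignmentRecord, Annotation, Gene
from .express import percent

__all__ = ["FusionParams", "FusionCall", "detect_fusions", "family_analysis", "group_fusion_loci"]


@dataclass(frozen=True)
class FusionParams:
    min_locus_fraction: float = 0.10
    min_combined_coverage: float = 0.99
    min_distance_bp: int = 10_000
    min_support: int = 2


@dataclass
class FusionCall:
    read_id: str
    segments: list[AlignmentRecord]
    precursor_loci: tuple[str, ...]            # annotated gene ids, genomic order
    per_locus_fraction: dict[str, float]
    combined_coverage: float
    min_pairwise_distance_bp: int | None       # None for inter-chromosomal pairs
    support_reads: int
    same_family: bool | None = None            # None when a precursor lacks a label


def _best_gene(segment: AlignmentRecord, annotation: Annotation) -> Gene | None:
    """Annotated gene with the largest overlap with the segment's span."""
    iv = segment.blocks.interval
    best, best_bp = None, 0
    for gene in annotation.genes_overlapping(iv, strand=iv.strand):
        bp = iv.intersection_length(gene.interval)
        if bp > best_bp:
            best, best_bp = gene, bp
    return best


def _pair_distance(a: Gene, b: Gene) -> int | None:
    if a.interval.chrom != b.interval.chrom:
        return None
    if a.interval.overlaps(b.interval):
        return 0
    return max(a.interval.start, b.interval.start) - min(a.interval.end, b.interval.end)


def _fusion_junctions(segments: Sequence[AlignmentRecord]) -> list[tuple[str, int, int]]:
    """Genomic gaps between consecutive segments (read order), same-chrom only."""
    ordered = sorted(segments, key=lambda s: s.segment_index)
    out = []
    for s1, s2 in zip(ordered, ordered[1:]):
        if s1.blocks.chrom != s2.blocks.chrom:
            continue
        a, b = sorted([s1.blocks.interval, s2.blocks.interval], key=lambda iv: iv.start)
        if a.end < b.start:
            out.append((s1.blocks.chrom, a.end, b.start))
    return out


def detect_fusions(
    alignments: Sequence[AlignmentRecord],
    annotation: Annotation,
    junction_support: pd.DataFrame | None = None,
    params: FusionParams = FusionParams(),
) -> list[FusionCall]:
    """Apply the five fusion criteria to every multi-segment read."""
    supported_counts: dict[tuple[str, int, int], int] = {}
    if junction_support is not None and len(junction_support):
        agg = junction_support.groupby(["chrom", "intron_start", "intron_end"])[
            "read_count"
        ].sum()
        supported_counts = {
            (str(c), int(s), int(e)): int(n) for (c, s, e), n in agg.items()
        }

    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_read.setdefault(rec.read_id, []).append(rec)

    calls: list[FusionCall] = []
    for read_id in sorted(by_read):
        segments = sorted(by_read[read_id], key=lambda s: s.segment_index)
        if len(segments) < 2:
            continue
        frac: dict[str, float] = {}
        genes: dict[str, Gene] = {}
        unassigned = False
        for seg in segments:
            gene = _best_gene(seg, annotation)
            if gene is None:
                unassigned = True
                break
            frac[gene.id] = frac.get(gene.id, 0.0) + seg.coverage
            genes[gene.id] = gene
        if unassigned or len(genes) < 2:                 # criterion (i)
            continue
        if any(f < params.min_locus_fraction for f in frac.values()):   # (ii)
            continue
        combined = sum(seg.coverage for seg in segments)
        if combined < params.min_combined_coverage:      # criterion (iii)
            continue
        distances = [
            _pair_distance(a, b) for a, b in combinations(genes.values(), 2)
        ]
        finite = [d for d in distances if d is not None]
        if any(d < params.min_distance_bp for d in finite):             # (iv)
            continue
        junctions = _fusion_junctions(segments)
        support = min(
            (supported_counts.get(j, 0) for j in junctions), default=0
        )
        if support < params.min_support:                 # criterion (v)
            continue
        ordered_loci = tuple(
            g.id
            for g in sorted(genes.values(), key=lambda g: (g.interval.chrom, g.interval.start))
        )
        calls.append(
            FusionCall(
                read_id=read_id,
                segments=segments,
                precursor_loci=ordered_loci,
                per_locus_fraction=frac,
                combined_coverage=combined,
                min_pairwise_distance_bp=min(finite) if finite else None,
                support_reads=support,
            )
        )
    return calls


def group_fusion_loci(calls: Sequence[FusionCall]) -> dict[tuple[str, ...], list[FusionCall]]:
    """Cluster calls into fusion loci by identical precursor locus sets."""
    out: dict[tuple[str, ...], list[FusionCall]] = {}
    for c in calls:
        out.setdefault(c.precursor_loci, []).append(c)
    return out


def family_analysis(
    calls: Sequence[FusionCall], annotation: Annotation
) -> dict:
    """Flag same-family fusions and summarise their share.

    A call is same-family when every precursor gene carries the same
    family label.  Calls with any unlabelled precursor are excluded
    from the denominator.
    """
    n_same = 0
    n_annotated = 0
    for call in calls:
        families = [
            (annotation.get(g).family if annotation.get(g) else None)
            for g in call.precursor_loci
        ]
        if any(f is None for f in families):
            call.same_family = None
            continue
        call.same_family = len(set(families)) == 1
        n_annotated += 1
        n_same += call.same_family
    return {
        "n_calls": len(calls),
        "n_with_annotated_families": n_annotated,
        "n_same_family": n_same,
        "same_family_percent": percent(n_same, n_annotated) if n_annotated else None,
    }
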
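"""End-to-end orchestration of the survey stages.

``run_survey`` wires the stages together the way the individual CLI
commands would be chained by hand: classify raw reads, keep FLNC and
5'-truncated single-segment alignments for collapsing (truncated reads
carry the flag the artifact filter needs), route multi-segment reads
to fusion detection, then compare collapsed isoforms against the
reference, extract AS events, call expression from junction support
and assemble the summary arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import readclass as rc
from .asevents import ASEvent, extract_events, type_counts
from .collapse import IsoformCluster, Locus, RemovalRecord, collapse_alignments
from .core import AlignmentRecord, Annotation, GenomeInterval
from .express import build_expression_matrix, summary_report
from .fusion import FusionCall, FusionParams, detect_fusions, family_analysis
from .refcompare import NoveltyCall, call_novel_gene, call_novel_isoform, fl_status

__all__ = ["SurveyOutputs", "run_survey"]


@dataclass
class SurveyOutputs:
    classified: dict[str, tuple[str, rc.ReadSignals]]
    read_summary: rc.ReadClassSummary
    clusters: list[IsoformCluster]
    removals: list[RemovalRecord]
    loci: list[Locus]
    isoforms_by_locus: dict[str, list]
    locus_novelty: dict[str, NoveltyCall]
    fl_status_by_isoform: dict[str, str]
    isoform_novelty: dict[str, NoveltyCall]
    events: list[ASEvent]
    event_type_counts: dict[str, int]
    fusion_calls: list[FusionCall]
    family_summary: dict
    expression: pd.DataFrame
    excluded_single_exon: list[str]
    summary: dict = field(default_factory=dict)


def _locus_interval(clusters: Sequence[IsoformCluster]) -> GenomeInterval:
    reps = [c.representative for c in clusters]
    return GenomeInterval(
        reps[0].chrom,
        min(r.interval.start for r in reps),
        max(r.interval.end for r in reps),
        reps[0].strand,
    )


def run_survey(
    reads: Mapping[str, str],
    alignments: Sequence[AlignmentRecord],
    annotation: Annotation,
    junction_support: pd.DataFrame,
    primer_5p: str,
    primer_3p: str,
    samples: Sequence[str] | None = None,
    signal_params: rc.SignalParams = rc.SignalParams(),
    fusion_params: FusionParams = FusionParams(),
) -> SurveyOutputs:
    classified = rc.classify_reads(reads, primer_5p, primer_3p, signal_params)
    read_summary = rc.summarize(classified)
    truncated = {r for r, (cat, _) in classified.items() if cat == "partial_5p"}
    usable = {r for r, (cat, _) in classified.items() if cat == "FLNC"} | truncated

    n_segments: dict[str, int] = {}
    for a in alignments:
        n_segments[a.read_id] = max(n_segments.get(a.read_id, 0), a.segment_index + 1)
    single = [
        a for a in alignments if n_segments[a.read_id] == 1 and a.read_id in usable
    ]
    multi = [a for a in alignments if n_segments[a.read_id] > 1]

    clusters, removals, loci = collapse_alignments(
        single, annotation, junction_support, truncated
    )

    isoforms_by_locus: dict[str, list] = {}
    for c in clusters:
        isoforms_by_locus.setdefault(c.locus_id, []).append(c.representative)

    locus_novelty: dict[str, NoveltyCall] = {}
    fl_by_iso: dict[str, str] = {}
    iso_novelty: dict[str, NoveltyCall] = {}
    for locus_id, isoforms in isoforms_by_locus.items():
        interval = _locus_interval(
            [c for c in clusters if c.locus_id == locus_id]
        )
        locus_novelty[locus_id] = call_novel_gene(interval, annotation)
        refs = annotation.transcripts_overlapping(interval)
        for iso in isoforms:
            fl_by_iso[iso.id] = fl_status(iso, refs)
            if locus_novelty[locus_id].level == "novel_gene":
                iso_novelty[iso.id] = locus_novelty[locus_id]
            else:
                iso_novelty[iso.id] = call_novel_isoform(iso, refs)

    events: list[ASEvent] = []
    for locus_id in sorted(isoforms_by_locus):
        events.extend(extract_events(isoforms_by_locus[locus_id], locus_id))
    ev_counts = type_counts(events)

    fusion_calls = detect_fusions(multi, annotation, junction_support, fusion_params)
    family = family_analysis(fusion_calls, annotation)

    all_isoforms = [i for isos in isoforms_by_locus.values() for i in isos]
    expression, excluded = build_expression_matrix(
        all_isoforms, junction_support, samples=samples
    )

    n_isoforms = len(all_isoforms)
    n_single = sum(1 for i in all_isoforms if i.n_exons == 1)
    as_loci = {e.locus_id for e in events}
    as_isoforms = [
        i
        for lid in as_loci
        for i in isoforms_by_locus[lid]
        if i.n_exons >= 2
    ]
    n_basic = sum(v for k, v in ev_counts.items() if k != "complex")
    summary = summary_report(
        {
            "n_isoforms": n_isoforms,
            "n_single_exon_isoforms": n_single,
            "n_loci": len(isoforms_by_locus),
            "n_as_loci": len(as_loci),
            "n_as_isoforms": len(as_isoforms),
            "n_events": len(events),
            "n_basic_events": n_basic,
            "n_fusion_annotated": family["n_with_annotated_families"],
            "n_fusion_same_family": family["n_same_family"],
        }
    )
    summary.update(
        {
            "n_loci": len(isoforms_by_locus),
            "n_isoforms": n_isoforms,
            "n_events": len(events),
            "n_fusion_calls": len(fusion_calls),
            "n_novel_gene_loci": sum(
                1 for v in locus_novelty.values() if v.level == "novel_gene"
            ),
        }
    )
    return SurveyOutputs(
        classified=classified,
        read_summary=read_summary,
        clusters=clusters,
        removals=removals,
        loci=loci,
        isoforms_by_locus=isoforms_by_locus,
        locus_novelty=locus_novelty,
        fl_status_by_isoform=fl_by_iso,
        isoform_novelty=iso_novelty,
        events=events,
        event_type_counts=ev_counts,
        fusion_calls=fusion_calls,
        family_summary=family,
        expression=expression,
        excluded_single_exon=excluded,
        summary=summary,
    )
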
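"""Cluster aligned full-length reads into loci and isoforms.

Two aligned reads belong to the same locus when they overlap by at
least 20% of the shorter read's span and at least one exon pair
overlaps by more than 20% of the shorter exon, on the same strand; the
locus relation is the transitive closure of this pairwise rule.  Within
a locus, single-exon reads merge by any overlap and multi-exon reads
merge by exact splice-chain identity; each cluster is represented by
its longest member.

Artifact filtering removes (a) clusters supported only by 5'-truncated
reads (unless the 5' exon spans an annotated intron, which is genuine
retention evidence), (b) clusters whose splice-site set is a proper
subset of another cluster in the same locus (5'-degraded fragments),
and (c) low-identity singleton clusters with an unvalidated junction.

Locus ids follow the "chrom.ordinal" scheme and isoforms
"chrom.ordinal.k", numbered in genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    AlignmentRecord,
    Annotation,
    GenomeInterval,
    TranscriptModel,
    overlap_fraction,
)

__all__ = [
    "Locus",
    "IsoformCluster",
    "RemovalRecord",
    "same_locus",
    "assign_loci",
    "merge_isoforms",
    "filter_artifacts",
    "collapse_alignments",
]

LOCUS_OVERLAP_MIN = 0.20       # >= on span overlap ("overlapped 20%")
EXON_OVERLAP_MIN = 0.20        # >  on exon overlap ("more than 20%")
LOW_PID_THRESHOLD = 99.0
MIN_READS_LOW_PID = 2


@dataclass
class Locus:
    id: str
    interval: GenomeInterval
    strand: str
    members: list[AlignmentRecord] = field(default_factory=list)


@dataclass
class IsoformCluster:
    id: str
    locus_id: str
    representative: TranscriptModel
    member_read_ids: list[str]
    n_reads: int
    min_pid: float

    @property
    def chain(self):
        return self.representative.splice_chain()

    @property
    def site_set(self) -> frozenset[int]:
        return frozenset(self.representative.splice_sites())


@dataclass
class RemovalRecord:
    cluster_id: str
    locus_id: str
    reason: str
    member_read_ids: list[str]


def same_locus(a: AlignmentRecord, b: AlignmentRecord) -> bool:
    """The pairwise locus rule (span >= 20% of shorter, exon > 20% of shorter)."""
    ta, tb = a.blocks, b.blocks
    if ta.chrom != tb.chrom or ta.strand != tb.strand:
        return False
    if not ta.interval.overlaps(tb.interval):
        return False
    if overlap_fraction(ta.interval, tb.interval, "shorter") < LOCUS_OVERLAP_MIN:
        return False
    for ea in ta.exons:
        for eb in tb.exons:
            if ea.overlaps(eb) and overlap_fraction(ea, eb, "shorter") > EXON_OVERLAP_MIN:
                return True
    return False


class _UnionFind:
    def __init__(self, n: int):
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


def assign_loci(alignments: Sequence[AlignmentRecord]) -> list[Locus]:
    """Transitive closure of the pairwise rule, strand-separated.

    Expects single-segment records only; multi-segment reads are fusion
    candidates and must be routed to the fusion detector instead.
    """
    multi = [r.read_id for r in alignments if r.segment_index != 0]
    if multi:
        raise ValueError(
            f"multi-segment alignments passed to assign_loci (e.g. {multi[0]}); "
            "route them to fusion detection"
        )
    loci: list[Locus] = []
    groups: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in alignments:
        groups.setdefault((rec.blocks.chrom, rec.blocks.strand), []).append(rec)

    raw: list[tuple[str, list[AlignmentRecord]]] = []
    for (chrom, strand), recs in groups.items():
        recs = sorted(recs, key=lambda r: (r.blocks.interval.start, r.read_id))
        uf = _UnionFind(len(recs))
        # only overlapping pairs can satisfy the rule; sweep on sorted starts
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if recs[j].blocks.interval.start >= recs[i].blocks.interval.end:
                    break
                if same_locus(recs[i], recs[j]):
                    uf.union(i, j)
        comp: dict[int, list[AlignmentRecord]] = {}
        for i, rec in enumerate(recs):
            comp.setdefault(uf.find(i), []).append(rec)
        for members in comp.values():
            raw.append((chrom, members))

    # number loci chrom.ordinal in genomic order, strands interleaved
    by_chrom: dict[str, list[list[AlignmentRecord]]] = {}
    for chrom, members in raw:
        by_chrom.setdefault(chrom, []).append(members)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda ms: min(m.blocks.interval.start for m in ms))
    for chrom in sorted(by_chrom):
        for k, members in enumerate(by_chrom[chrom], 1):
            start = min(m.blocks.interval.start for m in members)
            end = max(m.blocks.interval.end for m in members)
            strand = members[0].blocks.strand
            loci.append(
                Locus(
                    id=f"{chrom}.{k}",
                    interval=GenomeInterval(chrom, start, end, strand),
                    strand=strand,
                    members=sorted(
                        members, key=lambda m: (m.blocks.interval.start, m.read_id)
                    ),
                )
            )
    return loci


def _cluster_single_exon(members: list[AlignmentRecord]) -> list[list[AlignmentRecord]]:
    """Single-exon reads cluster by any overlap (transitive)."""
    members = sorted(members, key=lambda m: (m.blocks.interval.start, m.read_id))
    out: list[list[AlignmentRecord]] = []
    cur: list[AlignmentRecord] = []
    cur_end = -1
    for m in members:
        iv = m.blocks.interval
        if cur and iv.start < cur_end:
            cur.append(m)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                out.append(cur)
            cur = [m]
            cur_end = iv.end
    if cur:
        out.append(cur)
    return out


def merge_isoforms(locus: Locus) -> list[IsoformCluster]:
    """Collapse locus members into isoform clusters.

    Multi-exon members require exact splice-chain identity; single-exon
    members merge by overlap.  The representative is the longest member
    (span length), relabelled "locus.k" in genomic order.
    """
    single = [m for m in locus.members if m.blocks.n_exons == 1]
    multi = [m for m in locus.members if m.blocks.n_exons > 1]

    grouped: list[list[AlignmentRecord]] = _cluster_single_exon(single)
    by_chain: dict[tuple, list[AlignmentRecord]] = {}
    for m in multi:
        key = (m.blocks.chrom, m.blocks.strand, m.blocks.splice_chain().introns)
        by_chain.setdefault(key, []).append(m)
    grouped.extend(by_chain[k] for k in sorted(by_chain))

    clusters: list[IsoformCluster] = []
    reps = []
    for members in grouped:
        rep = max(members, key=lambda m: (m.blocks.span_length, m.read_id))
        reps.append((rep, members))
    reps.sort(key=lambda rm: (rm[0].blocks.interval.start, rm[0].blocks.interval.end))
    for k, (rep, members) in enumerate(reps, 1):
        cid = f"{locus.id}.{k}"
        rep_model = TranscriptModel(
            cid, locus.id, rep.blocks.exons, biotype=rep.blocks.biotype
        )
        clusters.append(
            IsoformCluster(
                id=cid,
                locus_id=locus.id,
                representative=rep_model,
                member_read_ids=sorted(m.read_id for m in members),
                n_reads=len(members),
                min_pid=min(m.pid for m in members),
            )
        )
    return clusters


def _spans_annotated_intron(
    cluster: IsoformCluster, annotation: Annotation | None
) -> bool:
    """True when the cluster's 5' exon fully covers an annotated intron."""
    if annotation is None:
        return False
    first = cluster.representative.first_exon()
    for t in annotation.transcripts_overlapping(
        cluster.representative.interval, strand=cluster.representative.strand
    ):
        for intron in t.introns():
            if first.contains(intron):
                return True
    return False


def filter_artifacts(
    clusters: Sequence[IsoformCluster],
    annotation: Annotation | None = None,
    junction_support: pd.DataFrame | None = None,
    truncated_read_ids: Iterable[str] = (),
    min_support_reads: int = 1,
) -> tuple[list[IsoformCluster], list[RemovalRecord]]:
    """Apply the redundancy / false-positive filters.

    Removal reasons: ``truncated_5p`` (all members flagged 5'-truncated,
    no annotated-intron rescue), ``subset_structure`` (splice-site set a
    proper subset of a sibling cluster's), ``low_pid_unsupported``
    (min PID < 99, a single read, and a junction neither annotated nor
    supported by short reads).  Without read flags the truncation filter
    degrades to subset removal only.
    """
    truncated = set(truncated_read_ids)
    annotated_introns = annotation.intron_set() if annotation is not None else set()
    supported: set[tuple[str, int, int]] = set()
    if junction_support is not None and len(junction_support):
        ok = junction_support[junction_support["read_count"] >= min_support_reads]
        supported = set(
            zip(ok["chrom"], ok["intron_start"].astype(int), ok["intron_end"].astype(int))
        )

    removals: list[RemovalRecord] = []
    kept: list[IsoformCluster] = []

    # (a) 5'-truncation flags, with the spanned-intron rescue
    stage_a: list[IsoformCluster] = []
    for c in clusters:
        if truncated and all(r in truncated for r in c.member_read_ids):
            if not _spans_annotated_intron(c, annotation):
                removals.append(
                    RemovalRecord(c.id, c.locus_id, "truncated_5p", c.member_read_ids)
                )
                continue
        stage_a.append(c)

    # (b) 5'-degraded structures within each locus: a multi-exon cluster
    #     whose intron chain is a proper 5' suffix of a sibling's chain
    #     (in transcription direction) is the signature of a read missing
    #     its 5' end.  A variant that merely lacks an internal intron
    #     (e.g. intron retention) introduces no such suffix and is kept.
    by_locus: dict[str, list[IsoformCluster]] = {}
    for c in stage_a:
        by_locus.setdefault(c.locus_id, []).append(c)
    stage_b: list[IsoformCluster] = []
    for locus_id in sorted(by_locus):
        sibs = sorted(
            by_locus[locus_id], key=lambda c: (-len(c.chain.introns), c.id)
        )
        survivors: list[IsoformCluster] = []
        for c in sibs:
            chain = c.chain.introns
            if chain and any(
                len(k.chain.introns) > len(chain)
                and k.chain.introns[len(k.chain.introns) - len(chain):] == chain
                for k in survivors
            ):
                removals.append(
                    RemovalRecord(c.id, locus_id, "subset_structure", c.member_read_ids)
                )
            else:
                survivors.append(c)
        stage_b.extend(survivors)

    # (c) low-identity singletons lacking junction validation
    for c in sorted(stage_b, key=lambda c: c.id):
        if c.min_pid < LOW_PID_THRESHOLD and c.n_reads < MIN_READS_LOW_PID:
            chrom = c.representative.chrom
            junctions = [
                (chrom, s, e) for s, e in c.representative.splice_chain().introns
            ]
            bad = [
                j for j in junctions if j not in annotated_introns and j not in supported
            ]
            if bad:
                removals.append(
                    RemovalRecord(c.id, c.locus_id, "low_pid_unsupported", c.member_read_ids)
                )
                continue
        kept.append(c)
    return kept, removals


def collapse_alignments(
    alignments: Sequence[AlignmentRecord],
    annotation: Annotation | None = None,
    junction_support: pd.DataFrame | None = None,
    truncated_read_ids: Iterable[str] = (),
) -> tuple[list[IsoformCluster], list[RemovalRecord], list[Locus]]:
    """End-to-end collapse: loci -> isoform clusters -> artifact filter."""
    loci = assign_loci(alignments)
    clusters = [c for locus in loci for c in merge_isoforms(locus)]
    kept, removals = filter_artifacts(
        clusters, annotation, junction_support, truncated_read_ids
    )
    return kept, removals, loci
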
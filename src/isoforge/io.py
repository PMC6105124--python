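"""Readers and writers for the external formats the pipeline touches.

FASTA (genome, reads) via Biopython; GFF3 (annotation, collapsed
isoforms) via gffutils; BED12 (alignment block chains) and the two TSV
tables (per-cytosine methylation calls, per-sample junction support) via
pandas.  All writers emit deterministic column order and sorting, so
``write(read(f))`` round-trips byte-identically on files this package
wrote.

GFF3 is 1-based closed on disk and converted to the internal 0-based
half-open convention on read.  The BED12 score column carries percent
identity x 10 as an integer; the name column carries
``read_id;seg=<k>;cov=<fraction>`` so that a spliced alignment record
survives the round trip.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    AlignmentRecord,
    Annotation,
    Gene,
    GenomeInterval,
    TranscriptModel,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed12",
    "write_bed12",
    "read_methylation_tsv",
    "write_methylation_tsv",
    "read_junction_support_tsv",
    "write_junction_support_tsv",
]

TRANSCRIPT_FEATURES = {"mRNA", "transcript"}

METHYL_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]
SUPPORT_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "read_count", "sample"]


class GFF3ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | os.PathLike) -> Annotation:
    """Parse a gene/transcript/exon GFF3 file into an :class:`Annotation`.

    Raises :class:`GFF3ParseError` when a Parent reference cannot be
    resolved (naming the offending feature) or when an exon falls outside
    its transcript's span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = {f.id for f in db.all_features()}
    genes: dict[str, Gene] = {}
    for gf in db.features_of_type("gene"):
        interval = GenomeInterval(gf.seqid, gf.start - 1, gf.end, gf.strand)
        genes[gf.id] = Gene(
            id=gf.id,
            interval=interval,
            biotype=gf.attributes.get("biotype", ["coding"])[0],
            family=(gf.attributes.get("family") or [None])[0],
        )

    for ftype in sorted(TRANSCRIPT_FEATURES):
        for tf in db.features_of_type(ftype):
            parents = tf.attributes.get("Parent", [])
            if not parents or parents[0] not in known_ids:
                raise GFF3ParseError(
                    f"transcript {tf.id!r}: unresolvable Parent {parents!r}"
                )
            gene = genes.get(parents[0])
            if gene is None:
                raise GFF3ParseError(
                    f"transcript {tf.id!r}: Parent {parents[0]!r} is not a gene"
                )
            exons = []
            for ef in db.children(tf, featuretype="exon", order_by="start"):
                exons.append(
                    GenomeInterval(ef.seqid, ef.start - 1, ef.end, ef.strand)
                )
            if not exons:
                raise GFF3ParseError(f"transcript {tf.id!r}: no exon children")
            span = GenomeInterval(tf.seqid, tf.start - 1, tf.end, tf.strand)
            for ex in exons:
                if ex.start < span.start or ex.end > span.end:
                    raise GFF3ParseError(
                        f"transcript {tf.id!r}: exon [{ex.start},{ex.end}) "
                        f"outside transcript span [{span.start},{span.end})"
                    )
            biotype = (tf.attributes.get("biotype") or [gene.biotype])[0]
            gene.transcripts.append(
                TranscriptModel(tf.id, gene.id, tuple(exons), biotype=biotype)
            )
    # exons whose Parent is missing entirely
    for ef in db.features_of_type("exon"):
        parents = ef.attributes.get("Parent", [])
        if not parents or parents[0] not in known_ids:
            raise GFF3ParseError(
                f"exon at {ef.seqid}:{ef.start}-{ef.end}: unresolvable Parent {parents!r}"
            )
    return Annotation(list(genes.values()))


def _fmt_attrs(pairs: Sequence[tuple[str, str | None]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs if v is not None)


def write_gff3(annotation: Annotation, path: str | os.PathLike) -> None:
    """Write an annotation with deterministic ordering (chrom, start, id)."""
    lines = ["##gff-version 3"]
    for gene in annotation:
        gi = gene.interval
        lines.append(
            "\t".join(
                [
                    gi.chrom,
                    "isoforge",
                    "gene",
                    str(gi.start + 1),
                    str(gi.end),
                    ".",
                    gi.strand,
                    ".",
                    _fmt_attrs(
                        [("ID", gene.id), ("biotype", gene.biotype), ("family", gene.family)]
                    ),
                ]
            )
        )
        for t in sorted(gene.transcripts, key=lambda t: (t.interval.start, t.id)):
            ti = t.interval
            lines.append(
                "\t".join(
                    [
                        ti.chrom,
                        "isoforge",
                        "mRNA",
                        str(ti.start + 1),
                        str(ti.end),
                        ".",
                        ti.strand,
                        ".",
                        _fmt_attrs([("ID", t.id), ("Parent", gene.id), ("biotype", t.biotype)]),
                    ]
                )
            )
            for k, ex in enumerate(t.exons, 1):
                lines.append(
                    "\t".join(
                        [
                            ex.chrom,
                            "isoforge",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            ex.strand,
                            ".",
                            _fmt_attrs([("ID", f"{t.id}.exon{k}"), ("Parent", t.id)]),
                        ]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def transcripts_to_annotation(transcripts: Iterable[TranscriptModel]) -> Annotation:
    """Group bare transcript models into single- or multi-transcript genes."""
    genes: dict[str, Gene] = {}
    for t in transcripts:
        g = genes.get(t.gene_id)
        if g is None:
            g = Gene(id=t.gene_id, interval=t.interval, biotype=t.biotype)
            genes[t.gene_id] = g
        g.transcripts.append(t)
        gi = g.interval
        g.interval = GenomeInterval(
            gi.chrom,
            min(gi.start, t.interval.start),
            max(gi.end, t.interval.end),
            gi.strand,
        )
    return Annotation(list(genes.values()))


# ---------------------------------------------------------------------------
# BED12

def write_bed12(records: Sequence[AlignmentRecord], path: str | os.PathLike) -> None:
    rows = []
    for rec in sorted(
        records, key=lambda r: (r.blocks.chrom, r.blocks.interval.start, r.read_id, r.segment_index)
    ):
        iv = rec.blocks.interval
        sizes = ",".join(str(len(e)) for e in rec.blocks.exons)
        starts = ",".join(str(e.start - iv.start) for e in rec.blocks.exons)
        rows.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    f"{rec.read_id};seg={rec.segment_index};cov={rec.coverage:.4f}",
                    str(int(round(rec.pid * 10))),
                    iv.strand,
                    str(iv.start),
                    str(iv.end),
                    "0",
                    str(rec.blocks.n_exons),
                    sizes,
                    starts,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def read_bed12(path: str | os.PathLike) -> list[AlignmentRecord]:
    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        names=[
            "chrom", "start", "end", "name", "score", "strand",
            "thick_start", "thick_end", "rgb", "block_count",
            "block_sizes", "block_starts",
        ],
        dtype={"chrom": str, "block_sizes": str, "block_starts": str},
    )
    records: list[AlignmentRecord] = []
    for row in df.itertuples(index=False):
        fields = dict(item.split("=", 1) for item in row.name.split(";")[1:])
        read_id = row.name.split(";")[0]
        seg = int(fields.get("seg", 0))
        cov = float(fields.get("cov", 1.0))
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = tuple(
            GenomeInterval(row.chrom, row.start + o, row.start + o + s, row.strand)
            for o, s in zip(offsets, sizes)
        )
        blocks = TranscriptModel(f"{read_id}.{seg}", read_id, exons, biotype="unknown")
        records.append(
            AlignmentRecord(read_id, blocks, pid=row.score / 10.0, coverage=cov, segment_index=seg)
        )
    return records


# ---------------------------------------------------------------------------
# TSV tables

def write_methylation_tsv(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    df = calls[METHYL_COLUMNS].sort_values(["chrom", "pos", "strand"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(METHYL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"methylation TSV missing columns: {sorted(missing)}")
    return df[METHYL_COLUMNS]


def write_junction_support_tsv(support: pd.DataFrame, path: str | os.PathLike) -> None:
    df = support[SUPPORT_COLUMNS].sort_values(
        ["sample", "chrom", "intron_start", "intron_end"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)


def read_junction_support_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SUPPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction support TSV missing columns: {sorted(missing)}")
    return df[SUPPORT_COLUMNS]
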
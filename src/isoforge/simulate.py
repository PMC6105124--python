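"""Synthetic transcriptome with planted truth.

Generates a small genome, a multi-isoform gene annotation with planted
alternative-splicing events, full-length/chimeric/truncated long reads
with spliced alignments, fusion reads spanning distant gene pairs, a
per-cytosine methylome with region- and context-specific levels, and a
per-sample junction-support table consistent with a planted binary
expression matrix.  Every record carries exactly one ground-truth
entry, so each downstream stage can be scored against what was
planted.

Gene construction: each gene starts from a base isoform of k exons;
every additional isoform applies exactly one event (ES, IR, AD, AA or
MEE) at its own internal exon "zone" (stride 2, so neighbouring events
never share a splice site).  Terminal exons are never touched, so all
isoforms of a gene share their first and last splice sites.  Base
isoforms of coding genes carry a >100-codon ORF; planted lncRNAs are
rejection-sampled to stay under the ORF filter.

All randomness flows from one seed through fixed per-generator
substreams, so any stage can be regenerated independently and
byte-identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Annotation, Gene, GenomeInterval, TranscriptModel, AlignmentRecord

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate_reference",
           "simulate_reads", "simulate_junction_support", "simulate_methylome",
           "simulate_all", "spliced_sequence"]

BASES = np.array(list("ACGT"))
STOP_RE = re.compile("TAA|TAG|TGA")
_COMP = str.maketrans("ACGT", "TGCA")

EVENT_TYPES = ("ES", "IR", "AD", "AA", "MEE")
AD_AA_SHIFT = 12          # bp, keeps variant exons well-formed
MEE_ALT_MARGIN = 80       # bp between the alternative exon and its intron walls

# substream tags
_S_REF, _S_READS, _S_METH, _S_JUNC = 11, 22, 33, 44


@dataclass
class SimConfig:
    """Study conditions for the synthetic survey."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 250_000
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_length_range: tuple[int, int] = (100, 150)
    intron_length_range: tuple[int, int] = (250, 400)
    gene_gap_range: tuple[int, int] = (2500, 4000)
    # isoforms per gene: value -> sampling weight (group c loci need >10)
    isoform_count_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.20, 3: 0.20, 4: 0.10, 5: 0.06, 12: 0.04}
    )
    planted_event_mix: Mapping[str, float] = field(
        default_factory=lambda: {"ES": 0.30, "IR": 0.30, "AD": 0.15, "AA": 0.15, "MEE": 0.10}
    )
    # reads
    n_reads_per_isoform: int = 3
    pid_noise: float = 0.0
    adapter_5p: str = "AAGCAGTGGTATCAACGCAGAGTACGCGGG"
    adapter_3p: str = "GTACTCTGCGTTGATACCACTGCTTCCGCC"
    polyA_length: int = 30
    chimera_rate: float = 0.05
    truncated_rate: float = 0.10
    # fusions
    n_fusion_pairs: int = 5
    n_reads_per_fusion: int = 2
    fusion_min_distance_bp: int = 10_000
    fusion_same_family_pairs: int = 3
    # novelty / lncRNA
    n_novel_genes: int = 5
    n_lncrnas: int = 10
    lncrna_length_range: tuple[int, int] = (350, 600)
    # expression
    tissue_names: tuple[str, ...] = ("SFB", "SM", "EDL", "EN")
    period_labels: tuple[str, ...] = ("adult", "day1")
    expression_prob: float = 0.7
    junction_depth_mean: float = 9.0
    fusion_support_reads: int = 3
    # methylome: per-context base levels by region; promoter and first
    # exon vary with the locus isoform-count group (a/b/c)
    methyl_depth: int = 50
    methyl_levels: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "CG": {"intergenic": 0.50, "intron": 0.30, "exon": 0.80},
            "CHG": {"intergenic": 0.02, "intron": 0.02, "exon": 0.02},
            "CHH": {"intergenic": 0.01, "intron": 0.01, "exon": 0.01},
        }
    )
    promoter_level_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"a": 0.80, "b": 0.50, "c": 0.20}
    )
    first_exon_level_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"a": 0.60, "b": 0.40, "c": 0.20}
    )
    promoter_bp: int = 2000
    splice_dip_halfwidth: int = 3
    splice_dip_factor: float = 0.10

    def validate(self) -> None:
        if abs(sum(self.planted_event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("planted_event_mix must sum to 1")
        if abs(sum(self.isoform_count_weights.values()) - 1.0) > 1e-9:
            raise ValueError("isoform_count_weights must sum to 1")
        for name in ("n_chroms", "n_genes", "n_reads_per_isoform", "polyA_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fusion_min_distance_bp < 0:
            raise ValueError("fusion_min_distance_bp must be non-negative")

    def samples(self) -> list[str]:
        return [f"{t}_{p}" for p in self.period_labels for t in self.tissue_names]


@dataclass
class GroundTruth:
    """One truth entry per simulated record."""

    config: SimConfig
    genes: dict[str, dict] = field(default_factory=dict)          # gene_id -> info
    isoforms: dict[str, TranscriptModel] = field(default_factory=dict)
    isoform_info: dict[str, dict] = field(default_factory=dict)   # planted_event, novel, kind
    events: list[tuple[str, str, str]] = field(default_factory=list)  # (gene, isoform, type)
    lncrna_classes: dict[str, str] = field(default_factory=dict)
    read_truth: dict[str, dict] = field(default_factory=dict)
    fusion_pairs: list[dict] = field(default_factory=list)
    expression: pd.DataFrame | None = None

    def isoforms_of(self, gene_id: str) -> list[TranscriptModel]:
        return [self.isoforms[i] for i in self.genes[gene_id]["isoforms"]]

    def multi_exon_isoform_ids(self) -> list[str]:
        return sorted(i for i, t in self.isoforms.items() if t.n_exons >= 2)

    def planted_event_counts(self) -> dict[str, int]:
        out = {t: 0 for t in EVENT_TYPES}
        for _, _, etype in self.events:
            out[etype] += 1
        return out


@dataclass
class SimResult:
    genome: dict[str, str]
    annotation: Annotation            # exported (known) subset
    truth: GroundTruth
    reads: dict[str, str]
    alignments: list[AlignmentRecord]
    junction_support: pd.DataFrame
    methylome: pd.DataFrame


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed % (2**31)])


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    s = "".join(genome[t.chrom][e.start : e.end] for e in t.exons)
    return revcomp(s) if t.strand == "-" else s


def _scan_longest_orf(seq: str) -> int:
    """Independent minimal ORF scan used only for rejection sampling."""
    best = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        start = None
        for k, c in enumerate(codons):
            if start is None and c == "ATG":
                start = k
            elif start is not None and STOP_RE.fullmatch(c):
                best = max(best, k - start)
                start = None
    return best


# ---------------------------------------------------------------------------
# reference

def _sample_isoform_count(rng: np.random.Generator, cfg: SimConfig) -> int:
    values = sorted(cfg.isoform_count_weights)
    probs = np.array([cfg.isoform_count_weights[v] for v in values], dtype=float)
    return int(rng.choice(values, p=probs / probs.sum()))


def _apply_event(
    exons: list[tuple[int, int]], etype: str, zone: int, strand: str,
    alt_exon: tuple[int, int] | None,
) -> list[tuple[int, int]]:
    out = [list(e) for e in exons]
    if etype == "ES":
        del out[zone]
    elif etype == "IR":
        out[zone][1] = out[zone + 1][1]
        del out[zone + 1]
    elif etype == "AD":
        if strand == "+":
            out[zone][1] -= AD_AA_SHIFT
        else:
            out[zone][0] += AD_AA_SHIFT
    elif etype == "AA":
        if strand == "+":
            out[zone][0] += AD_AA_SHIFT
        else:
            out[zone][1] -= AD_AA_SHIFT
    elif etype == "MEE":
        assert alt_exon is not None
        out[zone] = list(alt_exon)
    else:  # pragma: no cover
        raise ValueError(etype)
    return [tuple(e) for e in out]


def _build_gene(
    rng: np.random.Generator,
    cfg: SimConfig,
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    n_isoforms: int,
    enlarge_intron_1: int = 0,
) -> tuple[Gene, list[TranscriptModel], list[tuple[str, str]], int]:
    """Returns (gene, isoforms, [(isoform_id, event_type)...], gene_end)."""
    n_events = n_isoforms - 1
    event_types = (
        [str(e) for e in rng.choice(
            list(cfg.planted_event_mix),
            size=n_events,
            p=np.array(list(cfg.planted_event_mix.values())),
        )]
        if n_events
        else []
    )
    zones = [1 + 2 * j for j in range(n_events)]
    k = max(int(rng.integers(*cfg.exons_per_gene)), (2 * n_events + 3) if n_events else 0, 5)

    exon_lens = rng.integers(*cfg.exon_length_range, size=k)
    intron_lens = rng.integers(*cfg.intron_length_range, size=max(k - 1, 0)).astype(int)
    alt_exons: dict[int, tuple[int, int]] = {}
    alt_len = int(rng.integers(*cfg.exon_length_range))
    for j, etype in enumerate(event_types):
        if etype == "MEE":
            intron_lens[zones[j]] += alt_len + 2 * MEE_ALT_MARGIN
    if enlarge_intron_1 and k >= 3:
        intron_lens[1] += enlarge_intron_1

    exons: list[tuple[int, int]] = []
    pos = start
    for i in range(k):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < k - 1:
            pos += int(intron_lens[i])
    gene_end = exons[-1][1]

    for j, etype in enumerate(event_types):
        if etype == "MEE":
            z = zones[j]
            alt_start = exons[z][1] + MEE_ALT_MARGIN
            alt_exons[z] = (alt_start, alt_start + alt_len)

    def model(iso_id: str, coords: list[tuple[int, int]]) -> TranscriptModel:
        return TranscriptModel(
            iso_id,
            gene_id,
            tuple(GenomeInterval(chrom, s, e, strand) for s, e in coords),
            biotype="coding",
        )

    isoforms = [model(f"{gene_id}.i1", exons)]
    planted: list[tuple[str, str]] = []
    for j, etype in enumerate(event_types):
        iso_id = f"{gene_id}.i{j + 2}"
        coords = _apply_event(exons, etype, zones[j], strand, alt_exons.get(zones[j]))
        isoforms.append(model(iso_id, coords))
        planted.append((iso_id, etype))

    gene = Gene(
        id=gene_id,
        interval=GenomeInterval(chrom, exons[0][0], gene_end, strand),
        transcripts=list(isoforms),
        biotype="coding",
    )
    return gene, isoforms, planted, gene_end


def _embed_orf(
    rng: np.random.Generator, arrays: dict[str, np.ndarray], t: TranscriptModel,
    n_codons: int = 150,
) -> None:
    """Write ATG + n non-stop codons + TAA into the spliced sequence."""
    non_stop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]
    body = "".join(rng.choice(non_stop) for _ in range(n_codons))
    orf = "ATG" + body + "TAA"
    offset = 9
    _write_spliced(arrays, t, offset, orf)


def _spliced_to_genomic(t: TranscriptModel) -> np.ndarray:
    """Genomic position of every spliced base, transcription order."""
    parts = [np.arange(e.start, e.end) for e in t.exons]
    pos = np.concatenate(parts)
    return pos[::-1] if t.strand == "-" else pos


def _write_spliced(
    arrays: dict[str, np.ndarray], t: TranscriptModel, offset: int, s: str
) -> None:
    pos = _spliced_to_genomic(t)[offset : offset + len(s)]
    if len(pos) < len(s):
        raise ValueError("sequence does not fit in transcript")
    written = s if t.strand == "+" else s.translate(_COMP)
    arrays[t.chrom][pos] = np.array(list(written))


def _random_orf_poor(
    rng: np.random.Generator, length: int, max_aa: int = 60, attempts: int = 50
) -> str:
    best, best_orf = None, 10**9
    for _ in range(attempts):
        s = "".join(BASES[rng.integers(0, 4, length)])
        orf = _scan_longest_orf(s)
        if orf <= max_aa:
            return s
        if orf < best_orf:
            best, best_orf = s, orf
    return best  # deterministic fallback; still far below typical coding ORFs


def simulate_reference(cfg: SimConfig) -> tuple[dict[str, str], Annotation, GroundTruth]:
    """Genome FASTA dict, exported annotation, and the planted truth."""
    cfg.validate()
    rng = _rng(_S_REF, cfg.seed)
    truth = GroundTruth(config=cfg)

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    arrays = {
        c: BASES[rng.integers(0, 4, cfg.chrom_length_bp)].copy() for c in chroms
    }

    # --- genes ---------------------------------------------------------
    cursors = {c: 6000 for c in chroms}
    genes_by_chrom: dict[str, list[Gene]] = {c: [] for c in chroms}
    all_genes: list[Gene] = []
    for gidx in range(cfg.n_genes):
        chrom = chroms[gidx % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        # the first gene on each chromosome is a single-isoform host for
        # an intronic lncRNA (enlarged intron 1)
        is_host = gidx < cfg.n_chroms and cfg.n_lncrnas > 0
        n_iso = 1 if is_host else _sample_isoform_count(rng, cfg)
        gene_id = f"g{gidx:03d}"
        gene, isoforms, planted, gene_end = _build_gene(
            rng, cfg, gene_id, chrom, cursors[chrom], strand, n_iso,
            enlarge_intron_1=1800 if is_host else 0,
        )
        if gene_end + 8000 > cfg.chrom_length_bp:
            raise ValueError(
                f"infeasible packing: {cfg.n_genes} genes exceed "
                f"chrom_length_bp={cfg.chrom_length_bp}"
            )
        cursors[chrom] = gene_end + int(rng.integers(*cfg.gene_gap_range))
        genes_by_chrom[chrom].append(gene)
        all_genes.append(gene)
        _embed_orf(rng, arrays, isoforms[0])
        truth.genes[gene_id] = {
            "chrom": chrom,
            "strand": strand,
            "interval": gene.interval,
            "isoforms": [t.id for t in isoforms],
            "family": None,
            "exported": True,
            "intronic_host": is_host,
            "kind": "coding",
        }
        for t in isoforms:
            truth.isoforms[t.id] = t
            truth.isoform_info[t.id] = {
                "gene_id": gene_id,
                "planted_event": None,
                "novel": False,
                "kind": "coding",
            }
        for iso_id, etype in planted:
            truth.isoform_info[iso_id]["planted_event"] = etype
            truth.events.append((gene_id, iso_id, etype))

    # --- fusion pairs and gene families --------------------------------
    fusion_gene_pairs: list[tuple[Gene, Gene]] = []
    for chrom in chroms:
        gl = genes_by_chrom[chrom]
        i = 0
        while i < len(gl) and len(fusion_gene_pairs) < cfg.n_fusion_pairs:
            for j in range(i + 1, len(gl)):
                gap = gl[j].interval.start - gl[i].interval.end
                if gap >= cfg.fusion_min_distance_bp:
                    fusion_gene_pairs.append((gl[i], gl[j]))
                    i = j  # genes used once
                    break
            i += 1
    if len(fusion_gene_pairs) < cfg.n_fusion_pairs:
        raise ValueError("infeasible packing: not enough distant gene pairs for fusions")

    fam_counter = 0
    for p, (ga, gb) in enumerate(fusion_gene_pairs):
        if p < cfg.fusion_same_family_pairs:
            fam = f"FAM{fam_counter:02d}"
            fam_counter += 1
            ga.family = gb.family = fam
        else:
            ga.family = f"FAM{fam_counter:02d}"
            gb.family = f"FAM{fam_counter + 1:02d}"
            fam_counter += 2
        truth.fusion_pairs.append(
            {"genes": (ga.id, gb.id), "same_family": p < cfg.fusion_same_family_pairs,
             "read_ids": []}
        )
    for g in all_genes:
        if g.family is None:
            g.family = f"FAM{fam_counter:02d}"
            fam_counter += 1
        truth.genes[g.id]["family"] = g.family

    # --- planted lncRNAs ------------------------------------------------
    class_plan = _lncrna_class_plan(cfg.n_lncrnas)
    host_pool = [g for g in all_genes[cfg.n_chroms :]]
    fusion_genes = {g.id for ga, gb in fusion_gene_pairs for g in (ga, gb)}
    host_pool = [g for g in host_pool if g.id not in fusion_genes][:: 2]
    host_iter = iter(host_pool)
    lnc_host_ids: set[str] = set()
    intronic_counter = 0
    tail_cursor = {c: cursors[c] + 5000 for c in chroms}
    for li, klass in enumerate(class_plan):
        lnc_id = f"lnc{li:02d}"
        L = int(rng.integers(*cfg.lncrna_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        exon_coords: list[tuple[int, int]] | None = None
        if klass == "intergenic":
            chrom = chroms[li % cfg.n_chroms]
            s = tail_cursor[chrom]
            if s + L + 2200 > cfg.chrom_length_bp:
                raise ValueError("infeasible packing: lncRNA tail exceeds chromosome")
            if li < 2:  # two spliced lncRNAs to exercise multi-exon paths
                half = L // 2
                exon_coords = [(s, s + half), (s + half + 200, s + half + 200 + (L - half))]
                tail_cursor[chrom] = s + L + 200 + 2000
            else:
                exon_coords = [(s, s + L)]
                tail_cursor[chrom] = s + L + 2000
        elif klass == "intronic":
            # reserved single-isoform hosts carry one intronic lncRNA each
            host = all_genes[intronic_counter % cfg.n_chroms]
            lnc_host_ids.add(host.id)
            base = truth.isoforms[truth.genes[host.id]["isoforms"][0]]
            big_intron = base.introns()[1]
            chrom = host.interval.chrom
            shift = 700 * (intronic_counter // cfg.n_chroms)
            intronic_counter += 1
            s = big_intron.start + 100 + shift
            L = min(L, len(big_intron) - 200 - shift)
            if L < 100:
                raise ValueError("infeasible packing: intronic lncRNAs exceed host intron")
            exon_coords = [(s, s + L)]
        elif klass in ("sense", "antisense"):
            host = next(host_iter)
            lnc_host_ids.add(host.id)
            chrom = host.interval.chrom
            last_exon = max(
                truth.isoforms_of(host.id)[0].exons, key=lambda e: e.start
            )
            s = last_exon.end - 30
            exon_coords = [(s, s + L)]
            strand = host.interval.strand if klass == "sense" else (
                "-" if host.interval.strand == "+" else "+"
            )
        elif klass == "bidirectional":
            host = next(host_iter)
            lnc_host_ids.add(host.id)
            chrom = host.interval.chrom
            if host.interval.strand == "+":
                e = host.interval.start - 900
                exon_coords = [(e - L, e)]
                strand = "-"
            else:
                s = host.interval.end + 900
                exon_coords = [(s, s + L)]
                strand = "+"
        t = TranscriptModel(
            lnc_id,
            f"lncg{li:02d}",
            tuple(GenomeInterval(chrom, s0, e0, strand) for s0, e0 in exon_coords),
            biotype="lncRNA",
        )
        _plant_lncrna_sequence(rng, arrays, t, all_genes)
        truth.isoforms[lnc_id] = t
        truth.lncrna_classes[lnc_id] = klass
        truth.isoform_info[lnc_id] = {
            "gene_id": t.gene_id,
            "planted_event": None,
            "novel": True,
            "kind": "lncRNA",
        }
        truth.genes[t.gene_id] = {
            "chrom": chrom,
            "strand": strand,
            "interval": t.interval,
            "isoforms": [lnc_id],
            "family": None,
            "exported": False,
            "intronic_host": False,
            "kind": "lncRNA",
        }

    # --- withhold novel genes from the exported annotation --------------
    candidates = [
        g for g in all_genes
        if g.id not in fusion_genes
        and not truth.genes[g.id]["intronic_host"]
        and g.id not in lnc_host_ids
    ]
    withheld = {g.id for g in candidates[-cfg.n_novel_genes :]} if cfg.n_novel_genes else set()
    for gid in withheld:
        truth.genes[gid]["exported"] = False

    exported: list[Gene] = []
    for g in all_genes:
        if g.id in withheld:
            continue
        base = truth.isoforms[truth.genes[g.id]["isoforms"][0]]
        exported.append(
            Gene(id=g.id, interval=g.interval, transcripts=[base],
                 biotype="coding", family=g.family)
        )
        for iso_id in truth.genes[g.id]["isoforms"][1:]:
            truth.isoform_info[iso_id]["novel"] = True
    for gid in withheld:
        for iso_id in truth.genes[gid]["isoforms"]:
            truth.isoform_info[iso_id]["novel"] = True

    genome = {c: "".join(arrays[c]) for c in chroms}
    return genome, Annotation(exported), truth


def _lncrna_class_plan(n: int) -> list[str]:
    base = ["intergenic", "intergenic", "intronic", "sense", "antisense",
            "bidirectional", "intergenic", "intergenic", "intronic", "intergenic"]
    plan = [base[i % len(base)] for i in range(n)]
    return plan


def _plant_lncrna_sequence(
    rng: np.random.Generator,
    arrays: dict[str, np.ndarray],
    t: TranscriptModel,
    genes: Sequence[Gene],
) -> None:
    """Overwrite the candidate's free genomic positions with ORF-poor
    sequence; positions inside coding exons are left untouched."""
    exon_positions = _spliced_to_genomic(t)
    protected = np.zeros(len(exon_positions), dtype=bool)
    for g in genes:
        for tr in g.transcripts or []:
            for ex in tr.exons:
                protected |= (exon_positions >= ex.start) & (exon_positions < ex.end)
    free = ~protected
    chrom_arr = arrays[t.chrom]
    for _ in range(50):
        # s is the oriented spliced content of the free slots; positions
        # are already ordered in transcription direction, so a minus
        # transcript only needs complementation, not reversal
        s = _random_orf_poor(rng, int(free.sum()), max_aa=40, attempts=1)
        written = s if t.strand == "+" else s.translate(_COMP)
        chrom_arr[exon_positions[free]] = np.array(list(written))
        spliced = "".join(chrom_arr[exon_positions])
        if t.strand == "-":
            spliced = spliced.translate(_COMP)
        if _scan_longest_orf(spliced) <= 100:
            return
    # deterministic fallback: poly-pyrimidine filler kills every ATG
    filler = ("CT" * (int(free.sum()) // 2 + 1))[: int(free.sum())]
    chrom_arr[exon_positions[free]] = np.array(list(filler))


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    cfg: SimConfig, genome: Mapping[str, str], truth: GroundTruth
) -> tuple[dict[str, str], list[AlignmentRecord]]:
    """FL/chimeric/truncated reads for every isoform plus fusion reads."""
    rng = _rng(_S_READS, cfg.seed)
    reads: dict[str, str] = {}
    alignments: list[AlignmentRecord] = []
    polya = "A" * cfg.polyA_length
    counter = 0

    def next_id() -> str:
        nonlocal counter
        rid = f"read{counter:05d}"
        counter += 1
        return rid

    def draw_pid() -> float:
        if cfg.pid_noise <= 0:
            return 100.0
        return float(np.clip(rng.normal(100 * (1 - cfg.pid_noise), 0.5), 90.0, 100.0))

    # neighbour map for chimeric partners (same chromosome, adjacent gene)
    coding = [gid for gid, info in truth.genes.items() if info["kind"] == "coding"]
    by_chrom: dict[str, list[str]] = {}
    for gid in coding:
        by_chrom.setdefault(truth.genes[gid]["chrom"], []).append(gid)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: truth.genes[g]["interval"].start)
    neighbour: dict[str, str] = {}
    for chrom, gl in by_chrom.items():
        for i, gid in enumerate(gl):
            neighbour[gid] = gl[i + 1] if i + 1 < len(gl) else gl[i - 1]

    def blocks_model(rid: str, seg: int, exons: Sequence[GenomeInterval]) -> TranscriptModel:
        return TranscriptModel(f"{rid}.{seg}", rid, tuple(exons), biotype="unknown")

    for iso_id in sorted(truth.isoforms):
        t = truth.isoforms[iso_id]
        s = spliced_sequence(t, genome)
        for ri in range(cfg.n_reads_per_isoform):
            rid = next_id()
            # the first read of every isoform is intact full-length, so
            # each planted structure has at least one clean observation
            u = rng.random() if ri else 1.0
            if u < cfg.truncated_rate and t.n_exons >= 2:
                # 5'-truncated: first exon plus 10 bp of the next lost
                cut = len(t.first_exon()) + 10
                reads[rid] = s[cut:] + polya + cfg.adapter_3p
                if t.strand == "+":
                    exons = list(t.exons[1:])
                    exons[0] = GenomeInterval(t.chrom, exons[0].start + 10, exons[0].end, t.strand)
                else:
                    exons = list(t.exons[:-1])
                    exons[-1] = GenomeInterval(t.chrom, exons[-1].start, exons[-1].end - 10, t.strand)
                alignments.append(
                    AlignmentRecord(rid, blocks_model(rid, 0, exons), draw_pid(), 1.0)
                )
                truth.read_truth[rid] = {
                    "class": "partial_5p", "isoform_id": iso_id,
                    "truncated": True, "fusion": False,
                }
            elif u < cfg.truncated_rate + cfg.chimera_rate and truth.isoform_info[iso_id]["kind"] == "coding":
                partner_gene = neighbour[truth.isoform_info[iso_id]["gene_id"]]
                p = truth.isoforms[truth.genes[partner_gene]["isoforms"][0]]
                s2 = spliced_sequence(p, genome)
                reads[rid] = (
                    cfg.adapter_5p + s + polya + cfg.adapter_5p + s2 + polya + cfg.adapter_3p
                )
                l1, l2 = len(s), len(s2)
                c1 = round(l1 / (l1 + l2) * 0.999, 4)
                c2 = round(l2 / (l1 + l2) * 0.999, 4)
                alignments.append(
                    AlignmentRecord(rid, blocks_model(rid, 0, t.exons), draw_pid(), c1, 0)
                )
                alignments.append(
                    AlignmentRecord(rid, blocks_model(rid, 1, p.exons), draw_pid(), c2, 1)
                )
                truth.read_truth[rid] = {
                    "class": "FL_chimeric", "isoform_id": iso_id,
                    "truncated": False, "fusion": False, "partner": p.id,
                }
            else:
                reads[rid] = cfg.adapter_5p + s + polya + cfg.adapter_3p
                alignments.append(
                    AlignmentRecord(rid, blocks_model(rid, 0, t.exons), draw_pid(), 1.0)
                )
                truth.read_truth[rid] = {
                    "class": "FLNC", "isoform_id": iso_id,
                    "truncated": False, "fusion": False,
                }

    # fusion reads: one transcript running through two distant genes
    for pair in truth.fusion_pairs:
        ga, gb = pair["genes"]
        ta = truth.isoforms[truth.genes[ga]["isoforms"][0]]
        tb = truth.isoforms[truth.genes[gb]["isoforms"][0]]
        sa, sb = spliced_sequence(ta, genome), spliced_sequence(tb, genome)
        la, lb = len(sa), len(sb)
        ca = round(la / (la + lb) - 0.002, 4)
        cb = round(lb / (la + lb) - 0.002, 4)
        for _ in range(cfg.n_reads_per_fusion):
            rid = next_id()
            reads[rid] = cfg.adapter_5p + sa + sb + polya + cfg.adapter_3p
            alignments.append(
                AlignmentRecord(rid, blocks_model(rid, 0, ta.exons), draw_pid(), ca, 0)
            )
            alignments.append(
                AlignmentRecord(rid, blocks_model(rid, 1, tb.exons), draw_pid(), cb, 1)
            )
            truth.read_truth[rid] = {
                "class": "FLNC", "isoform_id": None, "truncated": False,
                "fusion": True, "fusion_genes": (ga, gb),
            }
            pair["read_ids"].append(rid)
    return reads, alignments


# ---------------------------------------------------------------------------
# junction support / expression truth

def simulate_junction_support(
    cfg: SimConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Per-sample junction read counts realising a planted expression matrix.

    Expression bits are drawn per multi-exon isoform and sample; a
    sample's support table then contains every junction of its expressed
    isoforms.  A 0 bit whose isoform's junctions are all shared with
    expressed siblings is indistinguishable from 1 under junction
    calling, so such bits are flipped to 1 before the table is written
    (the planted matrix stays consistent with the planted reads).
    """
    rng = _rng(_S_JUNC, cfg.seed)
    samples = cfg.samples()
    iso_ids = truth.multi_exon_isoform_ids()
    junctions = {
        i: {(truth.isoforms[i].chrom, s, e)
            for s, e in truth.isoforms[i].splice_chain().introns}
        for i in iso_ids
    }
    strand_of = {i: truth.isoforms[i].strand for i in iso_ids}
    bits = pd.DataFrame(
        rng.random((len(iso_ids), len(samples))) < cfg.expression_prob,
        index=iso_ids, columns=samples,
    ).astype(int)

    rows = []
    for sample in samples:
        expressed = [i for i in iso_ids if bits.at[i, sample] == 1]
        union: set[tuple[str, int, int]] = set()
        for i in expressed:
            union |= junctions[i]
        for i in iso_ids:
            if bits.at[i, sample] == 0 and junctions[i] <= union:
                bits.at[i, sample] = 1  # indistinguishable from expressed
        strand_by_junction: dict[tuple[str, int, int], str] = {}
        for i in iso_ids:
            for j in junctions[i]:
                strand_by_junction.setdefault(j, strand_of[i])
        for chrom, s, e in sorted(union):
            rows.append(
                (chrom, s, e, strand_by_junction[(chrom, s, e)],
                 1 + int(rng.poisson(cfg.junction_depth_mean)), sample)
            )
    # short-read support across the planted fusion junctions
    for pair in truth.fusion_pairs:
        ga, gb = pair["genes"]
        ta = truth.isoforms[truth.genes[ga]["isoforms"][0]]
        tb = truth.isoforms[truth.genes[gb]["isoforms"][0]]
        la, lb = sorted([ta, tb], key=lambda t: t.interval.start)
        rows.append(
            (ta.chrom, la.interval.end, lb.interval.start, ta.strand,
             cfg.fusion_support_reads, samples[0])
        )
    truth.expression = bits
    return pd.DataFrame(rows, columns=[
        "chrom", "intron_start", "intron_end", "strand", "read_count", "sample"
    ])


# ---------------------------------------------------------------------------
# methylome

REGION_INTERGENIC, REGION_PROMOTER, REGION_INTRON, REGION_EXON, REGION_FIRST_EXON = range(5)
GROUP_INDEX = {"a": 0, "b": 1, "c": 2}


def _region_maps(cfg: SimConfig, truth: GroundTruth, length: int, chrom: str):
    region = np.full(length, REGION_INTERGENIC, dtype=np.int8)
    group = np.zeros(length, dtype=np.int8)
    dip = np.zeros(length, dtype=bool)
    genes = [
        (gid, info) for gid, info in truth.genes.items() if info["chrom"] == chrom
    ]
    # promoters first so gene-body paint wins on overlap
    for gid, info in genes:
        iv = info["interval"]
        g = GROUP_INDEX["a" if info["kind"] != "coding" else
                        ("a" if len(info["isoforms"]) == 1 else
                         ("b" if len(info["isoforms"]) <= 10 else "c"))]
        if info["strand"] == "+":
            p0, p1 = max(0, iv.start - cfg.promoter_bp), iv.start
        else:
            p0, p1 = iv.end, min(length, iv.end + cfg.promoter_bp)
        region[p0:p1] = REGION_PROMOTER
        group[p0:p1] = g
    for gid, info in genes:
        iv = info["interval"]
        region[iv.start : iv.end] = REGION_INTRON
    for gid, info in genes:
        g = GROUP_INDEX["a" if info["kind"] != "coding" else
                        ("a" if len(info["isoforms"]) == 1 else
                         ("b" if len(info["isoforms"]) <= 10 else "c"))]
        rep = max(
            (truth.isoforms[i] for i in info["isoforms"]),
            key=lambda t: t.spliced_length,
        )
        for ex in rep.exons:
            region[ex.start : ex.end] = REGION_EXON
        first = rep.first_exon()
        region[first.start : first.end] = REGION_FIRST_EXON
        group[first.start : first.end] = g
    hw = cfg.splice_dip_halfwidth
    for iso in truth.isoforms.values():
        if iso.chrom != chrom:
            continue
        for s, e in iso.splice_chain().introns:
            dip[max(0, s - hw) : s + hw] = True
            dip[max(0, e - hw) : e + hw] = True
    return region, group, dip


def _level_lut(cfg: SimConfig, context: str) -> np.ndarray:
    """levels[region, group] for one cytosine context."""
    base = cfg.methyl_levels[context]
    lut = np.zeros((5, 3))
    lut[REGION_INTERGENIC, :] = base["intergenic"]
    lut[REGION_INTRON, :] = base["intron"]
    lut[REGION_EXON, :] = base["exon"]
    for g, gi in GROUP_INDEX.items():
        if context == "CG":
            lut[REGION_PROMOTER, gi] = cfg.promoter_level_by_group[g]
            lut[REGION_FIRST_EXON, gi] = cfg.first_exon_level_by_group[g]
        else:
            lut[REGION_PROMOTER, gi] = base["intergenic"]
            lut[REGION_FIRST_EXON, gi] = base["exon"]
    return lut


def expected_level(cfg: SimConfig, context: str, region: str, group: str = "a") -> float:
    """Planted level for a (context, region, isoform-count group)."""
    names = {
        "intergenic": REGION_INTERGENIC, "promoter": REGION_PROMOTER,
        "intron": REGION_INTRON, "exon": REGION_EXON, "first_exon": REGION_FIRST_EXON,
    }
    return float(_level_lut(cfg, context)[names[region], GROUP_INDEX[group]])


def simulate_methylome(
    cfg: SimConfig, genome: Mapping[str, str], truth: GroundTruth
) -> pd.DataFrame:
    """Per-cytosine strand/context counts at planted regional levels."""
    rng = _rng(_S_METH, cfg.seed)
    if cfg.methyl_depth <= 0:
        return pd.DataFrame(columns=[
            "chrom", "pos", "strand", "context", "count_methylated", "count_total"
        ])
    luts = {ctx: _level_lut(cfg, ctx) for ctx in ("CG", "CHG", "CHH")}
    frames = []
    for chrom in sorted(genome):
        seq = np.array(list(genome[chrom]))
        L = len(seq)
        region, group, dip = _region_maps(cfg, truth, L, chrom)
        for strand in ("+", "-"):
            if strand == "+":
                pos = np.flatnonzero(seq == "C")
                nxt1 = np.where(pos + 1 < L, pos + 1, pos)
                nxt2 = np.where(pos + 2 < L, pos + 2, pos)
                is_cg = seq[nxt1] == "G"
                is_chg = (~is_cg) & (seq[nxt2] == "G")
            else:
                pos = np.flatnonzero(seq == "G")
                nxt1 = np.where(pos - 1 >= 0, pos - 1, pos)
                nxt2 = np.where(pos - 2 >= 0, pos - 2, pos)
                is_cg = seq[nxt1] == "C"
                is_chg = (~is_cg) & (seq[nxt2] == "C")
            context = np.where(is_cg, "CG", np.where(is_chg, "CHG", "CHH"))
            level = np.empty(len(pos))
            for ctx in ("CG", "CHG", "CHH"):
                mask = context == ctx
                level[mask] = luts[ctx][region[pos[mask]], group[pos[mask]]]
            level = np.where(dip[pos], level * cfg.splice_dip_factor, level)
            meth = rng.binomial(cfg.methyl_depth, level)
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "context": context,
                "count_methylated": meth,
                "count_total": cfg.methyl_depth,
            }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig) -> SimResult:
    genome, annotation, truth = simulate_reference(cfg)
    reads, alignments = simulate_reads(cfg, genome, truth)
    support = simulate_junction_support(cfg, truth)
    methylome = simulate_methylome(cfg, genome, truth)
    return SimResult(genome, annotation, truth, reads, alignments, support, methylome)
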
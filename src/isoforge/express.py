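"""Junction-support expression calling and summary arithmetic.

An isoform is called expressed (1) in a sample when every one of its
splice junctions is spanned by short-read alignments in that sample;
any junction without support makes the call 0.  Single-exon isoforms
carry no junctions and are excluded (reported separately).  The binary
matrix feeds tissue/period specificity tables; ``percent`` implements
the 2-decimal rounding (half away from zero) used for every reported
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import TranscriptModel

__all__ = [
    "percent",
    "call_expression",
    "build_expression_matrix",
    "PeriodTable",
    "specificity_tables",
    "support_sets",
    "summary_report",
]

JunctionKey = tuple[str, int, int]


def percent(numerator: float, denominator: float, dp: int = 2) -> float:
    """100 x numerator/denominator, rounded half away from zero to dp."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-dp)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def round_half_up(value: float, dp: int = 2) -> float:
    exp = Decimal(1).scaleb(-dp)
    return float(Decimal(str(value)).quantize(exp, rounding=ROUND_HALF_UP))


def support_sets(
    support: pd.DataFrame, min_reads: int = 1
) -> dict[str, set[JunctionKey]]:
    """Per-sample sets of supported junctions (read_count >= min_reads)."""
    ok = support[support["read_count"] >= min_reads]
    out: dict[str, set[JunctionKey]] = {}
    for sample, sub in ok.groupby("sample"):
        out[str(sample)] = set(
            zip(sub["chrom"], sub["intron_start"].astype(int), sub["intron_end"].astype(int))
        )
    return out


def _junction_keys(isoform: TranscriptModel) -> list[JunctionKey]:
    return [(isoform.chrom, s, e) for s, e in isoform.splice_chain().introns]


def call_expression(isoform: TranscriptModel, sample_support: set[JunctionKey]) -> int:
    """1 iff every junction of a multi-exon isoform is supported."""
    if isoform.n_exons < 2:
        raise ValueError(f"single-exon isoform {isoform.id} has no junctions to call")
    return int(all(j in sample_support for j in _junction_keys(isoform)))


def build_expression_matrix(
    isoforms: Sequence[TranscriptModel],
    support: pd.DataFrame,
    samples: Sequence[str] | None = None,
    min_reads: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Binary isoform x sample matrix; returns (matrix, excluded single-exon ids)."""
    sets = support_sets(support, min_reads=min_reads)
    if samples is None:
        samples = sorted(sets)
    multi = [t for t in isoforms if t.n_exons >= 2]
    excluded = [t.id for t in isoforms if t.n_exons < 2]
    data = {
        s: [call_expression(t, sets.get(s, set())) for t in multi] for s in samples
    }
    matrix = pd.DataFrame(data, index=[t.id for t in multi], columns=list(samples))
    if matrix.index.has_duplicates:
        raise ValueError("duplicate isoform ids in expression matrix")
    return matrix, excluded


@dataclass
class PeriodTable:
    """Per-period expression categories over the tissues of that period."""

    period: str
    total: int
    expressed_in_at_least_one: int
    expressed_in_all: int
    expressed_only_single: int
    unexpressed_only_single: int
    unexpressed_in_all: int

    def as_dict(self) -> dict:
        return {
            "period": self.period,
            "total": self.total,
            "expressed_in_at_least_one": self.expressed_in_at_least_one,
            "expressed_in_all": self.expressed_in_all,
            "expressed_only_single": self.expressed_only_single,
            "unexpressed_only_single": self.unexpressed_only_single,
            "unexpressed_in_all": self.unexpressed_in_all,
        }

    def check_identity(self) -> None:
        assert (
            self.expressed_in_at_least_one + self.unexpressed_in_all == self.total
        ), "period table identity violated"


def specificity_tables(
    matrix: pd.DataFrame,
    tissue_of_sample: Mapping[str, str],
    period_of_sample: Mapping[str, str],
) -> dict:
    """Period tables plus per-tissue unique sets and the all-tissue shared set.

    Tissue uniqueness is computed after collapsing periods by logical OR:
    an isoform is unique to a tissue when it is expressed in that tissue
    (any period) and in no other tissue.
    """
    samples = list(matrix.columns)
    tissues = sorted({tissue_of_sample[s] for s in samples})
    periods = sorted({period_of_sample[s] for s in samples})

    # per-tissue OR over periods
    tissue_expr = pd.DataFrame(
        {
            t: matrix[[s for s in samples if tissue_of_sample[s] == t]].max(axis=1)
            for t in tissues
        }
    )
    n_tissues_expressed = tissue_expr.sum(axis=1)
    unique_sets = {
        t: sorted(
            tissue_expr.index[(tissue_expr[t] == 1) & (n_tissues_expressed == 1)]
        )
        for t in tissues
    }
    shared = sorted(tissue_expr.index[n_tissues_expressed == len(tissues)])

    period_tables: list[PeriodTable] = []
    for p in periods:
        cols = [s for s in samples if period_of_sample[s] == p]
        sub = matrix[cols]
        n_expr = sub.sum(axis=1)
        n = len(cols)
        table = PeriodTable(
            period=p,
            total=len(sub),
            expressed_in_at_least_one=int((n_expr >= 1).sum()),
            expressed_in_all=int((n_expr == n).sum()),
            expressed_only_single=int((n_expr == 1).sum()),
            unexpressed_only_single=int((n_expr == n - 1).sum()),
            unexpressed_in_all=int((n_expr == 0).sum()),
        )
        table.check_identity()
        period_tables.append(table)
    return {
        "period_tables": period_tables,
        "unique_by_tissue": unique_sets,
        "shared_all_tissues": shared,
    }


def summary_report(outputs: Mapping[str, object]) -> dict:
    """Assemble the pipeline's headline counts and ratios.

    ``outputs`` may carry any of: n_isoforms, n_single_exon_isoforms,
    n_loci, n_as_loci, n_as_isoforms, n_events, n_basic_events,
    n_lncrna, n_single_exon_lncrna, n_fusion_same_family,
    n_fusion_annotated, n_lincrna_candidates, n_lincrna_known.
    Missing upstream counts yield missing fields, never fabricated ones.
    """
    out: dict[str, object] = {}

    def have(*keys: str) -> bool:
        return all(outputs.get(k) not in (None, 0) or outputs.get(k) == 0 for k in keys)

    g = outputs.get
    if g("n_isoforms") and g("n_single_exon_isoforms") is not None:
        out["single_exon_isoform_percent"] = percent(
            g("n_single_exon_isoforms"), g("n_isoforms")
        )
        out["multi_exon_isoform_percent"] = percent(
            g("n_isoforms") - g("n_single_exon_isoforms"), g("n_isoforms")
        )
    if g("n_loci") and g("n_as_loci") is not None:
        out["as_locus_percent"] = percent(g("n_as_loci"), g("n_loci"))
    if g("n_isoforms") and g("n_as_isoforms") is not None:
        out["as_isoform_percent"] = percent(g("n_as_isoforms"), g("n_isoforms"))
    if g("n_as_loci"):
        if g("n_events") is not None:
            out["mean_events_per_as_locus"] = round_half_up(
                g("n_events") / g("n_as_loci")
            )
        if g("n_as_isoforms") is not None:
            out["mean_isoforms_per_as_locus"] = round_half_up(
                g("n_as_isoforms") / g("n_as_loci")
            )
    if g("n_events") and g("n_basic_events") is not None:
        out["five_basic_model_percent"] = percent(g("n_basic_events"), g("n_events"))
    if g("n_lncrna") and g("n_single_exon_lncrna") is not None:
        out["single_exon_lncrna_percent"] = percent(
            g("n_single_exon_lncrna"), g("n_lncrna"), dp=1
        )
    if g("n_fusion_annotated") and g("n_fusion_same_family") is not None:
        out["same_family_fusion_percent"] = percent(
            g("n_fusion_same_family"), g("n_fusion_annotated")
        )
    if g("n_lincrna_candidates") is not None and g("n_lincrna_known") is not None:
        out["novel_lincrna_count"] = g("n_lincrna_candidates") - g("n_lincrna_known")
    return out
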
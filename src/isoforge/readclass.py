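"""Raw long-read classification from primer and poly(A) signals.

A consensus read is full length (FL) when it carries the 5' cDNA
synthesis primer, the 3' primer and a poly(A) tract; it is full-length
non-chimeric (FLNC) when additionally neither primer occurs in the read
interior (an interior primer marks an artifactual concatenation of two
cDNAs).  Reads missing exactly one signal are reported as partial for
that signal.

Primer matching is approximate (edit distance, via edlib) within a
terminal window at each read end; the thresholds are engineering
parameters exposed on :class:`SignalParams`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .express import percent

__all__ = [
    "SignalParams",
    "ReadSignals",
    "ReadClassSummary",
    "detect_signals",
    "classify",
    "classify_reads",
    "summarize",
    "CATEGORY_ORDER",
]

# categories ordered from weakest to strongest evidence
CATEGORY_ORDER = ["other", "partial_5p", "partial_3p", "partial_polyA", "FL_chimeric", "FLNC"]

DEFAULT_LENGTH_BINS = ((600, 1000), (1000, 2000), (2000, None))


@dataclass(frozen=True)
class SignalParams:
    terminal_window: int = 100
    max_mismatch: int = 2
    polya_min: int = 8          # run of A's, allowing <=1 non-A
    polya_max_nona: int = 1


@dataclass(frozen=True)
class ReadSignals:
    has_5p: bool
    has_3p: bool
    has_polyA: bool
    interior_primer: bool
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")


def _find_approx(needle: str, hay: str, max_dist: int) -> bool:
    if not hay:
        return False
    res = edlib.align(needle, hay, mode="HW", task="distance", k=max_dist)
    return res["editDistance"] != -1


def _has_polya_run(seq: str, min_run: int, max_nona: int) -> bool:
    """Run of >= min_run consecutive A allowing <= max_nona non-A bases."""
    n = len(seq)
    if n < min_run:
        return False
    # sliding window over window length min_run counting non-A
    nona = sum(1 for c in seq[:min_run] if c != "A")
    if nona <= max_nona:
        return True
    for i in range(min_run, n):
        nona += seq[i] != "A"
        nona -= seq[i - min_run] != "A"
        if nona <= max_nona:
            return True
    return False


def detect_signals(
    read_seq: str,
    primer_5p: str,
    primer_3p: str,
    params: SignalParams = SignalParams(),
) -> ReadSignals:
    """Locate 5'/3' primers, the poly(A) tract and any interior primer."""
    if not read_seq:
        raise ValueError("empty read sequence")
    if len(primer_5p) < 10 or len(primer_3p) < 10:
        raise ValueError("primers must be >= 10 nt")
    seq = read_seq.upper()
    w = params.terminal_window
    head = seq[:w]
    tail = seq[-w:]
    has_5p = _find_approx(primer_5p, head, params.max_mismatch)
    has_3p = _find_approx(primer_3p, tail, params.max_mismatch)

    # poly(A): within the 3' window upstream of the 3' primer (or read end)
    tail_region = seq[-(w + len(primer_3p)) :]
    has_polya = _has_polya_run(tail_region, params.polya_min, params.polya_max_nona)

    interior = seq[w:-w] if len(seq) > 2 * w else ""
    interior_primer = _find_approx(primer_5p, interior, params.max_mismatch) or _find_approx(
        primer_3p, interior, params.max_mismatch
    )
    return ReadSignals(has_5p, has_3p, has_polya, interior_primer, len(read_seq))


def classify(signals: ReadSignals) -> str:
    """Map detected signals to a read category.

    FL requires all three signals; FLNC additionally requires no
    interior primer.  With exactly one signal missing the read is
    partial for that signal; otherwise "other".
    """
    present = (signals.has_5p, signals.has_3p, signals.has_polyA)
    if all(present):
        return "FL_chimeric" if signals.interior_primer else "FLNC"
    if sum(present) == 2:
        if not signals.has_5p:
            return "partial_5p"
        if not signals.has_3p:
            return "partial_3p"
        return "partial_polyA"
    return "other"


def classify_reads(
    reads: Mapping[str, str],
    primer_5p: str,
    primer_3p: str,
    params: SignalParams = SignalParams(),
) -> dict[str, tuple[str, ReadSignals]]:
    """Classify every read; returns read_id -> (category, signals)."""
    out: dict[str, tuple[str, ReadSignals]] = {}
    for rid in reads:
        sig = detect_signals(reads[rid], primer_5p, primer_3p, params)
        out[rid] = (classify(sig), sig)
    return out


@dataclass
class ReadClassSummary:
    counts: dict[str, int]
    flnc_by_length_bin: dict[str, int]
    mean_flnc_length: float
    flnc_of_fl_percent: float

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "flnc_by_length_bin": dict(self.flnc_by_length_bin),
            "mean_flnc_length": self.mean_flnc_length,
            "flnc_of_fl_percent": self.flnc_of_fl_percent,
        }


def _bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo}"


def summarize(
    classified: Mapping[str, tuple[str, ReadSignals]],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_LENGTH_BINS,
) -> ReadClassSummary:
    """Tabulate signal counts, FL/FLNC totals and FLNC length bins."""
    if not classified:
        raise ValueError("no classified reads")
    counts: Counter[str] = Counter()
    flnc_lengths: list[int] = []
    for cat, sig in classified.values():
        counts["with_5p"] += sig.has_5p
        counts["with_3p"] += sig.has_3p
        counts["polyA"] += sig.has_polyA
        is_fl = sig.has_5p and sig.has_3p and sig.has_polyA
        counts["FL"] += is_fl
        if cat == "FLNC":
            counts["FLNC"] += 1
            flnc_lengths.append(sig.length_bp)
    bin_counts = {
        _bin_label(lo, hi): sum(
            1 for L in flnc_lengths if L >= lo and (hi is None or L < hi)
        )
        for lo, hi in bins
    }
    mean_len = sum(flnc_lengths) / len(flnc_lengths) if flnc_lengths else 0.0
    pct = percent(counts["FLNC"], counts["FL"]) if counts["FL"] else 0.0
    return ReadClassSummary(dict(counts), bin_counts, mean_len, pct)
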
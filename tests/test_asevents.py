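"""Alternative-splicing event extraction, classification and model codes."""

import numpy as np
import pytest

from conftest import make_transcript
from isoforge.asevents import (
    chromosome_correlation,
    classify_event,
    extract_events,
    model_code,
    pair_events,
    type_counts,
)

T_BASE = [(0, 100), (200, 300), (400, 500)]


def shift(coords, delta):
    return [(s + delta, e + delta) for s, e in coords]


class TestPairEvents:
    def test_cassette_exon_yields_single_es(self):
        t1 = make_transcript(T_BASE, tid="t1")
        t2 = make_transcript([(0, 100), (400, 500)], tid="t2")
        events = pair_events(t1, t2)
        assert len(events) == 1
        assert events[0].type == "ES"
        assert not events[0].open_ended

    def test_identical_chains_no_events(self):
        t1 = make_transcript(T_BASE, tid="t1")
        t2 = make_transcript([(10, 100), (200, 300), (400, 560)], tid="t2")
        # same splice chain, different terminal ends
        assert pair_events(t1, t2) == []

    def test_intron_retention(self):
        t1 = make_transcript(T_BASE, tid="t1")
        t3 = make_transcript([(0, 300), (400, 500)], tid="t3")
        events = pair_events(t1, t3)
        assert [e.type for e in events] == ["IR"]

    def test_alternative_acceptor_three_bp(self):
        t1 = make_transcript(T_BASE, tid="t1")
        t4 = make_transcript([(0, 100), (203, 300), (400, 500)], tid="t4")
        assert [e.type for e in pair_events(t1, t4)] == ["AA"]

    def test_alternative_donor(self):
        t1 = make_transcript(T_BASE, tid="t1")
        t5 = make_transcript([(0, 88), (200, 300), (400, 500)], tid="t5")
        assert [e.type for e in pair_events(t1, t5)] == ["AD"]

    def test_mutually_exclusive_exons(self):
        ta = make_transcript([(0, 100), (200, 300), (600, 700)], tid="ta")
        tb = make_transcript([(0, 100), (400, 500), (600, 700)], tid="tb")
        assert [e.type for e in pair_events(ta, tb)] == ["MEE"]

    def test_pair_order_symmetric(self):
        t1 = make_transcript(T_BASE, tid="t1")
        t2 = make_transcript([(0, 100), (400, 500)], tid="t2")
        k1 = {e.key for e in pair_events(t1, t2)}
        k2 = {e.key for e in pair_events(t2, t1)}
        assert k1 == k2


class TestModelCode:
    def _es_events(self, delta=0, strand="+"):
        t1 = make_transcript(shift(T_BASE, delta), strand=strand, tid="t1")
        t2 = make_transcript(shift([(0, 100), (400, 500)], delta), strand=strand, tid="t2")
        return pair_events(t1, t2)

    def test_translation_invariant(self):
        (a,) = self._es_events(0)
        (b,) = self._es_events(12345)
        assert model_code(a) == model_code(b)

    def test_strand_invariant(self):
        (plus,) = self._es_events(strand="+")
        (minus,) = self._es_events(strand="-")
        assert model_code(plus) == model_code(minus)

    def test_es_and_ir_codes_differ(self):
        (es,) = self._es_events()
        t1 = make_transcript(T_BASE, tid="t1")
        t3 = make_transcript([(0, 300), (400, 500)], tid="t3")
        (ir,) = pair_events(t1, t3)
        assert model_code(es) != model_code(ir)

    def test_variants_joined_smaller_first(self):
        (es,) = self._es_events()
        code = model_code(es)
        assert code.startswith("0,")


class TestExtractEvents:
    def test_deduplicates_across_pairs(self):
        base = make_transcript(T_BASE, tid="b")
        skip = make_transcript([(0, 100), (400, 500)], tid="s")
        ir = make_transcript([(0, 100), (200, 500)], tid="r")
        events = extract_events([base, skip, ir], "L1")
        # cassette exon seen in (b,s) and (s,r); retained intron in (b,r)
        # and (s,r): after dedup exactly one of each plus none extra
        counts = type_counts(events)
        assert counts["ES"] == 1
        assert counts["IR"] == 1

    def test_fewer_than_two_multi_exon_isoforms(self):
        single = make_transcript([(0, 500)], tid="s")
        multi = make_transcript(T_BASE, tid="m")
        assert extract_events([single, multi], "L") == []

    def test_basic_types_partition_events(self, survey):
        counts = survey.event_type_counts
        assert sum(counts.values()) == len(survey.events)
        assert all(v >= 0 for v in counts.values())

    def test_recovery_of_planted_mix(self, sim, survey):
        planted = sim.truth.planted_event_counts()
        got = {k: v for k, v in survey.event_type_counts.items() if k != "complex"}
        assert got == planted
        assert survey.event_type_counts["complex"] == 0


class TestBruteForceOracle:
    """Event counts match an exon-inclusion comparison over the common span."""

    def _oracle_count(self, t1, t2):
        lo = max(t1.interval.start, t2.interval.start)
        hi = min(t1.interval.end, t2.interval.end)
        if lo >= hi:
            return 0

        def bitmap(t):
            x = np.zeros(hi - lo, dtype=bool)
            for e in t.exons:
                a, b = max(e.start, lo), min(e.end, hi)
                if a < b:
                    x[a - lo : b - lo] = True
            return x

        diff = bitmap(t1) ^ bitmap(t2)
        # maximal differing intervals
        idx = np.flatnonzero(diff)
        if len(idx) == 0:
            return 0
        breaks = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, breaks + 1)
        intervals = [(int(r[0]) + lo, int(r[-1]) + 1 + lo) for r in runs]

        def bounds(t):
            out = set()
            for s, e in t.splice_chain().introns:
                out.update((s, e))
            return {b for b in out if lo < b < hi}

        shared = bounds(t1) & bounds(t2)
        # group differing intervals separated by a shared site
        groups = 1
        for (a_end), (b_start) in zip(
            [e for _, e in intervals[:-1]], [s for s, _ in intervals[1:]]
        ):
            if any(a_end <= s <= b_start for s in shared):
                groups += 1
        return groups

    def test_random_splice_variants_match_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(40):
            k = int(rng.integers(4, 7))
            coords, pos = [], 0
            for _ in range(k):
                L = int(rng.integers(60, 160))
                coords.append((pos, pos + L))
                pos += L + int(rng.integers(80, 250))

            def variant(tid):
                keep = [0, k - 1] + [
                    i for i in range(1, k - 1) if rng.random() < 0.7
                ]
                ex = [coords[i] for i in sorted(set(keep))]
                # occasionally retain an intron by merging two exons
                if len(ex) > 2 and rng.random() < 0.4:
                    j = int(rng.integers(0, len(ex) - 1))
                    ex[j] = (ex[j][0], ex[j + 1][1])
                    del ex[j + 1]
                return make_transcript(ex, tid=tid)

            t1, t2 = variant("t1"), variant("t2")
            if t1.n_exons < 2 or t2.n_exons < 2:
                continue
            got = len(pair_events(t1, t2))
            assert got == self._oracle_count(t1, t2), f"trial {trial}"


class TestChromosomeCorrelation:
    def test_proportional_counts_perfect_correlation(self):
        genes = {"chr1": 10, "chr2": 20, "chr3": 30}
        events = {"chr1": 5, "chr2": 10, "chr3": 15}
        assert chromosome_correlation(genes, events) == pytest.approx(1.0)

    def test_reversed_counts_anticorrelated(self):
        genes = {"c1": 1, "c2": 2, "c3": 3}
        events = {"c1": 3, "c2": 2, "c3": 1}
        assert chromosome_correlation(genes, events) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct Pearson formula on (2,4,6,8) vs (1,2,3,5): r = 13/sqrt(175)
        genes = {"c1": 2, "c2": 4, "c3": 6, "c4": 8}
        events = {"c1": 1, "c2": 2, "c3": 3, "c4": 5}
        assert chromosome_correlation(genes, events) == pytest.approx(
            13 / np.sqrt(175), abs=1e-12
        )

    def test_too_few_chromosomes(self):
        with pytest.raises(ValueError):
            chromosome_correlation({"c1": 1, "c2": 2}, {"c1": 1, "c2": 2})

    def test_zero_variance_reported_missing(self):
        genes = {"c1": 5, "c2": 5, "c3": 5}
        events = {"c1": 1, "c2": 2, "c3": 3}
        assert chromosome_correlation(genes, events) is None
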
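"""Methylation levels: pooling conventions, junction stacks, metagene bins."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_transcript
from isoforge.methyl import (
    assign_contexts,
    donor_acceptor_site_level,
    group_comparison,
    isoform_count_group,
    junctions_of,
    metagene,
    site_level,
    stack_junctions,
)
from isoforge.simulate import expected_level

COLS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]


def calls(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestSiteLevel:
    @pytest.mark.parametrize("c,t,expected", [(3, 4, 0.75), (0, 10, 0.0)])
    def test_ratio(self, c, t, expected):
        assert site_level(c, t) == pytest.approx(expected)

    def test_uncovered_site_missing(self):
        assert site_level(0, 0) is None

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            site_level(-1, 4)
        with pytest.raises(ValueError):
            site_level(5, 4)


class TestAssignContexts:
    def test_genome_is_authoritative(self):
        #            0123456789
        genome = {"chr1": "ACGTACCGGA"}
        df = calls([
            ("chr1", 1, "+", "CHH", 1, 2),   # C followed by G: really CG
            ("chr1", 5, "+", "CG", 1, 2),    # CCG: really CHG
            ("chr1", 8, "-", "CHH", 1, 2),   # G..C two back on minus: CHG
        ])
        out = assign_contexts(df, genome)
        assert list(out.context) == ["CG", "CHG", "CHG"]
        assert out.attrs["context_mismatches"] == 3

    def test_simulator_contexts_consistent_with_genome(self, sim):
        sample = sim.methylome.iloc[:2000]
        out = assign_contexts(sample, sim.genome)
        assert out.attrs["context_mismatches"] == 0


class TestStackJunctions:
    def test_single_site_at_first_intron_base(self):
        jn = [("chr1", 100, 200, "+")]
        df = stack_junctions(jn, calls([("chr1", 100, "+", "CG", 5, 10)]))
        row = df[(df.side == "donor") & (df.offset == 1) & (df.strand_class == "sense")]
        assert row.level.item() == pytest.approx(0.5)

    def test_pooled_counts_not_mean_of_levels(self):
        jn = [("chr1", 100, 200, "+"), ("chr1", 1100, 1200, "+")]
        df = stack_junctions(
            jn,
            calls([
                ("chr1", 100, "+", "CG", 1, 2),
                ("chr1", 1100, "+", "CG", 3, 4),
            ]),
        )
        row = df[(df.side == "donor") & (df.offset == 1) & (df.strand_class == "sense")]
        assert row.level.item() == pytest.approx(4 / 6)  # not (0.5 + 0.75) / 2

    def test_pooled_level_is_coverage_weighted_mean(self):
        rng = np.random.default_rng(2)
        rows = []
        for k in range(40):
            t = int(rng.integers(1, 60))
            rows.append(("chr1", 60 + k, "+", "CG", int(rng.integers(0, t + 1)), t))
        df = stack_junctions([("chr1", 100, 200, "+")], calls(rows))
        sub = calls(rows)
        sub["level"] = sub.count_methylated / sub.count_total
        for _, r in df[df.strand_class == "sense"].iterrows():
            # recompute as weighted mean of the per-site levels at that offset
            pos = 100 + r.offset - 1 if r.offset > 0 else 100 + r.offset
            s = sub[sub.pos == pos]
            if len(s):
                w = (s.level * s.count_total).sum() / s.count_total.sum()
                assert r.level == pytest.approx(w)

    def test_minus_strand_offset_one_is_first_intronic_base(self):
        jn = [("chr1", 100, 200, "-")]  # donor boundary at 200; base 199
        df = stack_junctions(jn, calls([("chr1", 199, "-", "CG", 4, 8)]))
        row = df[(df.side == "donor") & (df.offset == 1) & (df.strand_class == "sense")]
        assert row.level.item() == pytest.approx(0.5)

    def test_strand_flip_symmetry(self):
        # mirror the coordinate system: profiles must be unchanged
        N = 10_000
        rng = np.random.default_rng(5)
        jn = [("chr1", 4000, 4600, "+")]
        rows = []
        for _ in range(200):
            p = int(rng.integers(3900, 4700))
            strand = "+" if rng.random() < 0.5 else "-"
            t = int(rng.integers(1, 30))
            rows.append(("chr1", p, strand, "CG", int(rng.integers(0, t + 1)), t))
        fwd = stack_junctions(jn, calls(rows))

        jn_m = [("chr1", N - 4600, N - 4000, "-")]
        rows_m = [
            ("chr1", N - 1 - p, "-" if s == "+" else "+", ctx, c, t)
            for (_, p, s, ctx, c, t) in rows
        ]
        rev = stack_junctions(jn_m, calls(rows_m))
        key = ["side", "context", "strand_class", "offset"]
        pd.testing.assert_frame_equal(
            fwd.set_index(key).sort_index(), rev.set_index(key).sort_index()
        )


class TestDonorAcceptorSites:
    def test_no_cytosine_at_boundary_missing(self):
        df = donor_acceptor_site_level(
            [("chr1", 100, 200, "+")], calls([("chr1", 555, "+", "CG", 1, 2)])
        )
        assert df.empty

    def test_single_donor_site(self):
        df = donor_acceptor_site_level(
            [("chr1", 100, 200, "+")], calls([("chr1", 100, "+", "CG", 2, 4)])
        )
        row = df[(df.side == "donor") & (df.strand_class == "sense")]
        assert row.level.item() == pytest.approx(0.5)

    def test_planted_dip_below_flank_mean(self, sim):
        jn = junctions_of(list(sim.truth.isoforms.values()))
        sites = donor_acceptor_site_level(jn, sim.methylome)
        prof = stack_junctions(jn, sim.methylome)
        cg_sites = sites[(sites.context == "CG") & (sites.strand_class == "combined")]
        flanks = prof[
            (prof.context == "CG") & (prof.strand_class == "combined")
            & (prof.offset.abs() >= 10)
        ]
        assert (cg_sites.level < flanks.level.mean() / 2).all()


class TestMetagene:
    def test_uniform_level_flat_profile(self):
        rng = np.random.default_rng(3)
        rows = [
            ("chr1", int(p), "+", "CG", 5, 10)
            for p in rng.choice(30_000, size=3000, replace=False)
        ]
        t = make_transcript([(12_000, 13_000), (14_000, 16_000)])
        prof = metagene([t], calls(rows), up=5000, down=5000)
        covered = prof[prof.coverage > 0]
        assert np.allclose(covered.level, 0.5)
        assert len(prof) == 300

    def test_minus_strand_profile_mirrors_plus(self):
        N = 40_000
        rng = np.random.default_rng(4)
        rows = [
            ("chr1", int(p), "+", "CG", int(rng.integers(0, 11)), 10)
            for p in range(10_000, 20_000, 7)
        ]
        t_plus = make_transcript([(12_000, 18_000)])
        fwd = metagene([t_plus], calls(rows), up=2000, down=2000)
        rows_m = [("chr1", N - 1 - p, "-", ctx, c, t) for (_, p, _, ctx, c, t) in rows]
        t_minus = make_transcript([(N - 18_000, N - 12_000)], strand="-")
        rev = metagene([t_minus], calls(rows_m), up=2000, down=2000)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_promoter_lower_than_body_when_planted(self, sim):
        truth = sim.truth
        group_c = [
            info for info in truth.genes.values()
            if info["kind"] == "coding" and len(info["isoforms"]) > 10
        ]
        reps = [
            max((truth.isoforms[i] for i in info["isoforms"]),
                key=lambda t: t.spliced_length)
            for info in group_c
        ]
        prof = metagene(reps, sim.methylome, up=2000, down=2000)
        up = prof[prof.region == "upstream"].level.mean()
        body = prof[prof.region == "body"].level.mean()
        assert up < body  # group-c promoters planted far below gene bodies


class TestGroupComparison:
    @pytest.mark.parametrize("n,expected", [(1, "a"), (2, "b"), (10, "b"), (11, "c")])
    def test_group_boundaries(self, n, expected):
        assert isoform_count_group(n) == expected

    def test_all_single_isoform_loci_leave_bc_empty(self):
        t = make_transcript([(1000, 1500), (2000, 2500)])
        df = group_comparison({"L1": [t]}, calls([("chr1", 1200, "+", "CG", 5, 10)]))
        assert df[(df.group == "b")].coverage.eq(0).all()
        assert df[(df.group == "c")].coverage.eq(0).all()
        assert np.isnan(df[(df.group == "b")].level).all()

    def test_promoter_ordering_recovered(self, sim):
        truth, cfg = sim.truth, sim.truth.config
        by_locus = {
            gid: [truth.isoforms[i] for i in info["isoforms"]]
            for gid, info in truth.genes.items()
            if info["kind"] == "coding"
        }
        df = group_comparison(by_locus, sim.methylome)
        prom = df[df.region == "promoter"].set_index("group").level
        assert prom["a"] > prom["b"] > prom["c"]
        for g in "abc":
            assert prom[g] == pytest.approx(
                cfg.promoter_level_by_group[g], abs=0.05
            )
        first = df[df.region == "first_exon"].set_index("group").level
        assert first["a"] > first["b"] > first["c"]
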
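"""Locus assignment, isoform merging and artifact filtering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_alignment, truth_key
from isoforge.collapse import (
    assign_loci,
    collapse_alignments,
    filter_artifacts,
    merge_isoforms,
    same_locus,
)
from isoforge.core import Annotation, Gene, GenomeInterval
from conftest import make_transcript


class TestAssignLoci:
    def test_identical_transcripts_one_locus(self):
        a = make_alignment("r1", [(0, 100), (200, 300)])
        b = make_alignment("r2", [(0, 100), (200, 300)])
        assert len(assign_loci([a, b])) == 1

    def test_opposite_strands_separate(self):
        a = make_alignment("r1", [(0, 100), (200, 300)], strand="+")
        b = make_alignment("r2", [(0, 100), (200, 300)], strand="-")
        assert len(assign_loci([a, b])) == 2

    def test_ten_percent_span_overlap_insufficient(self):
        a = make_alignment("r1", [(0, 1000)])
        b = make_alignment("r2", [(900, 2000)])
        assert not same_locus(a, b)
        assert len(assign_loci([a, b])) == 2

    def test_transitive_closure_chains_loci(self):
        # a-b overlap, b-c overlap, a-c do not: still one locus
        a = make_alignment("r1", [(0, 500)])
        b = make_alignment("r2", [(300, 900)])
        c = make_alignment("r3", [(700, 1300)])
        assert not same_locus(a, c)
        assert len(assign_loci([a, b, c])) == 1

    def test_multi_segment_input_rejected(self):
        seg = make_alignment("r1", [(0, 100)], segment_index=1, coverage=0.5)
        with pytest.raises(ValueError, match="fusion"):
            assign_loci([seg])

    def test_brute_force_closure_equivalence(self):
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(2, 9))
            alns = []
            for i in range(n):
                start = int(rng.integers(0, 3000))
                n_ex = int(rng.integers(1, 4))
                coords, pos = [], start
                for _ in range(n_ex):
                    L = int(rng.integers(50, 400))
                    coords.append((pos, pos + L))
                    pos += L + int(rng.integers(30, 200))
                alns.append(make_alignment(f"r{i}", coords, strand="+"))
            # independent oracle: naive all-pairs closure via BFS
            adj = {i: set() for i in range(n)}
            for i in range(n):
                for j in range(i + 1, n):
                    if same_locus(alns[i], alns[j]):
                        adj[i].add(j)
                        adj[j].add(i)
            seen, comps = set(), []
            for i in range(n):
                if i in seen:
                    continue
                stack, comp = [i], set()
                while stack:
                    k = stack.pop()
                    if k in comp:
                        continue
                    comp.add(k)
                    stack.extend(adj[k] - comp)
                seen |= comp
                comps.append(frozenset(alns[k].read_id for k in comp))
            loci = assign_loci(alns)
            got = {frozenset(m.read_id for m in l.members) for l in loci}
            assert got == set(comps), f"trial {trial}"


class TestMergeIsoforms:
    def _locus(self, alns):
        (locus,) = assign_loci(alns)
        return locus

    def test_same_chain_longest_retained(self):
        short = make_alignment("r1", [(10, 100), (200, 300), (400, 480)])
        long = make_alignment("r2", [(0, 100), (200, 300), (400, 530)])
        (cluster,) = merge_isoforms(self._locus([short, long]))
        assert cluster.n_reads == 2
        assert cluster.representative.interval.start == 0
        assert cluster.representative.interval.end == 530

    def test_nested_single_exon_reads_merge(self):
        outer = make_alignment("r1", [(0, 1000)])
        inner = make_alignment("r2", [(200, 800)])
        (cluster,) = merge_isoforms(self._locus([outer, inner]))
        assert cluster.n_reads == 2

    def test_three_bp_acceptor_shift_separates(self):
        a = make_alignment("r1", [(0, 100), (200, 300)])
        b = make_alignment("r2", [(0, 100), (203, 300)])
        clusters = merge_isoforms(self._locus([a, b]))
        assert len(clusters) == 2

    def test_isoform_ids_follow_locus_ordinal_scheme(self):
        a = make_alignment("r1", [(0, 100), (200, 300)])
        b = make_alignment("r2", [(0, 100), (203, 300)])
        clusters = merge_isoforms(self._locus([a, b]))
        assert [c.id for c in clusters] == ["chr1.1.1", "chr1.1.2"]


def annotation_with_intron(intron=(100, 200)):
    t = make_transcript([(0, intron[0]), (intron[1], intron[1] + 100)], tid="ref1", gene="gA")
    return Annotation([Gene("gA", t.interval, [t])])


class TestFilterArtifacts:
    def _clusters(self, alns):
        loci = assign_loci(alns)
        return [c for l in loci for c in merge_isoforms(l)]

    def test_suffix_chain_removed(self):
        full = make_alignment("r1", [(0, 100), (200, 300), (400, 500), (600, 700)])
        tail = make_alignment("r2", [(230, 300), (400, 500), (600, 700)])
        kept, removed = filter_artifacts(self._clusters([full, tail]))
        assert len(kept) == 1 and len(removed) == 1
        assert removed[0].reason == "subset_structure"
        assert removed[0].member_read_ids == ["r2"]

    def test_internal_variant_not_subset(self):
        base = make_alignment("r1", [(0, 100), (200, 300), (400, 500)])
        skip = make_alignment("r2", [(0, 100), (400, 500)])  # cassette exon out
        kept, removed = filter_artifacts(self._clusters([base, skip]))
        assert len(kept) == 2 and not removed

    @pytest.mark.parametrize(
        "pid,n_reads,junction_known,expect_kept",
        [
            (98.5, 1, True, True),    # low pid, single read, junction annotated
            (99.5, 1, False, True),   # rule only applies below pid 99
            (98.5, 2, False, True),   # two reads vouch for the model
            (98.5, 1, False, False),  # nothing vouches: removed
        ],
    )
    def test_low_pid_rule_truth_table(self, pid, n_reads, junction_known, expect_kept):
        alns = [
            make_alignment(f"r{i}", [(0, 100), (200, 300)], pid=pid)
            for i in range(n_reads)
        ]
        ann = annotation_with_intron((100, 200)) if junction_known else annotation_with_intron((7000, 7100))
        kept, removed = filter_artifacts(self._clusters(alns), annotation=ann)
        assert bool(kept) == expect_kept

    def test_junction_support_rescues_low_pid_singleton(self):
        alns = [make_alignment("r1", [(0, 100), (200, 300)], pid=98.0)]
        support = pd.DataFrame(
            [("chr1", 100, 200, "+", 5, "s1")],
            columns=["chrom", "intron_start", "intron_end", "strand", "read_count", "sample"],
        )
        kept, removed = filter_artifacts(self._clusters(alns), junction_support=support)
        assert kept and not removed

    def test_truncation_flag_removes_unless_intron_spanned(self):
        read = make_alignment("r1", [(0, 300)])
        ann_spanned = annotation_with_intron((100, 200))     # exon covers the intron
        ann_far = annotation_with_intron((7000, 7100))
        kept, removed = filter_artifacts(
            self._clusters([read]), annotation=ann_far, truncated_read_ids={"r1"}
        )
        assert not kept and removed[0].reason == "truncated_5p"
        kept, removed = filter_artifacts(
            self._clusters([read]), annotation=ann_spanned, truncated_read_ids={"r1"}
        )
        assert kept and not removed


class TestPipelineProperties:
    def test_idempotence(self, survey):
        reps = [
            make_alignment(
                c.representative.id.replace(".", "_"),
                [(e.start, e.end) for e in c.representative.exons],
                strand=c.representative.strand,
                chrom=c.representative.chrom,
            )
            for c in survey.clusters
        ]
        kept, removed, _ = collapse_alignments(reps)
        assert not removed
        chains = lambda cs: sorted(
            (c.representative.chrom, c.representative.strand,
             c.representative.splice_chain().introns,
             c.representative.interval.start, c.representative.interval.end)
            for c in cs
        )
        assert chains(kept) == chains(survey.clusters)

    def test_partition_every_read_in_cluster_or_removal(self, sim, survey):
        in_clusters = [r for c in survey.clusters for r in c.member_read_ids]
        in_removals = [r for r in survey.removals for r in r.member_read_ids]
        together = sorted(in_clusters + in_removals)
        assert len(together) == len(set(together))
        usable = {
            r for r, (cat, _) in survey.classified.items()
            if cat in ("FLNC", "partial_5p")
        }
        multi_segment = {
            a.read_id for a in sim.alignments if a.segment_index > 0
        }
        assert set(together) == usable - multi_segment

    def test_recovery_matches_planted_isoforms(self, sim, survey):
        planted = {truth_key(t) for t in sim.truth.isoforms.values()}
        kept = {truth_key(c.representative) for c in survey.clusters}
        assert kept == planted
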
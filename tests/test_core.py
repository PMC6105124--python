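"""Interval arithmetic, transcript models and format round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from isoforge.core import (
    AlignmentRecord,
    Annotation,
    Gene,
    GenomeInterval,
    TranscriptModel,
    extract_junctions,
    overlap_fraction,
)
from isoforge.io import (
    GFF3ParseError,
    read_bed12,
    read_gff3,
    write_bed12,
    write_gff3,
)


def iv(start, end, strand="+", chrom="chr1"):
    return GenomeInterval(chrom, start, end, strand)


def transcript(exon_coords, strand="+", tid="t1", gene="g1", chrom="chr1"):
    return TranscriptModel(
        tid, gene, tuple(GenomeInterval(chrom, s, e, strand) for s, e in exon_coords)
    )


class TestGenomeInterval:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            GenomeInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomeInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomeInterval("chr1", 0, 10, "x")

    @pytest.mark.parametrize(
        "a,b,denom,expected",
        [
            ((0, 100), (0, 100), "a", 1.0),
            ((0, 100), (50, 150), "a", 0.5),
            ((0, 100), (200, 300), "a", 0.0),
            ((0, 1000), (900, 2000), "shorter", 0.1),
        ],
    )
    def test_overlap_fraction(self, a, b, denom, expected):
        assert overlap_fraction(iv(*a), iv(*b), denom) == pytest.approx(expected)

    def test_overlap_cross_chromosome_errors(self):
        with pytest.raises(ValueError):
            overlap_fraction(iv(0, 10), iv(0, 10, chrom="chr2"))

    @given(
        st.tuples(st.integers(0, 500), st.integers(1, 500)),
        st.tuples(st.integers(0, 500), st.integers(1, 500)),
    )
    def test_overlap_shorter_symmetric_and_bounded(self, a, b):
        ia = iv(a[0], a[0] + a[1])
        ib = iv(b[0], b[0] + b[1])
        f = overlap_fraction(ia, ib, "shorter")
        assert 0.0 <= f <= 1.0
        assert f == overlap_fraction(ib, ia, "shorter")


class TestSpliceChain:
    def test_single_exon_empty_chain(self):
        assert extract_junctions(transcript([(0, 100)])).is_empty

    def test_plus_strand_roles(self):
        chain = extract_junctions(transcript([(0, 100), (200, 300)]))
        assert chain.introns == ((100, 200),)
        assert chain.donor_positions() == (100,)
        assert chain.acceptor_positions() == (200,)

    def test_minus_strand_swaps_roles_same_intron(self):
        chain = extract_junctions(transcript([(0, 100), (200, 300)], strand="-"))
        assert chain.introns == ((100, 200),)
        assert chain.donor_positions() == (200,)
        assert chain.acceptor_positions() == (100,)

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=8))
    def test_junction_count_is_exons_minus_one(self, lens):
        coords, pos = [], 0
        for L in lens:
            coords.append((pos, pos + L))
            pos += L + 10
        t = transcript(coords)
        assert len(extract_junctions(t)) == t.n_exons - 1

    def test_exon_order_validated(self):
        with pytest.raises(ValueError):
            transcript([(0, 100), (100, 200)])  # empty intron


GFF_TOY = """##gff-version 3
chr1\tx\tgene\t101\t900\t.\t+\t.\tID=g1
chr1\tx\tmRNA\t101\t900\t.\t+\t.\tID=t1;Parent=g1
chr1\tx\texon\t101\t200\t.\t+\t.\tID=t1.e1;Parent=t1
chr1\tx\texon\t301\t400\t.\t+\t.\tID=t1.e2;Parent=t1
chr1\tx\texon\t801\t900\t.\t+\t.\tID=t1.e3;Parent=t1
"""


class TestGFF3:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(GFF_TOY)
        ann = read_gff3(p)
        t = ann.transcripts[0]
        assert (t.exons[0].start, t.exons[0].end) == (100, 200)

    def test_three_exon_transcript_yields_two_introns(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(GFF_TOY)
        t = read_gff3(p).transcripts[0]
        assert t.splice_chain().introns == ((200, 300), (400, 800))

    def test_round_trip_byte_identical(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(GFF_TOY)
        out1 = tmp_path / "o1.gff3"
        out2 = tmp_path / "o2.gff3"
        write_gff3(read_gff3(p), out1)
        write_gff3(read_gff3(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_malformed_parent_errors(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(GFF_TOY.replace("Parent=g1", "Parent=nosuch"))
        with pytest.raises(GFF3ParseError, match="nosuch"):
            read_gff3(p)

    def test_exon_outside_span_errors(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(GFF_TOY.replace("exon\t801\t900", "exon\t801\t1900"))
        with pytest.raises(GFF3ParseError, match="outside"):
            read_gff3(p)


@st.composite
def transcript_models(draw, chrom="chr1"):
    strand = draw(st.sampled_from("+-"))
    n = draw(st.integers(1, 5))
    pos = draw(st.integers(0, 1000))
    coords = []
    for _ in range(n):
        L = draw(st.integers(20, 200))
        coords.append((pos, pos + L))
        pos += L + draw(st.integers(30, 300))
    tid = draw(st.sampled_from(["tA", "tB", "tC"]))
    return transcript(coords, strand=strand, tid=tid, gene=f"gene_{tid}", chrom=chrom)


class TestRoundTrips:
    @given(models=st.lists(transcript_models(), min_size=1, max_size=4, unique_by=lambda t: t.id))
    @settings(max_examples=30, deadline=None)
    def test_gff3_reader_writer_inverse(self, tmp_path_factory, models):
        tmp = tmp_path_factory.mktemp("gff")
        genes = [Gene(t.gene_id, t.interval, [t]) for t in models]
        path = tmp / "x.gff3"
        write_gff3(Annotation(genes), path)
        back = read_gff3(path)
        orig = {t.id: t for t in models}
        assert set(t.id for t in back.transcripts) == set(orig)
        for t in back.transcripts:
            assert t.exons == orig[t.id].exons

    @given(models=st.lists(transcript_models(), min_size=1, max_size=4))
    @settings(max_examples=30, deadline=None)
    def test_bed12_reader_writer_inverse(self, tmp_path_factory, models):
        tmp = tmp_path_factory.mktemp("bed")
        recs = [
            AlignmentRecord(f"r{i}", t, pid=99.5, coverage=0.98, segment_index=0)
            for i, t in enumerate(models)
        ]
        path = tmp / "x.bed12"
        write_bed12(recs, path)
        back = read_bed12(path)
        assert len(back) == len(recs)
        by_id = {r.read_id: r for r in back}
        for r in recs:
            b = by_id[r.read_id]
            assert b.blocks.exons == r.blocks.exons
            assert b.pid == pytest.approx(r.pid, abs=0.05)
            assert b.coverage == pytest.approx(r.coverage, abs=1e-4)


class TestAlignmentRecord:
    def test_bounds_validated(self):
        t = transcript([(0, 100)])
        with pytest.raises(ValueError):
            AlignmentRecord("r", t, pid=101.0, coverage=1.0)
        with pytest.raises(ValueError):
            AlignmentRecord("r", t, pid=99.0, coverage=0.0)
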
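"""Shared fixtures: one synthetic survey, generated once per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from isoforge.pipeline import run_survey

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from isoforge.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim():
    """Default study conditions, fixed seed, noise-free identities."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def survey(sim):
    cfg = sim.truth.config
    return run_survey(
        sim.reads,
        sim.alignments,
        sim.annotation,
        sim.junction_support,
        cfg.adapter_5p,
        cfg.adapter_3p,
        samples=cfg.samples(),
    )


def make_transcript(exon_coords, strand="+", tid="t1", gene="g1", chrom="chr1", biotype="unknown"):
    from isoforge.core import GenomeInterval, TranscriptModel

    return TranscriptModel(
        tid,
        gene,
        tuple(GenomeInterval(chrom, s, e, strand) for s, e in exon_coords),
        biotype=biotype,
    )


def make_alignment(read_id, exon_coords, strand="+", pid=100.0, coverage=1.0,
                   segment_index=0, chrom="chr1"):
    from isoforge.core import AlignmentRecord

    blocks = make_transcript(
        exon_coords, strand=strand, tid=f"{read_id}.{segment_index}",
        gene=read_id, chrom=chrom,
    )
    return AlignmentRecord(read_id, blocks, pid=pid, coverage=coverage,
                           segment_index=segment_index)


def truth_key(t):
    """Identity of a transcript structure: chain for multi-exon reads,
    exact span for single-exon ones."""
    return (
        t.chrom,
        t.strand,
        t.splice_chain().introns,
        (t.interval.start, t.interval.end) if t.n_exons == 1 else None,
    )
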
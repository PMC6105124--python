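"""Generate a synthetic full-length transcriptome survey with planted truth.

The generator builds a small genome, genes with multiple isoforms (one
planted splicing event per extra isoform), long reads with adapters and
poly(A) tails, fusion reads spanning distant gene pairs, a per-cytosine
methylome and a junction-support table. Every record has a truth entry.
"""

from collections import Counter

from isoforge.simulate import SimConfig, simulate_all

cfg = SimConfig(seed=7, n_genes=20, chrom_length_bp=160_000, n_lncrnas=6,
                n_fusion_pairs=2, fusion_same_family_pairs=1, n_novel_genes=2)
res = simulate_all(cfg)
truth = res.truth

print(f"genome: {len(res.genome)} chromosomes, "
      f"{sum(len(s) for s in res.genome.values()):,} bp")
print(f"genes: {sum(1 for g in truth.genes.values() if g['kind'] == 'coding')} coding "
      f"({len(res.annotation)} exported to the reference annotation), "
      f"{len(truth.lncrna_classes)} planted lncRNAs")
print(f"isoforms: {len(truth.isoforms)}, planted AS events: "
      f"{truth.planted_event_counts()}")
print(f"reads: {len(res.reads)} "
      f"({Counter(v['class'] for v in truth.read_truth.values())})")
print(f"methylation calls: {len(res.methylome):,} cytosines; "
      f"junction-support rows: {len(res.junction_support):,}")
# The event counts are what the AS classifier must recover; the read
# class mix is what the FLNC classifier must recover.
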
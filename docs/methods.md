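# Methods

This note records the models, conventions and deliberate choices
behind each stage, the parameters that matter, and what the synthetic
data does and does not establish.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3 I/O converts
to/from 1-based closed, BED12 is native. A transcript is an ordered
chain of non-overlapping exon blocks on one chromosome and strand; its
splice chain is the ordered intron list in transcription direction,
with the donor at the boundary adjacent to the upstream exon. Two
multi-exon structures are the same isoform exactly when their splice
chains are equal; transcript termini never enter that identity, since
full-length reads of one isoform legitimately differ at their ends.
Percent identity (PID) and query coverage are carried as alignment
metadata from the upstream aligner; coverage is the query fraction
(the aligner's convention for target fraction differs, and nothing
downstream depends on the distinction except the fusion thresholds,
which are stated for query fractions).

## Read classification

Primers are matched by edit distance (edlib) within a terminal window;
the poly(A) tract is a run of ≥ `polya_min` A's tolerating one other
base, searched in the 3' window upstream of the 3' primer. Defaults —
window 100 nt, ≤ 2 mismatches, run ≥ 8 — are engineering parameters of
this implementation (upstream classifiers keep theirs internal), all
exposed on `SignalParams`. Classification is monotone by construction:
adding a signal can only promote a read (other → partial → FL), and an
interior primer is only consulted once all three signals are present.

## Collapsing and artifact filters

The locus rule (span overlap ≥ 0.20, exon overlap > 0.20) is read with
the *shorter* element as denominator — the permissive symmetric choice
— with boundary strictness following the wording of each clause ("20%"
→ ≥, "more than 20%" → >). Loci are transitive closures computed by
union-find over overlapping pairs (verified against an all-pairs
closure in tests).

Filters, in order:

1. **5'-truncation flags.** A cluster whose members are all flagged
   5'-truncated (no 5' primer) is removed, unless its 5'-most exon
   fully spans an annotated intron — that configuration is genuine
   retention evidence, not degradation. Without flags (real data
   lacking a classifier run) this stage is skipped and only stage 2
   catches truncations.
2. **5'-suffix structures.** A multi-exon cluster whose intron chain
   is a proper 5' suffix (transcription direction) of a sibling
   cluster's chain is removed. The suffix — not subset — test is
   essential: a skipping or retention variant's introns are a *set*
   subset of the base isoform's, yet they are real biology; only a
   contiguous missing 5' prefix is the degradation signature.
   Single-exon clusters are exempt (an empty chain is a suffix of
   everything).
3. **Low-identity singletons.** min PID < 99 *and* a single supporting
   read *and* at least one junction that is neither annotated nor
   short-read-supported ⇒ removed. The three conditions are a
   conjunction; any vouching evidence keeps the model.

Representative = longest member by genomic span; ties break on read
id for determinism.

## AS variation units

Events are computed per isoform pair over the intersection of their
spans: sites (position, role) present in only one chain, grouped into
maximal runs between shared sites. Transcript termini act as
sentinels: when both transcripts start (or end) at the same
coordinate the boundary closes the run; otherwise the run is
open-ended. Basic templates require closed flanks, except the
non-variable side of AD/AA (an alternative donor's upstream exon may
legitimately reach the transcript start). Units are deduplicated
locus-wide on (flanks, variant chains), so one cassette exon observed
across many pairs counts once — the fixed counting convention for
genome totals. Model codes renumber the pooled sites 1..n in
transcription direction with `^`/`-` role marks and join the two
variant strings (lexicographically smaller first) with a comma;
distinct code strings, counted genome-wide, are distinct models.

## Fusion detection

All five criteria are conjunctive; relaxing any one can only enlarge
the call set (a tested invariant). Distances are between nearest gene
boundaries; inter-chromosomal pairs satisfy the distance criterion
(the notion is undefined across chromosomes, and a trans-chromosomal
split is if anything stronger evidence). The short-read support
threshold is explicit (`min_support`, default 2) since "a certain
amount" must be a tunable number. Calls support ≥ 3 precursor genes
natively; the distance rule then applies to every pair.

## lncRNA filter and classes

The ORF filter scans the three forward frames only (candidate
sequences are already oriented); ATG counted, stop required and
excluded; "longer than 100 aa" is strict, so 100 aa passes and 101
fails. Position classes are evaluated sense > antisense > intronic >
bidirectional > intergenic; the order resolves candidates qualifying
for several classes in favour of the more direct relationship to a
coding gene. `bidirectional_window` defaults to 1,000 bp —
"bidirectional" needs an explicit promoter-distance definition and
this is ours. External coding-potential models and homology screens
are integration points, not computations: `apply_external_screen`
consumes a precomputed keep-list.

## Methylation

Per-site level is C/(C+T), missing when uncovered. Every aggregation
pools raw counts (Σ C / Σ (C+T)) rather than averaging site levels:
pooled estimates are depth-weighted, robust to shallow sites, and
algebraically equal to the coverage-weighted mean of site levels (a
tested identity). Junction stacks place offset +1 at the first base
downstream of the boundary in transcription direction, so donor +1 is
the first intronic and acceptor +1 the first exonic base; cytosines
are split by strand relative to transcription and also pooled
("combined"). Metagene bins (100 per region) map positions by
fractional coordinate within the nominal window; flank windows
clipped at chromosome ends simply contribute nothing. Group
comparisons (a: 1 isoform, b: 2–10, c: > 10) use each locus's longest
transcript as representative — in the data that motivated this
design, the longest transcript's methylation tracked the
all-transcript pool — with the promoter as 2 kb upstream of its TSS.

## Expression calling

Binary per sample: 1 iff every junction of a multi-exon isoform has ≥
`min_reads` (default 1) supporting short reads; single-exon isoforms
are excluded and reported separately (they have no junctions to test).
The period tables satisfy `expressed_in_at_least_one +
unexpressed_in_all = total` on any input; tissue uniqueness collapses
periods by OR before counting. Ratios round half away from zero at 2
decimals (`express.percent`), the convention that reproduces the
reported summary arithmetic exactly.

## Synthetic data: what it emulates, and what it does not

Each gene grows from a base isoform of k exons (exons 100–150 bp,
introns 250–400 bp); every additional isoform applies one event at
its own internal exon zone with stride 2, so no two events share a
splice site, terminal exons are untouched, and the planted event list
is exactly recoverable. Isoform counts are drawn from a weighted mix
(40% single-isoform; 4% of loci with 12 isoforms to populate group
c). Coding base isoforms carry an embedded 151-codon ORF; planted
lncRNAs are rejection-sampled below the ORF filter. Reads are adapter
+ spliced sequence + 30 A + adapter; 10% are 5'-truncated past the
first junction, 5% chimeric (two transcripts joined by an interior
primer, from *adjacent* genes so fusion criteria reject them), and
each planted fusion pair (genes ≥ 10 kb apart, same-chromosome)
contributes clean split-aligned FLNC reads with per-locus fractions
≈ 0.5 and combined coverage ≈ 0.996. The first read of every isoform
is always intact, so each planted structure has at least one clean
observation under any seed.

Methylation levels are planted per context and region (CG exon 0.8,
intron 0.3, intergenic 0.5; CHG 0.02, CHH 0.01), with promoter and
first-exon CG declining across isoform-count groups (0.8/0.5/0.2 and
0.6/0.4/0.2) to emulate the negative association between promoter
methylation and splicing diversity, and a 10× dip within 3 bp of
splice sites; counts are binomial at depth 50. Expression bits are
Bernoulli(0.7) per isoform × sample; a 0 bit whose junctions are all
covered by expressed siblings in that sample is indistinguishable
from 1 under junction calling and is flipped to 1 before the support
table is written, keeping the planted matrix and the generated table
mutually consistent.

Not emulated: real long-read error profiles and quality scores (PID
is drawn, not simulated from errors), expression magnitudes beyond
binary junction presence, inter-chromosomal fusions (the support
table schema is single-chromosome), overlapping genes on the same
strand, and alternative transcription start/end sites. Passing the
recovery suite therefore shows the *logic* of each stage is exact
under clean, well-separated structures; it does not certify behaviour
under heavy 5' degradation, mapping ambiguity or error-rich
alignments.

## Problem sizes and determinism

Default study conditions: 2 chromosomes × 250 kb, 50 genes, ~160
isoforms, 10 lncRNAs, 5 fusion pairs (3 same-family), 5 withheld
genes, 3 reads per isoform, methylation depth 50 (~250k cytosine
records), 4 tissues × 2 periods. The full test suite runs in well
under a minute; the acceptance script in a few seconds. All
randomness flows from one seed through fixed per-generator substreams
(`numpy` Generator seeded with `[tag, seed]`), so any stage
regenerates independently and byte-identically; the statistical
acceptance check on pooled methylation uses a 3-standard-error band
at the pooled depth.

## Known limitations

- The locus rule's denominators ("shorter") and the suffix reading of
  the subset filter are recorded choices among defensible readings;
  both are fixed and tested, not tuned.
- `fl_status` takes the best grade over all same-locus reference
  transcripts (per-locus best), not per-transcript reporting.
- Open-ended variation units are kept and flagged but only AD/AA can
  classify as basic types there; genuinely terminal-end variation
  (alternative first/last exons) is counted as complex.
- The methylation context of a call can be reassigned from the genome
  sequence (`assign_contexts`; the genome is authoritative and the
  mismatch count is reported); without a genome the call file's own
  context column is trusted.
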
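# Methods

This note documents the models and procedures implemented in `riquant`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinates and gene models

All internal coordinates are 0-based, half-open, on the forward genomic
strand; strand enters only when extracting sequence or assigning
donor/acceptor roles. GTF input (1-based inclusive) is converted at the
boundary. Introns are the gaps between consecutive exons of each
transcript, deduplicated across transcripts; ordinals follow transcription
order. Gaps shorter than `min_intron_length` (default 30 nt — annotation
micro-gaps, not real introns) are dropped and tallied. An intron wholly
contained in another transcript's exon is flagged `known_retained`: the
annotation itself documents a retained form, and such introns are excluded
from "novel" tallies. Overlapping genes are treated independently; a read
may contribute evidence to introns of several genes.

## Junction evidence and PIR

Per intron and sample, reads are classified from their CIGAR geometry:

* **EE** — an N-gap equal to the intron's (start, end) with at least
  `min_overhang` (default 8 nt) aligned on both sides. The gap match is
  exact: splice-aware aligners report exact junctions for short reads.
* **EI5 / EI3** — a single aligned block covering
  `[boundary − overhang, boundary + overhang)` contiguously at the donor /
  acceptor. Deletions do not break a block (the read physically spans the
  reference); only N-gaps do.
* **IB** — all aligned blocks inside the intron body.

A read spliced at an *alternative* junction overlapping the intron (a gap
that overlaps the intron but does not match it) is evidence of neither
splicing of this intron nor retention, and contributes to no category. A
fragment (read pair) counts at most once per category per intron; when
mates disagree, EE beats EI beats IB, so a retained molecule's two mates
cannot be double-counted. Reads on the unexpected library strand are
excluded from counts but kept in the `sense_fraction` denominator, which
therefore estimates the strand fidelity of the library (~0.98 for
dUTP-style protocols) and acts as a DNA-contamination control.

PIR per boundary is `100·EI/(EI+EE)`; `minPIR = min(PIR5, PIR3)` with
`defined = False` when either denominator is zero. By default intronic-body
reads are reported but excluded from the statistic — the conservative
junction-only reading that guards against one-sided mismapping. The
alternative `pir_mode="with_intronic"` adds IB to both numerators after
rescaling to junction-equivalent counts by the ratio of eligible read start
positions, `(read_len − 2·overhang + 1) / max(intron_len − read_len + 1, 1)`;
this mode needs the intron length and the read length and is provided
because the defining ratio can be read either way.

## Expression gate and background

fpkm = fragment count over the gene's exonic union on the expected strand,
divided by (exonic kb × mapped millions). The expression background is the
95th percentile of fpkm over `n_regions` random windows (default 500 × 1 kb)
placed uniformly in intergenic space (gene spans ± 1 kb excluded),
length-weighted across gaps. The percentile uses linear interpolation
between order statistics with Weibull plotting positions (rank q(n+1)); the
convention is recorded in the output. With sparse intergenic signal the
Weibull form is slightly conservative (a higher threshold) compared to the
inclusive convention, which collapses to ~0 when >95% of windows are empty.
A gene is "expressed" in a condition when fpkm exceeds the background in a
majority of replicates.

## Retained-intron calls, switches, differential tests

A replicate passes for an intron when its PIR is defined, junction coverage
(EE+EI5+EI3) ≥ `min_coverage` (default 10), and `minPIR > 25`. The intron is
called retained in a condition when the passing fraction strictly exceeds
50% of replicates and the host gene is expressed. "Intron expressed in >50%
of replicas" is thus interpreted as passing the minPIR+coverage filter; the
looser reading (≥1 read of intronic evidence) is available as
`replicate_rule="any_evidence"`. Condition-level PIR pools counts (sum,
then ratio) rather than averaging ratios, which is robust to unequal depth.
Introns with no defined replicate yield a `no_data` call, distinct from
"not retained".

Switches between two conditions use the categorical boundary rule: pooled
usage ≤ 25% on one side and > 25% on the other, with the gene expressed in
both; direction is reported relative to the second condition. The rule is
symmetric under swapping conditions by construction.

The splicing-index test compares per-replicate normalized inclusion
(feature reads / gene reads, pseudocount 0.5 on both) between conditions:
fold change is the ratio of condition means, the p-value a Welch test on
log2 inclusion. Two significance flags are emitted: PATTERN-style
(p ≤ 0.05, |FC| ≥ 1.5) and EXON-style (p ≤ 0.01, |FC| ≥ 2.0). To keep the
test defined when a group has zero sample variance (exactly replicated toy
inputs), each group's variance is floored. The floor is specified as a 5%
coefficient of variation on the linear scale; by the delta method that maps
to a constant log2-scale variance floor (0.05/ln 2)² ≈ 0.0052, which is
what the implementation applies (`cv_floor` configurable). `gene_de` runs
the same Welch machinery on log2 CPM with FC ≥ 1.5 / uncorrected p ≤ 0.05
flags plus a BH-adjusted column; it is a deliberately simple, self-contained
two-group comparison, labelled as such in its output metadata, not a
negative-binomial count model — use a dedicated DE package for real data.

## Long-read validation

Each primary long-read alignment is classified per overlapping intron:
**spliced** when an N-gap matches both annotated boundaries within `slack`
(default 10 nt); otherwise **retained** when both boundary windows
(± `flank`, default 10 nt) lie inside single aligned blocks and the aligned
fraction of the intron body is ≥ `body_cov_min` (default 0.8); otherwise
**uninformative** (e.g. 5'-truncated molecules ending inside the intron).
Deletions keep blocks contiguous, so small indel noise typical of nanopore
alignments does not break boundary coverage; no error correction is
attempted here. A candidate is validated with ≥ `min_support` retained
molecules (default 1); the validation rate is computed over candidates with
at least one informative molecule, and zero-informative candidates are
reported separately. Increasing slack can only add spliced calls; raising
`body_cov_min` can only remove retained calls (tested monotonicities).

## Intron features

* **Relative position**: intron midpoint as percent of the pre-mRNA span
  (the longest transcript's span), measured 5'→3'; the midpoint makes the
  measure symmetric and insensitive to intron length. Invariant under
  genomic translation and strand mirroring.
* **Splice-site strength**: a trainable per-position log2-odds (PWM) scorer
  with the classical scoring windows — donor 9-mer (3 exonic + 6 intronic),
  acceptor 23-mer (20 intronic + 3 exonic) — trained with pseudocount 1
  from user-supplied true sites against a background composition or
  sequence set, requiring ≥ 50 training sites. A PWM preserves the
  comparative use of splice-site scores (distribution shifts between intron
  classes); externally computed scores (e.g. maximum-entropy models) can be
  substituted through the same interface. Windows containing N score as
  undefined.
* **Stop-codon frames**: frame f ∈ {0,1,2} (relative to the intron's first
  base) contains a stop iff TAA/TAG/TGA occurs at a position ≡ f (mod 3).
  For random 1 kb sequence all three frames are stopped with probability
  ≫ 0.999, which is why retained introns essentially always truncate all
  reading frames.
* **Motif profiling**: exact, overlapping, sense-strand occurrences of a
  given motif (default ATAGA, a suboptimal polyadenylation-signal-like
  pentamer); positions as percent of intron length binned into quintiles;
  presence/absence enrichment against a background intron set via Fisher's
  exact test, odds ratio with Haldane 0.5 correction when a cell is empty.
  De-novo motif discovery is out of scope.

## Targeted editing

Editing sites are specified as (chrom, 0-based position, strand, label)
with sense-strand reference base A. An internal pileup walks primary
alignments (mapq ≥ 20, baseq ≥ 20 by default) and classifies each covering
base as reference (A), edited (G), or other; for minus-strand genes the
observed base is complemented first so classification always happens in
sense-transcript space. Per-read haplotypes are tallied over reads that
cover *every* site with a clean A/G call (the informative subset); on that
subset the count-weighted marginal of the haplotype table equals the
per-site fraction exactly (`site_editing(require_all_sites=True)` uses the
identical filter, and the equality is asserted in tests). Reads covering
only a subset of sites are deliberately excluded from the haplotype
universe — the one unambiguous choice when molecules must be compared
site-for-site. Alternative 5' splice-site usage (exon skipping) reuses the
exact junction-gap rule. Counts are raw read tallies throughout; no
amplification model is applied. Between-condition comparison uses a
two-proportion z-test per site with BH correction across sites.

## Synthetic data generator

The generator emulates the study design the statistics were built for: four
conditions (rostral/caudal × injured/naïve; labelled AI, AN, BI, BN) with
three replicates each, 150 nt strand-specific single-end reads at 98%
strand fidelity, polyadenylated full-length long reads, and an editing
locus with five clustered A sites next to an alternatively spliced exon.
Defaults: 20 genes of 3–5 exons (100–250 nt) and introns of 60–300 nt on
random strands, ≥ 3.5 kb intergenic spacers (so 1 kb background windows fit
outside gene spans ± 1 kb), retention ρ = 0.5 for the retained subset
(20% of introns, half of them condition-specific) against ρ = 0.02
background, substitution errors at 0.001/nt.

Reads are emitted as already-aligned SAM constructed from the known
molecule structure: the computation under test is the counting and
classification logic, not an aligner. Key generator properties:

* Donor/acceptor sites are written as GT..AG with consensus-biased windows
  (85% per-position consensus match) so splice-model training has signal.
* Per-intron retention is independent Bernoulli per molecule; real
  co-retention correlation within a molecule is **not** modelled.
* A read's molecule type is drawn with probability proportional to the
  molecule's number of fragment start positions (L − read_len + 1) via
  rejection sampling. This length weighting matters: sampling molecule
  types by abundance alone depresses the junction-read retention fraction
  below ρ (for a 280 nt intron between 200 nt exons, to ≈ 0.256 at
  ρ = 0.3), because longer retained molecules spread the same one read over
  more positions. With fragment-capacity weighting the EI fraction at a
  boundary equals ρ exactly in expectation.
* Long reads are full molecules, 5'-truncated with probability 0.2
  (3'-anchored chemistry), with small deletions at 0.002/nt; editing reads
  are amplicon-like molecules spanning the whole locus, with haplotypes
  drawn from a configurable distribution and skipping at a configurable
  fraction.
* Identical configurations give byte-identical outputs (integer-seeded
  `numpy` generators with fixed stream ids per sample; floating outputs
  rounded to 6 decimals in TSVs).

What passing tests on this generator shows — and does not show: the
counting, calling, validation and editing statistics recover known truth
under idealized alignments (no mismapping, no PCR duplication, no coverage
bias, uniform fragmentation, exact junctions). They say nothing about
aligner artefacts, GC or positional bias, co-retention structure, or
annotation errors in real data.

## Problem sizes used by the property checks

The reproduction script and the acceptance-style tests use: a 5-gene locus
at ~100× junction coverage for PIR recovery (3 binomial SE bands on the
smaller boundary denominator; exact at ρ = 0 and 1); 50 genes × 4
conditions × 3 replicates for the full filter chain (recall vs false-call
rate against truth); the exhaustive 101×101 integer grid for the switch
rule; 50 true (ρ = 0.5) and 50 unretained (ρ = 0) candidates at 20× long-read
depth for validation; exhaustive sequences to length 12 plus 1000 random
1 kb sequences for the stop-codon scanner; 1000 editing reads with
independent-site marginals (0.8, 0.6, 0.1, 0.4, 0.05) plus 500 count-level
null simulations for the comparison's size; 200 Monte-Carlo repeats (3 vs 3,
CV 10%) for splicing-index power and size; and a 4-gene double run for
byte-level determinism. The false long-read candidates use ρ = 0 because
with `min_support = 1` at 20× depth any nonzero retention would make
"validation" of such an intron a correct, not a false, outcome.

## Known limitations

Single-end generator default (paired mode is not emitted); no multi-mapper
or UMI handling; `gene_de` is not a count model; the PWM scorer is not a
maximum-entropy model (interface accepts external scores); minPIR, as a
minimum of two noisy proportions, is biased slightly downward at low
coverage (≈ 0.5 SE), which the 3-SE recovery bands absorb; the haplotype
universe excludes partially covering reads by design.
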
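# Methods

This note documents the models and procedures natscape implements, the
parameters that matter, the synthetic data the tests run on, and the
design choices made where the method left room.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted only at the I/O boundary. Minus-strand
transcripts keep their genomic span but expose `five_prime()` /
`three_prime()` helpers so orientation logic never handles raw
coordinates. Biotypes are restricted to six classes (PC, lncRNA, TE,
pseudogene, tRNA, other_NPC); anything else maps to other_NPC with a
warning. `coding_class` collapses these to the PC/NPC dichotomy used by
every downstream stratification. Missing expression cells mean "not
observed in that sample", never zero — the network stage counts sample
occurrences, so conflating the two would silently create edges.

## lncRNA candidate filter

A candidate (Cuffmerge-style class code u/x/i) is retained when length
> 200 nt (strict), longest forward-frame ATG→stop ORF ≤ 120 aa
(inclusive, stop codon excluded from the length), external coding
probability < 0.365 (strict), no homology to the annotation, and FPKM
≥ 2 in every sample *where the transcript was assembled*. The last rule
is the one genuinely open reading of "low FPKM in any sample": samples
where the transcript is absent from the assembly carry no evidence about
its expression, so they do not reject. The ORF scan is forward-frames
only because candidates are stranded transcripts; a both-strands mode
exists behind a flag. The filter is order-independent, idempotent, and
monotone in every threshold (tests assert all three).

## cis-NAT identification

Any opposite-strand transcript pair on one chromosome whose *full spans*
overlap by ≥ 1 nt is a cis pair; span overlap (not exonic overlap) is the
default because antisense pairing is a property of the transcribed locus,
with an `exonic` mode available. Orientation follows from which ends meet:
nested spans (equal spans included — the tie-break) are *containing*;
otherwise, if the plus-strand member is the left one, the two 3′ ends
meet in the overlap (*convergent*), else the two 5′ ends do
(*divergent*). Non-overlapping opposite-strand neighbours within
`nearby_max_gap` are *nearby tail-to-tail* (plus member left) or *nearby
head-to-head*. The gap cutoff has no canonical value in the literature
this implements; the default 100 nt is exposed in the config and written
into output headers. Pairs are deduplicated to gene level keeping the
longest overlap, and nearby pairs are tagged but excluded from the
downstream statistics by default (their mechanism of action is unclear,
and they have no duplex region to measure).

## trans-NAT identification

The search aligns each transcript against the reverse complement of
every other. Seeding is exact 13-mer matching through one global k-mer
index (probing each transcript's reverse complement), so the all-vs-all
cost stays near-linear on realistic catalogs; each seeded diagonal is
scanned with Kadane's maximum-sum segment (match +1 / mismatch −1). This
gapless formulation is exact for the quantity the acceptance rule needs:
because flanking matches outweigh an interior mismatch run, the maximal
segment bridges bubbles up to half the region, which is what lets the
10 % rule actually reject them rather than never see them. Candidates
need region ≥ 100 nt and identity ≥ 0.8 — engineering defaults, not
published values, and logged as such.

Verification is positional: the region of A laid against the reverse
complement of the region of B, paired where equal (optional G:U wobble:
in that frame, (G,A) and (T,C) count as paired), bubbles = maximal
unpaired runs. Accept iff max bubble ≤ 0.10 × region length, boundary
inclusive. Thermodynamic duplex prediction is deliberately out of scope:
the acceptance criterion is geometric, free energies are not used
downstream, and a deterministic rule is exactly testable. Pairs whose
genomic loci overlap are excluded (they are the cis stage's job — and
their overlap region is trivially self-complementary, so the aligner
would always "find" them).

## NAT-siRNA calling

Library filter: drop reads overlapping rRNA/snRNA/snoRNA/miRNA loci
(tRNA loci are intentionally retained in the library), keep only reads
with exactly one genomic hit, keep lengths 18–28 nt. Calling: reads are
grouped by exact sequence — under unique mapping a sequence determines
its locus, so the implementation keys on (sequence, locus), which is
identical on real data and stays well-defined if a generator ever emits
two loci with one sequence. A group is called when its locus lies fully
inside ≥ 1 pair's duplex region (genomic overlap for cis; either
projected pairing region for trans) and the sequence occurs in ≥ 3 data
sets, regardless of tissue. "Single locus, possibly several pairs" is the
reconciliation of unique mapping with hub genes: the locus may fall in
several overlaps (the siRNA is then *nonunique*), and the producing gene
of each pair is the member transcribed on the read's strand. When both
members share the read's strand (possible for trans pairs) the producer
is ambiguous; the call defaults to member A and carries an ambiguity
flag. Full containment (not any-overlap) is the residency rule for these
short reads; an any-overlap mode exists.

## Overlap enrichment statistic

Per pair and data set: density of *distinct siRNA loci* (not read
counts — a read-count mode exists behind a flag) in the duplex region,
N_o/L_o, and in the union of the two gene spans minus the duplex region,
N_g/L_g (union, so bases shared by both genes are counted once). A_o and
A_g average these over the pairs of a stratum; R = A_o/A_g. Significance
is a *paired* t-test across pairs within one data set (each pair
contributes a matched density pair), one-tailed with H₁: overlap
density > non-overlap density; identical vectors return t = 0, p = 0.5
exactly. Pairs with empty non-overlap span are skipped and flagged. The
calibration simulator draws Poisson locus counts at the synthetic
bundle's geometry (300 nt duplex region, ~2 kb spans, background 0.02
loci/nt): at 50 pairs the test holds its nominal 5 % size within the
binomial band and reaches full power at a 5× density ratio. The dsRNA
check applies the same paired one-tailed logic to read coverage in the
duplex region versus equal-length flanks truncated at the gene span.

## Histone-modification patterns

Enriched tiles merge into domains when the edge-to-edge gap is ≤ 200 nt
(inclusive) and survive at ≥ 400 nt (inclusive). A mark targets a gene
when a domain overlaps the gene span by ≥ 1 nt — the simplest defensible
rule; a promoter-inclusive mode (−1 kb) exists. G1 = {H3K4me2, H3K4me3,
H3K36me3, H2Bub} (euchromatic), G2 = {H3K27me1, H3K27me3}
(heterochromatic); a gene is G1, G2, G1+G2 or NON, and a pair's class is
the unordered state pair — exactly ten classes cover the 4×4
combinations. The null redraws, each repeat, `n_pairs` random pairings
from the non-NAT pool *without replacement within the repeat* (drawing
with replacement would let one gene pair with itself), matched in number
to the observed set; the summary reports per-class means plus a
2.5/97.5 percentile envelope so direction can be asserted, not just
compared to a mean. Pool composition is unmatched for biotype by
default (a matched mode exists). Metagene profiles use 100 gene-body
bins of 1 % each and 1 kb flanks in 10-bp bins, strand-flipped so bin 0
is 5′.

## DNA methylation distance

Per gene region (body = span; promoter = 1 kb upstream of the TSS — a
5′-UTR region is also implemented where CDS annotation exists) and
context (CG/CHG/CHH), cytosines pool into 20 positional bins as
Σmethylated/Σtotal — pooled, not averaged, so deeply covered sites weigh
more; bins without a covered cytosine are missing, never zero. D_mC
= 1 − Pearson r over mutually covered bins, requiring ≥ 3 such bins and
non-constant vectors (otherwise the value is undefined and flagged —
reporting 0 would fake perfect similarity). The correlation support is
positional bins by default; correlating per-sample means across
methylation data sets is available, since either reading of "correlation
of methylation levels between the pair" is defensible. Observed pair
distances are compared with randomized non-NAT pair distances by
one-tailed Mann–Whitney (H₁: observed smaller); the cis-vs-trans
comparison reports mean D_mC per region × context (suffix -P promoter,
-B body) with a two-sided rank-sum p.

## Coexpression network

Genes in < 3 expression samples are removed; PCC is computed over
samples covering both genes (≥ 3, non-constant). Edges require
|PCC| ≥ 0.8 — inclusive, with a strict-inequality flag, since the two
natural statements of the threshold differ on the boundary. Edge
features: NAT-siRNA production (any called siRNA listing the pair) and
modification similarity (PCC of the two genes' concatenated six-mark
binary domain-overlap profiles over 20 body bins; |PCC| ≥ 0.8, either
sign — strongly opposed profiles are as informative as strongly similar
ones). dsRNA support is an edge attribute, not a filter. Export is an
edge-list TSV plus GraphML with biotype and degree node attributes.

## Synthetic data: what it emulates, and what it does not

The generator lays out gene units on random-sequence chromosomes with
intergenic gaps of 250–600 nt — always above both the nearby-gap cutoff
and the domain-merge gap, so planted pair counts are *exact*, and
recovery tests can demand equality rather than tolerance. Defaults: 12
convergent + 12 divergent + 12 containing + 12 nearby pairs, 15 trans
pairs, 400 non-NAT genes (~526 transcripts) on 4 × 750 kb chromosomes;
genes 0.8–2 kb; overlaps 150–400 nt, capped so each member keeps a
≥ 400 nt exclusive span (that floor is what makes chromatin states
exactly recoverable, see below).

* **Trans pairs** copy the reverse complement of a 300 nt transcript
  segment into the partner's locus on another chromosome; an optional
  bubble mutates a centered run of a configurable fraction of the copy.
  15 % bubbles are rejected by the duplex rule, 10 % accepted, both at
  100 % in the acceptance suite.
* **Small RNA**: siRNA loci arise at 0.10 loci/nt in duplex regions and
  0.02 loci/nt elsewhere in gene spans (a 5× planted enrichment); each
  locus is observed per data set with probability 0.8 over 6 data sets,
  so duplex loci recur in ≥ 3 data sets while per-dataset background
  still calibrates the enrichment null when the two rates are set equal.
  Lengths put 40 % mass at 21 nt and 30 % at 24 nt, mirroring the two
  biological siRNA size classes. The truth table records the *realized*
  number of qualifying loci, so siRNA recovery is exact, not
  statistical.
* **Chromatin**: pair members share their G1/G2 state with probability
  0.9 (baseline mix 50/30/10/10 for G1/G2/G1+G2/NON). Tiles for
  overlapping cis pairs are laid on each member's exclusive span —
  overlapping genes share genomic territory, so full-span tiles would
  contaminate each member with its partner's marks and make discordant
  planted states unrecoverable; containing pairs, whose inner gene has
  no exclusive span, are forced concordant for the same reason.
* **Methylation**: per gene region and context, a latent 20-bin profile
  around a Beta-distributed mean (CG high, CHG mid, CHH low); pair
  members share the latent profile plus N(0, 0.05) noise; binomial
  counts at coverage 20 on a 30 nt site grid.
* **Expression**: bivariate log-normal, latent correlation ρ = 0.9 for
  pair genes over 15 samples, 5 % missing cells (≥ 3 observations kept
  per gene). Exponentiation attenuates the realized Pearson correlation
  to ~0.93, so edge recovery is high (~80 %) but deliberately not 100 %.

One root seed spawns independent per-layer RNG streams, so bundles are
byte-deterministic and regenerating one layer never perturbs another.

What the generator does **not** emulate: real sequence composition,
splicing (single-exon transcripts), mapping or sequencing error,
coverage biases, the HMM tile-calling upstream of the chromatin stage,
or any mutant/stress biology. Passing tests therefore demonstrate that
the statistics recover the signals they are defined to measure under
clean planted conditions — not that those signals are detectable at
real-data noise levels.

## Numerical and scale choices

Monte-Carlo sizes are scaled to the problem: nulls default to 10,000
repeats (the chromatin null is vectorized; the pipeline accepts a
`repeats` override for toy runs), the enrichment calibration uses 1,000
simulations of 50 pairs, and D_mC recovery is checked over 50 generator
seeds with 200 randomized pairs each. Percentages print at one decimal
via a formatting-based rounding helper so reported ratios match
table-printing conventions. Degenerate inputs resolve explicitly: empty
input tables give empty results; zero-length pairing regions, unknown
marks/contexts/strands, orphan GFF3 exons and negative counts raise
errors naming the offending record; undefined correlations are flagged,
never coerced to 0.

## Known limitations

Transcript-to-genome projection spans introns rather than splitting
duplex regions across junctions (single-exon synthetic data is
unaffected; spliced real data would slightly over-extend trans duplex
projections). The gapless aligner will not bridge indel-containing
duplexes — consistent with treating bubbles as mismatch runs, but a
limitation for diverged real trans pairs. The enrichment t-test assumes
approximate normality of paired density differences; at very low locus
counts its size drifts conservative (the calibration simulator makes
this measurable). Nearby cis pairs are identified but excluded from all
duplex-based statistics by construction.
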
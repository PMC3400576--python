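# Methods

## Overview

`tailmap` implements a small-RNA sequence-analysis procedure for
studying 3′-end 2′-*O*-methylation: reads are demultiplexed by exact
4-nt barcode, 3′-adapter-trimmed, collapsed to unique inserts, mapped
to the genome by perfect 5′-anchored matching (≥ 18 nt), annotated into
a hierarchical class system, and summarized into tailing and
length-variant statistics. A synthetic-data module generates genomes,
annotations and sequencing libraries with per-read ground truth so the
whole pipeline runs, and can be validated, at desk scale.

## Mapping and the operational definition of a tail

A read maps wherever its first 18 nucleotides match the genome
perfectly on either strand (exact k-mer index; positions containing
ambiguous bases are excluded with a warning). Each seed hit is extended
3′-wards greedily while read and genome agree; only placements with the
maximal matched length are kept, and the remaining read suffix is the
recorded *tail*. Two consequences are deliberate:

* a tail never begins with a base that is genome-templated at the next
  position — "non-templated" is defined operationally, not from truth
  labels;
* a genuine added nucleotide that happens to coincide with the genomic
  continuation is absorbed into the templated match. This lengthens
  the apparent templated read and can move it out of a length-defined
  class (a 26G read with an absorbed single-base tail is observed as a
  27-nt antisense siRNA). Because each simulated 26G species is one
  fixed genomic window, the absorption probability is locus-specific
  (its continuation base), and the acceptance check for tailing-rate
  recovery conditions on that base per species rather than averaging
  over a uniform genome.

Multi-mapping reads contribute fractional weight 1/n_hits to every
best placement by default (keeping count conservation exact); a
"first placement, full count" policy is available. Coordinates are
0-based half-open internally, 1-based inclusive at the GFF3 boundary;
a minus-strand alignment's `start` is the genomic position of the
read's biological 5′ end.

## Class hierarchy

Fixed priority: (1) *structural* if the templated interval overlaps an
rRNA/tRNA locus on either strand (fragment contamination regardless of
polarity); (2) *miRNA* if fully inside a miRNA locus, sense;
(3) *21U* if the read 5′ end coincides exactly with an annotated 21U
locus 5′ end on the same strand and the templated length is 18–21 nt
(the 18-nt floor is the mapper's; lengths above 21 are impossible from
a 21-nt locus template); (4) antisense siRNA if fully inside an mRNA —
*22G*/*26G* when the **templated** length is 22/26 and the 5′ base is
G, else *siRNA_other*; (5) *senseRNA* if fully inside an mRNA, sense;
(6) *other*, including all partial overlaps. Using templated rather
than full read length for the 22/26 criterion keeps a tailed read in
its class; the 20-mer/21-mer statistics use only lengths 20 and 21.
26G reads are subclassed by the host gene's Argonaute target label
(ERGO-1 / ALG-3/4); labels may also be supplied as explicit gene sets,
which must be disjoint.

## Statistics

* **rpm**: counts × 10⁶ / Σ(non-structural counts); the conversion
  factor is recorded per library. By construction non-structural rpm
  sums to one million.
* **20-mer fraction** per 21U locus: `n20 / (n20 + n21)`, reported for
  loci with at least 250 raw (weighted, unnormalized) 20+21-mer reads;
  all thresholds in the package (250 reads, 500 rpm, cloning ratio
  0.9, two-fold change, p < 0.05 via strict inequality on p and
  inclusive fold bounds) are inclusive at their stated boundary.
* **Tail frequencies**: percentage of a class's weighted reads carrying
  U-trim / A-trim / Other tails.
* **DE calls**: a gene changes only if both replicate p-values are
  below 0.05 and both ratios change at least two-fold in the same
  direction; discordant replicates are "unchanged". No multiple-testing
  correction is applied anywhere — raw test p-values are reported, and
  DE calling uses the two-replicate rule instead of an FDR procedure.
* **CSR-1 target selection**: IP cloning frequency ≥ 500 rpm and
  cloning ratio ≥ 0.9. The cloning ratio is taken as supplied in the
  input table (conventionally IP/(IP+input)); the column name is
  configurable.
* **Wilcoxon tests**: paired signed-rank across libraries within a
  gene group, unpaired rank-sum between groups within a library. The
  exact null distribution is used for n ≤ 25 when there are no zero or
  tied differences, otherwise a continuity-corrected normal
  approximation with rank-split zeros and mid-rank ties; identical
  vectors return p = 1.
* **Chi-squared**: Pearson, no continuity correction, on count tables
  with all-positive marginals. Cross-genotype 21U abundance is
  compared on 21U-vs-miRNA count tables (the contingency construction
  is a documented package choice).

## The simulator

Each attempted sequencing read draws a molecule:

1. **class** from configurable weights over {miRNA, 21U, 26G-ERGO-1,
   26G-ALG-3/4, 22G, structural};
2. **locus** within the class with log-normal abundance weights
   (σ = 0.75) intrinsic to the locus (hash-seeded, so shared across
   libraries);
3. **mature sequence**: the locus sequence for miRNA/21U; for 26G and
   22G an antisense window inside the target mRNA whose read starts
   with 5′G (one fixed window per gene for 26G — one species per
   target — and a random candidate window per molecule for 22G);
   structural molecules are 18–26-nt 5′ fragments of rRNA/tRNA loci;
4. **methylation** with class/genotype probability m; unmethylated
   molecules survive decay with probability s, are 3′-trimmed with
   probability p_trim × (locus propensity ~ Beta(2, 8), intrinsic to
   the locus), and tailed with probability p_tail using a class
   tail-base composition π; trim and tail lengths are truncated
   geometric (trim: P(1 nt) = 0.8, max 3, floor 18 nt templated; tail:
   q = 0.6, max 4). Methylated molecules use near-zero baseline rates
   (0.005 trim, 0.01 tail);
5. **clonability**: 5′-triphosphate species (22G) clone with
   probability 0.05 unless TAP-treated (then 1); oxidation leaves
   unmethylated molecules clonable with probability 0.05. Unclonable
   molecules are the adaptor-only reads of oxidized libraries: the
   sequencing attempt is consumed but no read is emitted, so oxidation
   changes library composition without touching the absolute yield of
   methylated molecules — the mechanism behind oxidation enrichment.
   Decay is a Bernoulli survival per molecule, not a time process:
   only steady-state abundances are observed, so the simplest
   mechanism that reproduces differential stability suffices.

Emitted reads are `barcode + insert + adapter`, padded/truncated to a
fixed read length with constant quality; a truth table records origin
locus, class, genotype, methylation, templated length, tail and
treatment per emitted read, plus the class the annotator is expected
to assign given the final templated length.

The random stream is consumed identically for every treatment, so two
runs with the same seed and different treatments simulate the same
molecules and differ only in clonability — the ox/unox invariant on
methylated yield is exact, not statistical. Per-library seeds in the
pipeline are fixed offsets from the master seed.

**Genotype presets** differ only in the methylation probability of the
HEN1-substrate classes (21U and ERGO-1 26G): wild-type 0.98, hypomorph
0.5, null 0. ALG-3/4 26G RNAs are never methylated but survive
unmethylated (s = 0.95), encoding the finding that only ERGO-1-bound
26G RNAs are methylation-dependent; ERGO-1 26G unmethylated survival
is 0.25 (strong dependence), 21U unmethylated survival 0.9 (mild
dependence). These survival/oxidation/clonability values are free
tunables chosen to produce the qualitative regime, not measurements;
no test treats preset magnitudes as external ground truth — the
directional suite asserts orderings only.

**What the generator does not model**: sequencing errors, quality-score
realism, ligation bias, transcriptome-level expression dynamics, and
genome repeat structure beyond what random sequence provides. Passing
tests therefore demonstrate correctness of the analysis operations and
internal consistency of the modeled mechanisms on data whose
statistical structure matches the assumptions — not performance on
real libraries.

## Numerical and design choices

* Barcode matching is exact: 4-nt codes at Hamming distance ≥ 2 make
  single-mismatch rescue unsafe. Reads whose adapter is not found are
  kept and flagged (the mapper's tail trimming absorbs residual
  adapter, or the read fails annotation); inserts shorter than 18 nt
  after trimming are discarded.
* Collapsing orders unique inserts lexicographically; all tables are
  sorted, so outputs are independent of input order and byte-stable.
* The 21U locus packing places loci in dense clusters on the first
  chromosome; infeasible packing raises an error naming the class.
* Run manifests contain the config hash, package version and per-stage
  record counts but no timestamps, so identical runs are byte-identical;
  wall-clock information goes to stderr logs.
* Problem sizes: the directional analyses use 100,000 attempted reads
  per library on a 50 kb genome with 30 clustered 21U loci — enough for
  every locus to clear the 250-read profile filter — and recovery
  checks use 20,000 reads, where three binomial standard errors bound
  estimates within ~1% absolute.

## Known limitations

* The mapper is exact-match only (no mismatches or indels); divergent
  or SNP-bearing reads are unmapped rather than softly aligned.
* Fractional multimapper weighting spreads counts without an
  assignment model; on repeat-rich real genomes a dedicated
  multi-mapping strategy would be preferable.
* Tail absorption (above) biases observed tailing rates downward in a
  genome-dependent way; with real genomes the effect averages toward
  ~1/4 per base but never vanishes. Truth-table comparisons quantify
  it exactly on synthetic data.
* The 22G/26G length criterion on templated length is a package
  decision where the convention is ambiguous; switching to full read
  length would reclassify tailed 22/26-mers.
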
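# tailmap

Small-RNA tailing analysis at desk scale: prefix-anchored exact read
mapping with non-templated 3′-tail recording, hierarchical small-RNA
class annotation, and the tailing / length-variant statistics used to
study 3′-end methylation of small RNAs — driven by a ground-truthed
simulator of methylation-dependent small-RNA sequencing libraries.

## The scientific problem

HEN1-family methyltransferases deposit a 2′-*O*-methyl group on the 3′
terminal nucleotide of certain small-RNA classes. In *C. elegans* the
candidate substrates are the 21U RNAs (piRNAs: 21 nt, 5′U, bound by
PRG-1/2) and the 26G RNAs (26 nt, 5′G, antisense to their target mRNAs,
bound by ERGO-1 or ALG-3/4). Methylation protects a small RNA's 3′ end
from non-templated nucleotide additions (*tailing*, especially
uridylation) and from 3′ shortening (*trimming*), both of which are
linked to decay. Sequencing libraries read this state out three ways:

* **oxidation (NaIO₄)** renders unmethylated 3′ ends unclonable, so an
  oxidized library is enriched for methylated species;
* **tails** appear as genome-mismatching 3′ read suffixes — a read is
  mapped by requiring a perfect match of at least its first 18 nt, the
  match is extended 3′-wards as far as the genome agrees, and the
  remaining suffix is recorded and classified as *U-trim* (only T
  bases), *A-trim* (only A) or *Other*;
* **trimming** appears as 20-mer variants of 21U loci — reads whose 5′
  end coincides exactly with an annotated 21U locus but that are one
  nucleotide short; the per-locus *20-mer fraction*
  `n20 / (n20 + n21)` is a proxy for 3′ instability.

Counts are normalized as reads per million non-structural reads (rpm;
rRNA/tRNA-matching reads are excluded from the denominator). The class
hierarchy assigns each mapped read exactly one label — structural →
miRNA → 21U → antisense siRNA (22G/26G by templated length and 5′G) →
senseRNA → other — and 26G reads are subclassed by their host gene's
Argonaute (ERGO-1 vs ALG-3/4).

The package is for method developers and students who want a complete,
tested, reproducible implementation of this analysis that runs in
seconds on synthetic data with known ground truth, rather than on a
multi-gigabyte archive run.

## Worked example

```python
from tailmap import (generate_genome, genotype_preset, simulate_library,
                     TreatmentSpec, GenomeIndex, LocusIndex, annotate_collapsed,
                     demultiplex, preprocess_library, class_counts, normalize_rpm,
                     ratio_21u_to_mirna, tail_frequency, length_profiles)
from tailmap.simulate import DEFAULT_ADAPTER

bundle = generate_genome(
    n_chrom=1, lengths=[50_000],
    locus_plan={"21U": 30, "miRNA": 5, "mRNA": 10, "rRNA": 1, "tRNA": 2},
    seed=7,
)
index, loci = GenomeIndex(bundle.chromosomes), LocusIndex(bundle.loci)

for genotype in ("wild-type", "null"):
    sim = simulate_library(bundle, genotype_preset(genotype), TreatmentSpec(),
                           depth=100_000, seed=1)
    assigned, _ = demultiplex([seq for _, seq in sim.reads], ["ACTA"])
    collapsed, _ = preprocess_library(assigned["ACTA"], DEFAULT_ADAPTER)
    table, _ = annotate_collapsed(collapsed, index, loci)
    counts = class_counts(table)
    rpm = normalize_rpm(counts).rpm
    u_trim = tail_frequency(table[table.rna_class == "26G"], "26G").u_trim_pct
    frac20 = length_profiles(table, min_raw=250.0)
    frac20 = frac20[frac20.passes_filter]["fraction_20"].mean()
    print(f"{genotype:>9}: 21U/miRNA {ratio_21u_to_mirna(counts):.3f}  "
          f"26G rpm {rpm['26G']:>7.0f}  26G U-trim {u_trim:.1f}%  "
          f"mean 20-mer fraction {100*frac20:.1f}%")
```

prints

```
wild-type: 21U/miRNA 0.374  26G rpm  130934  26G U-trim 0.7%  mean 20-mer fraction 0.7%
     null: 21U/miRNA 0.333  26G rpm   64594  26G U-trim 3.6%  mean 20-mer fraction 18.4%
```

Losing methylation halves 26G abundance, raises 26G uridylation
five-fold and raises the mean 21U 20-mer fraction from under 1% to
~18%, while total 21U abundance (relative to miRNAs) barely moves —
the differential-stability pattern the simulator presets encode.

The same analysis is available as a CLI (`tailmap run --config
config.yaml`, with `simulate`, `demux`, `trim`, `collapse`, `map`,
`quantify` and `report` subcommands for the individual stages); a run
writes per-library annotation tables, figure-ready TSV panels, a JSON
report and a manifest with per-stage record counts. Identical config
and seed give byte-identical outputs.

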
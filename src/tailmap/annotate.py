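"""Hierarchical small-RNA class annotation of mapped reads.

Each placement is assigned exactly one class by a fixed priority:

1. ``structural`` — the templated interval overlaps an rRNA/tRNA locus
   on either strand (fragment contamination regardless of polarity);
2. ``miRNA`` — fully inside a miRNA locus, sense;
3. ``21U`` — the read 5' end coincides exactly with an annotated 21U
   locus 5' end on the same strand, with templated length 18-21 nt
   (3'-shortened piRNA variants keep their class);
4. siRNA — fully inside an mRNA locus, antisense; subdivided into
   ``22G`` / ``26G`` when the *templated* length is 22 or 26 nt and the
   5' nucleotide is G, otherwise ``siRNA_other``;
5. ``senseRNA`` — fully inside an mRNA locus, sense;
6. ``other`` — everything else, including partial overlaps.

Class length criteria use the genome-matched (templated) length; the
non-templated tail is ignored for interval computation.  26G reads are
subclassed by the Argonaute target status of their host gene (ERGO-1
vs ALG-3/4).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .genome import LocusAnnotation
from .mapper import GenomeIndex, TailAlignment, TailClass, map_read, ReadTooShortError

RNA_CLASSES = (
    "structural", "miRNA", "21U", "22G", "26G", "siRNA_other", "senseRNA", "other"
)

AGO_SUBCLASSES = ("ERGO-1", "ALG-3/4", "unassigned")

ANNOTATION_COLUMNS = [
    "insert", "chrom", "strand", "start", "weight", "rna_class", "locus_id",
    "templated_length", "five_prime_nt", "tail", "tail_class", "ago_subclass",
]


@dataclass(frozen=True)
class AnnotatedRead:
    """A mapped read placement with its small-RNA class."""

    alignment: TailAlignment
    weight: float
    rna_class: str
    locus_id: Optional[str]
    templated_length: int
    five_prime_nt: str
    tail_class: TailClass
    ago_subclass: str = "unassigned"


class LocusIndex:
    """Interval lookup over loci plus a 21U 5'-end dictionary."""

    def __init__(self, loci: Iterable[LocusAnnotation]):
        self.trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.u21_five_prime: Dict[Tuple[str, str, int], LocusAnnotation] = {}
        for loc in loci:
            self.trees[loc.chrom].addi(loc.start, loc.end, loc)
            if loc.locus_class == "21U":
                self.u21_five_prime[(loc.chrom, loc.strand, loc.five_prime_pos)] = loc

    def overlapping(self, chrom: str, lo: int, hi: int) -> List[LocusAnnotation]:
        if chrom not in self.trees:
            return []
        found = [iv.data for iv in self.trees[chrom].overlap(lo, hi)]
        found.sort(key=lambda l: (l.start, l.end, l.locus_id))
        return found


def annotate(
    alignment: TailAlignment,
    loci: LocusIndex,
    *,
    weight: float = 1.0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AnnotatedRead:
    """Assign one small-RNA class to a mapped read placement."""
    L = alignment.matched_len
    if alignment.strand == "+":
        lo, hi = alignment.start, alignment.start + L
    else:
        lo, hi = alignment.start - L + 1, alignment.start + 1
    if lo < 0:
        raise ValueError("alignment extends beyond chromosome start")
    if chrom_lengths is not None and hi > chrom_lengths[alignment.chrom]:
        raise ValueError("alignment extends beyond chromosome end")

    cands = loci.overlapping(alignment.chrom, lo, hi)
    five_prime = alignment.insert[0]
    tail_class = alignment.tail_class

    def result(rna_class, locus=None, ago="unassigned"):
        return AnnotatedRead(
            alignment=alignment, weight=weight, rna_class=rna_class,
            locus_id=locus.locus_id if locus is not None else None,
            templated_length=L, five_prime_nt=five_prime,
            tail_class=tail_class, ago_subclass=ago,
        )

    # 1. structural contamination, either strand, any overlap
    for loc in cands:
        if loc.locus_class in ("rRNA", "tRNA"):
            return result("structural", loc)

    def fully_inside(loc):
        return lo >= loc.start and hi <= loc.end

    # 2. miRNA: fully inside, sense
    for loc in cands:
        if loc.locus_class == "miRNA" and fully_inside(loc) and loc.strand == alignment.strand:
            return result("miRNA", loc)

    # 3. 21U: exact 5'-end coincidence, same strand, templated length 18-21
    u21 = loci.u21_five_prime.get((alignment.chrom, alignment.strand, alignment.start))
    if u21 is not None and 18 <= L <= 21:
        return result("21U", u21)

    # 4. siRNA: fully inside an mRNA, antisense
    for loc in cands:
        if loc.locus_class == "mRNA" and fully_inside(loc) and loc.strand != alignment.strand:
            if L == 22 and five_prime == "G":
                return result("22G", loc)
            if L == 26 and five_prime == "G":
                ago = loc.ago_target if loc.ago_target in ("ERGO-1", "ALG-3/4") else "unassigned"
                return result("26G", loc, ago)
            return result("siRNA_other", loc)

    # 5. senseRNA: fully inside an mRNA, sense
    for loc in cands:
        if loc.locus_class == "mRNA" and fully_inside(loc) and loc.strand == alignment.strand:
            return result("senseRNA", loc)

    # 6. everything else, including partial overlaps
    return result("other")


def subclass_26g(gene_id: str, ergo1_targets: Set[str], alg34_targets: Set[str]) -> str:
    """Look up the hosting Argonaute of a 26G target gene.

    The two target sets must be disjoint; overlaps must be resolved
    upstream.
    """
    both = set(ergo1_targets) & set(alg34_targets)
    if both:
        raise ValueError(f"genes in both target sets (resolve upstream): {sorted(both)}")
    if gene_id in ergo1_targets:
        return "ERGO-1"
    if gene_id in alg34_targets:
        return "ALG-3/4"
    return "unassigned"


def annotate_collapsed(
    collapsed: Sequence,
    index: GenomeIndex,
    loci: LocusIndex,
    *,
    multimap: str = "fractional",
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Map and annotate a collapsed library.

    ``multimap='fractional'`` spreads each read's count as weight
    1/n_hits over all best placements (keeps count conservation exact);
    ``'first'`` assigns the full count to the first placement in
    deterministic (chrom, strand, start) order.

    Returns the annotation table plus mapping statistics (weights).
    """
    if multimap not in ("fractional", "first"):
        raise ValueError("multimap must be 'fractional' or 'first'")
    records = []
    stats = {"input_weight": 0.0, "mapped_weight": 0.0,
             "unmapped_weight": 0.0, "too_short_weight": 0.0}
    for cr in collapsed:
        stats["input_weight"] += cr.count
        try:
            alns = map_read(cr.insert, index)
        except ReadTooShortError:
            stats["too_short_weight"] += cr.count
            continue
        if not alns:
            stats["unmapped_weight"] += cr.count
            continue
        stats["mapped_weight"] += cr.count
        if multimap == "first":
            alns = alns[:1]
            weights = [float(cr.count)]
        else:
            weights = [cr.count / a.n_hits for a in alns]
        for aln, w in zip(alns, weights):
            records.append(annotate(aln, loci, weight=w))
    return records_to_frame(records), stats


def records_to_frame(records: Iterable[AnnotatedRead]) -> pd.DataFrame:
    """Annotated reads as a tidy table, one row per read x placement."""
    rows = [
        (
            r.alignment.insert, r.alignment.chrom, r.alignment.strand,
            r.alignment.start, r.weight, r.rna_class,
            r.locus_id if r.locus_id is not None else "",
            r.templated_length, r.five_prime_nt, r.alignment.tail,
            r.tail_class.value, r.ago_subclass,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return df.sort_values(
        ["insert", "chrom", "strand", "start"], kind="mergesort"
    ).reset_index(drop=True)
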
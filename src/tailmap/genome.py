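"""Synthetic genome construction and locus-annotation I/O.

The toy genome stands in for a real assembly: random ACGT chromosomes
carrying non-overlapping annotated loci of five classes (rRNA, tRNA,
miRNA, 21U piRNA loci and protein-coding mRNAs).  21U loci are packed
into dense clusters on the first chromosome, echoing the clustered
genomic organisation of nematode piRNA loci.  mRNA loci optionally
carry an Argonaute-target label (ERGO-1, ALG-3/4 or CSR-1) that is used
downstream to subclass antisense small RNAs.

Coordinates are 0-based half-open throughout the library; the GFF3
boundary converts to the 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOCUS_CLASSES = ("rRNA", "tRNA", "miRNA", "21U", "mRNA")
AGO_TARGETS = ("ERGO-1", "ALG-3/4", "CSR-1", "none")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BYTE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

#: fixed lengths (nt) for classes whose loci are size-invariant here
CLASS_LENGTHS = {"21U": 21, "miRNA": 22, "tRNA": 72, "rRNA": 120}

DEFAULT_AGO_FRACTIONS = {"ERGO-1": 0.20, "ALG-3/4": 0.20, "CSR-1": 0.25, "none": 0.35}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return seq.translate(_COMPLEMENT)[::-1]


class PackingError(ValueError):
    """Requested loci cannot be placed on the genome without overlap."""


@dataclass(frozen=True)
class LocusAnnotation:
    """A single annotated locus (0-based half-open interval)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    locus_class: str
    ago_target: str = "none"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.locus_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be + or -")
        if self.locus_class not in LOCUS_CLASSES:
            raise ValueError(f"{self.locus_id}: unknown locus_class {self.locus_class!r}")
        if self.ago_target not in AGO_TARGETS:
            raise ValueError(f"{self.locus_id}: unknown ago_target {self.ago_target!r}")
        if self.ago_target != "none" and self.locus_class != "mRNA":
            raise ValueError(f"{self.locus_id}: ago_target only applies to mRNA loci")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the locus 5' end on its own strand."""
        return self.start if self.strand == "+" else self.end - 1

    def sequence(self, chromosomes: Mapping[str, str]) -> str:
        """Locus sequence 5'->3' on the locus strand."""
        s = chromosomes[self.chrom][self.start:self.end]
        return s if self.strand == "+" else revcomp(s)


@dataclass
class GenomeBundle:
    """Chromosome sequences plus their locus annotations."""

    chromosomes: Dict[str, str]
    loci: List[LocusAnnotation] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for loc in self.loci:
            if loc.chrom not in self.chromosomes:
                raise ValueError(f"{loc.locus_id}: unknown chromosome {loc.chrom}")
            if loc.end > len(self.chromosomes[loc.chrom]):
                raise ValueError(f"{loc.locus_id}: interval exceeds chromosome")
            if loc.locus_class == "21U" and loc.length != 21:
                raise ValueError(f"{loc.locus_id}: 21U loci must be exactly 21 nt")
            if loc.locus_id in seen:
                raise ValueError(f"duplicate locus_id {loc.locus_id}")
            seen.add(loc.locus_id)

    def loci_of(self, *classes: str) -> List[LocusAnnotation]:
        return [l for l in self.loci if l.locus_class in classes]

    def locus(self, locus_id: str) -> LocusAnnotation:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.chromosomes.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for loc in sorted(self.loci, key=lambda l: (l.chrom, l.start, l.locus_id)):
                attrs = (
                    f"ID={loc.locus_id};locus_id={loc.locus_id};"
                    f"locus_class={loc.locus_class};ago_target={loc.ago_target}"
                )
                fh.write(
                    f"{loc.chrom}\ttailmap\t{loc.locus_class}\t{loc.start + 1}\t"
                    f"{loc.end}\t.\t{loc.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_files(cls, fasta_path, gff3_path) -> "GenomeBundle":
        chromosomes = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        loci = []
        with open(gff3_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                loci.append(
                    LocusAnnotation(
                        locus_id=attrs.get("locus_id", attrs.get("ID", "")),
                        chrom=cols[0],
                        start=int(cols[3]) - 1,
                        end=int(cols[4]),
                        strand=cols[6],
                        locus_class=attrs.get("locus_class", cols[2]),
                        ago_target=attrs.get("ago_target", "none"),
                    )
                )
        return cls(chromosomes=chromosomes, loci=loci)


# ---------------------------------------------------------------------------
# generation


def _overlaps(intervals, start, end) -> bool:
    return any(start < e and s < end for s, e in intervals)


def _decode(arr: np.ndarray) -> str:
    return _BYTE_TO_BASE[arr].tobytes().decode("ascii")


_ID_PREFIX = {"21U": "u21", "miRNA": "mir", "mRNA": "gene", "rRNA": "rrn", "tRNA": "trn"}


def generate_genome(
    n_chrom: int,
    lengths: Sequence[int],
    locus_plan: Mapping[str, int],
    seed: int,
    *,
    ago_fractions: Mapping[str, float] | None = None,
    mrna_length_range: tuple[int, int] = (600, 1200),
    n_21u_clusters: int = 2,
    write_dir=None,
    max_attempts: int = 1000,
) -> GenomeBundle:
    """Generate a random genome with non-overlapping annotated loci.

    Parameters
    ----------
    n_chrom, lengths
        Number of chromosomes and their lengths (each >= 1 kb).
    locus_plan
        Counts per locus class, e.g. ``{"21U": 30, "mRNA": 10}``.
    seed
        Master seed; identical seeds produce byte-identical FASTA/GFF3.
    ago_fractions
        Fractions of mRNA loci assigned to each Argonaute target label.
    write_dir
        If given, ``genome.fa`` and ``loci.gff3`` are written there.

    Raises
    ------
    PackingError
        If a class cannot be placed without overlap; the message names
        the offending class.
    """
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have one entry per chromosome")
    if any(L < 1000 for L in lengths):
        raise ValueError("chromosome lengths must be at least 1 kb")
    for cls in locus_plan:
        if cls not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class in plan: {cls!r}")

    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {name: rng.integers(0, 4, size=L, dtype=np.uint8) for name, L in zip(chrom_names, lengths)}
    occupied: Dict[str, list] = {name: [] for name in chrom_names}
    loci: List[LocusAnnotation] = []
    counters = {cls: 0 for cls in LOCUS_CLASSES}

    chrom_probs = np.asarray(lengths, dtype=float)
    chrom_probs /= chrom_probs.sum()

    def place(cls: str, length: int, chrom: str | None = None) -> tuple[str, int]:
        for _ in range(max_attempts):
            c = chrom if chrom is not None else chrom_names[rng.choice(n_chrom, p=chrom_probs)]
            L = len(seqs[c])
            if L < length:
                continue
            start = int(rng.integers(0, L - length + 1))
            if not _overlaps(occupied[c], start, start + length):
                occupied[c].append((start, start + length))
                return c, start
        raise PackingError(f"could not place {cls} locus without overlap")

    def new_id(cls: str) -> str:
        counters[cls] += 1
        return f"{_ID_PREFIX[cls]}-{counters[cls]:04d}"

    # larger features first so packing stays feasible
    for cls in ("mRNA", "rRNA", "tRNA", "miRNA"):
        for _ in range(locus_plan.get(cls, 0)):
            if cls == "mRNA":
                length = int(rng.integers(mrna_length_range[0], mrna_length_range[1] + 1))
            else:
                length = CLASS_LENGTHS[cls]
            chrom, start = place(cls, length)
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(
                LocusAnnotation(new_id(cls), chrom, start, start + length, strand, cls)
            )

    # 21U loci: clustered on the first chromosome
    n_21u = locus_plan.get("21U", 0)
    if n_21u:
        k = max(1, min(n_21u_clusters, n_21u))
        per_cluster = [n_21u // k + (1 if i < n_21u % k else 0) for i in range(k)]
        for n_in_cluster in per_cluster:
            gaps = rng.integers(4, 20, size=n_in_cluster)
            span = int(n_in_cluster * 21 + gaps.sum())
            chrom, block_start = place("21U", span, chrom=chrom_names[0])
            pos = block_start
            for g in gaps:
                loci.append(
                    LocusAnnotation(
                        new_id("21U"), chrom, pos, pos + 21,
                        "+" if rng.random() < 0.5 else "-", "21U",
                    )
                )
                pos += 21 + int(g)

    # Argonaute target labels for mRNA loci (largest-remainder allocation)
    fracs = dict(DEFAULT_AGO_FRACTIONS if ago_fractions is None else ago_fractions)
    mrna_idx = [i for i, l in enumerate(loci) if l.locus_class == "mRNA"]
    if mrna_idx:
        n_mrna = len(mrna_idx)
        labels = []
        quotas = {t: fracs.get(t, 0.0) * n_mrna for t in AGO_TARGETS}
        base = {t: int(q) for t, q in quotas.items()}
        short = n_mrna - sum(base.values())
        for t in sorted(AGO_TARGETS, key=lambda t: quotas[t] - base[t], reverse=True)[:short]:
            base[t] += 1
        for t in AGO_TARGETS:
            labels.extend([t] * base[t])
        labels = [labels[j] for j in rng.permutation(n_mrna)]
        for i, label in zip(mrna_idx, labels):
            l = loci[i]
            loci[i] = LocusAnnotation(
                l.locus_id, l.chrom, l.start, l.end, l.strand, l.locus_class, label
            )

    # enforce a 5' uridine on 21U loci (T in read space)
    for l in loci:
        if l.locus_class == "21U":
            if l.strand == "+":
                seqs[l.chrom][l.start] = 3  # T
            else:
                seqs[l.chrom][l.end - 1] = 0  # A on +, read 5' base is T

    bundle = GenomeBundle(
        chromosomes={name: _decode(arr) for name, arr in seqs.items()},
        loci=sorted(loci, key=lambda l: (l.chrom, l.start, l.locus_id)),
    )
    if write_dir is not None:
        write_dir = Path(write_dir)
        write_dir.mkdir(parents=True, exist_ok=True)
        bundle.to_fasta(write_dir / "genome.fa")
        bundle.to_gff3(write_dir / "loci.gff3")
    return bundle
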
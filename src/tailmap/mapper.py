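"""Prefix-anchored exact read mapping with 3' tail recording.

A read is placed on the genome wherever its first 18 nucleotides match
perfectly (either strand).  From each seed hit the match is extended
3'-wards as far as read and genome agree; the remaining, genome-
mismatching 3' suffix of the read is recorded as its non-templated
*tail*.  Only placements achieving the maximal matched length are kept,
so a tail never begins with a nucleotide that is genome-templated at
the next position — this makes "non-templated" operational.

Tails are classified by base content: ``U_TRIM`` if composed solely of
T bases (uridylation in read space), ``A_TRIM`` if solely A
(adenylation), ``OTHER`` for any mixed or C/G-containing tail, and
``NONE`` for tail-less reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Sequence, Tuple

from .genome import revcomp

logger = logging.getLogger(__name__)

SEED_LEN = 18

_VALID = frozenset("ACGT")


class ReadTooShortError(ValueError):
    """Read shorter than the seed length; reported as "too short"."""


class TailClass(str, Enum):
    U_TRIM = "U_TRIM"
    A_TRIM = "A_TRIM"
    OTHER = "OTHER"
    NONE = "NONE"


def classify_tail(tail: str) -> TailClass:
    """Classify a non-templated 3' tail by its base content."""
    if not set(tail) <= _VALID:
        raise ValueError(f"tail contains non-ACGT characters: {tail!r}")
    if not tail:
        return TailClass.NONE
    bases = set(tail)
    if bases == {"T"}:
        return TailClass.U_TRIM
    if bases == {"A"}:
        return TailClass.A_TRIM
    return TailClass.OTHER


@dataclass(frozen=True)
class TailAlignment:
    """A read's genomic placement plus its recorded 3' tail.

    ``start`` is the 0-based genomic position of the read's 5' end on
    its strand (for '-' placements the match runs leftwards on the
    reference).
    """

    insert: str
    chrom: str
    strand: str
    start: int
    matched_len: int
    tail: str
    n_hits: int

    def __post_init__(self):
        if self.matched_len < SEED_LEN:
            raise ValueError("matched_len must be >= seed length")
        if self.matched_len + len(self.tail) != len(self.insert):
            raise ValueError("matched_len + |tail| must equal |insert|")

    @property
    def tail_class(self) -> TailClass:
        return classify_tail(self.tail)


class GenomeIndex:
    """Exact-lookup index over all seed-length k-mers of both strands."""

    def __init__(self, chromosomes: Mapping[str, str], k: int = SEED_LEN):
        self.k = k
        self.chrom_lengths = {name: len(seq) for name, seq in chromosomes.items()}
        # strand-oriented sequences: reads extend rightwards on these
        self.strand_seqs: Dict[Tuple[str, str], str] = {}
        self._index: Dict[str, List[Tuple[str, str, int]]] = {}
        n_ambiguous = 0
        for name in sorted(chromosomes):
            seq = chromosomes[name].upper()
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
            for strand, sseq in (("+", seq), ("-", revcomp(seq))):
                self.strand_seqs[(name, strand)] = sseq
                bad = [i for i, ch in enumerate(sseq) if ch not in _VALID]
                bad_ptr = 0
                next_bad = bad[0] if bad else len(sseq)
                for i in range(len(sseq) - k + 1):
                    while next_bad < i:
                        bad_ptr += 1
                        next_bad = bad[bad_ptr] if bad_ptr < len(bad) else len(sseq)
                    if next_bad < i + k:
                        n_ambiguous += 1
                        continue
                    self._index.setdefault(sseq[i:i + k], []).append((name, strand, i))
        if n_ambiguous:
            logger.warning(
                "excluded %d k-mer positions containing ambiguous bases", n_ambiguous
            )

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, kmer: str) -> Sequence[Tuple[str, str, int]]:
        return self._index.get(kmer, ())

    def map_read(self, insert: str) -> List[TailAlignment]:
        return map_read(insert, self)


def map_read(insert: str, index: GenomeIndex) -> List[TailAlignment]:
    """Map a read by perfect 5'-anchored matching.

    Returns all maximal-matched-length placements (possibly empty).
    Every returned alignment carries the same matched length and tail.
    """
    k = index.k
    if len(insert) < k:
        raise ReadTooShortError("too short")
    hits = index.lookup(insert[:k])
    best_len = 0
    best: List[Tuple[str, str, int, int]] = []
    L = len(insert)
    for chrom, strand, off in hits:
        sseq = index.strand_seqs[(chrom, strand)]
        limit = min(L, len(sseq) - off)
        m = k
        while m < limit and insert[m] == sseq[off + m]:
            m += 1
        if m > best_len:
            best_len = m
            best = [(chrom, strand, off, m)]
        elif m == best_len:
            best.append((chrom, strand, off, m))
    if not best:
        return []
    tail = insert[best_len:]
    n_hits = len(best)
    alns = []
    for chrom, strand, off, m in best:
        N = index.chrom_lengths[chrom]
        start = off if strand == "+" else N - 1 - off
        alns.append(
            TailAlignment(
                insert=insert, chrom=chrom, strand=strand, start=start,
                matched_len=m, tail=tail, n_hits=n_hits,
            )
        )
    alns.sort(key=lambda a: (a.chrom, a.strand, a.start))
    return alns
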
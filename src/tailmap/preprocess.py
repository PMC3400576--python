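"""Read preprocessing: barcode demultiplexing, 3' adapter trimming and
collapsing of identical inserts.

Barcode matching is exact over the first four nucleotides (4-nt codes
at Hamming distance >= 2 make mismatch rescue unsafe).  Adapter
trimming removes the leftmost exact match of an adapter prefix of at
least ``min_overlap`` nt (or of the full adapter); reads without a
recognizable adapter are kept and flagged, since downstream mapping
trims residual 3' sequence anyway.  Collapsing groups identical inserts
into unique sequences with counts, in lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

BARCODE_LEN = 4


@dataclass(frozen=True, order=True)
class CollapsedRead:
    """A unique insert and the number of raw reads supporting it."""

    insert: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


def read_fastq_sequences(path) -> List[str]:
    """Sequences of a FASTQ file, in file order."""
    with open(path) as fh:
        return [seq for _, seq, _ in FastqGeneralIterator(fh)]


def demultiplex(
    reads: Iterable[str], barcodes: Sequence[str]
) -> Tuple[Dict[str, List[str]], int]:
    """Split reads by exact 4-nt barcode match.

    Returns a map barcode -> list of inserts (barcode stripped) and the
    number of discarded (non-matching or too-short) reads.
    """
    barcodes = list(barcodes)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be mutually distinct")
    for bc in barcodes:
        if len(bc) != BARCODE_LEN:
            raise ValueError(f"barcode {bc!r} is not {BARCODE_LEN} nt")
    assigned: Dict[str, List[str]] = {bc: [] for bc in barcodes}
    discarded = 0
    bc_set = set(barcodes)
    for read in reads:
        head = read[:BARCODE_LEN]
        if len(read) >= BARCODE_LEN and head in bc_set:
            assigned[head].append(read[BARCODE_LEN:])
        else:
            discarded += 1
    return assigned, discarded


def trim_adapter(insert: str, adapter: str, min_overlap: int = 6) -> Tuple[str, bool]:
    """Trim the 3' adapter off an insert.

    Scans for the leftmost position where either the full adapter
    occurs, or the read suffix exactly equals an adapter prefix of
    length >= ``min_overlap``.  Returns ``(trimmed_insert, trimmed)``;
    an insert without a match is returned unchanged with ``trimmed``
    False.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    alen = len(adapter)
    for i in range(len(insert) + 1):
        rest = len(insert) - i
        if rest >= alen:
            if insert[i:i + alen] == adapter:
                return insert[:i], True
        elif rest >= min_overlap:
            if insert[i:] == adapter[:rest]:
                return insert[:i], True
        else:
            break
    return insert, False


def collapse(inserts: Iterable[str]) -> List[CollapsedRead]:
    """Group identical inserts; deterministic lexicographic order."""
    counts: Dict[str, int] = {}
    for ins in inserts:
        counts[ins] = counts.get(ins, 0) + 1
    return [CollapsedRead(ins, counts[ins]) for ins in sorted(counts)]


def preprocess_library(
    inserts: Iterable[str],
    adapter: str,
    *,
    min_overlap: int = 6,
    min_len: int = 18,
) -> Tuple[List[CollapsedRead], Dict[str, int]]:
    """Adapter-trim, length-filter and collapse one demultiplexed library.

    Inserts shorter than ``min_len`` after trimming are discarded (the
    prefix-anchored mapper requires at least that many templated
    nucleotides).  Untrimmed reads are kept.
    """
    kept: List[str] = []
    stats = {"input": 0, "untrimmed": 0, "too_short": 0, "kept": 0}
    for ins in inserts:
        stats["input"] += 1
        trimmed, ok = trim_adapter(ins, adapter, min_overlap)
        if not ok:
            stats["untrimmed"] += 1
        if len(trimmed) < min_len:
            stats["too_short"] += 1
            continue
        kept.append(trimmed)
        stats["kept"] += 1
    return collapse(kept), stats


def write_collapsed_fasta(path, collapsed: Sequence[CollapsedRead]) -> None:
    """Write collapsed reads with count-annotated headers (seq_<i>_x<count>)."""
    with open(path, "w") as fh:
        for i, cr in enumerate(collapsed, start=1):
            fh.write(f">seq_{i}_x{cr.count}\n{cr.insert}\n")


def read_collapsed_fasta(path) -> List[CollapsedRead]:
    out: List[CollapsedRead] = []
    header = None
    seq_parts: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    out.append(_collapsed_from(header, "".join(seq_parts)))
                header, seq_parts = line[1:], []
            elif line:
                seq_parts.append(line)
    if header is not None:
        out.append(_collapsed_from(header, "".join(seq_parts)))
    return out


def _collapsed_from(header: str, seq: str) -> CollapsedRead:
    count = int(header.rsplit("_x", 1)[1]) if "_x" in header else 1
    return CollapsedRead(seq, count)
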
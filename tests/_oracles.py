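"""Independent brute-force oracles used by the test suite.

The mapping oracle performs an exhaustive longest-common-prefix scan
over every genomic offset of both strands, with only a trivial
first-two-base prefilter (offsets failing it have LCP < 2 and can never
reach the 18-nt seed requirement).  It shares no code with the k-mer
index implementation.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_force_map(insert: str, chromosomes: dict, k: int = 18):
    """All maximal perfect-prefix placements of ``insert`` (>= k nt
    matched), as sorted tuples (chrom, strand, start, matched_len, tail).

    ``start`` is the genomic position of the read's 5' end on its
    strand, matching the implementation's coordinate convention.
    """
    assert len(insert) >= k
    r0, r1 = insert[0].encode(), insert[1].encode()
    hits = []
    for chrom in sorted(chromosomes):
        seq = chromosomes[chrom]
        N = len(seq)
        for strand, sseq in (("+", seq), ("-", _revcomp(seq))):
            arr = np.frombuffer(sseq.encode(), dtype=np.uint8)
            cand = np.flatnonzero(
                (arr[: N - 1] == r0[0]) & (arr[1:] == r1[0])
            )
            for off in cand:
                off = int(off)
                limit = min(len(insert), N - off)
                if limit < k:
                    continue
                j = 2
                while j < limit and sseq[off + j] == insert[j]:
                    j += 1
                if j >= k:
                    hits.append((chrom, strand, off, j))
    if not hits:
        return []
    best = max(h[3] for h in hits)
    out = []
    for chrom, strand, off, m in hits:
        if m != best:
            continue
        N = len(chromosomes[chrom])
        start = off if strand == "+" else N - 1 - off
        out.append((chrom, strand, start, m, insert[m:]))
    return sorted(out)


def enumerate_tail_classes(k: int):
    """Direct enumeration of all 4**k tails, classified by an
    independent predicate (set comparison on the characters)."""
    from itertools import product

    counts = {"U_TRIM": 0, "A_TRIM": 0, "OTHER": 0, "NONE": 0}
    tails = []
    for combo in product("ACGT", repeat=k):
        tail = "".join(combo)
        if k == 0:
            cls = "NONE"
        elif all(c == "T" for c in tail):
            cls = "U_TRIM"
        elif all(c == "A" for c in tail):
            cls = "A_TRIM"
        else:
            cls = "OTHER"
        counts[cls] += 1
        tails.append(tail)
    return tails, counts
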
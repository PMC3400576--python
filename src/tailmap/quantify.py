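"""Library summaries and statistics for small-RNA tailing analysis.

Implements reads-per-million normalization over non-structural reads,
21U:miRNA abundance ratios, per-locus 20/21-mer length profiles,
non-templated tail frequency tables, siRNA length distributions, 26G
Argonaute-subclass ratios, CSR-1 target selection, two-replicate
differential-expression calls, grouped 22G coverage comparisons with
Wilcoxon tests, and small helpers (Pearson chi-squared on count tables,
squared Pearson correlation).

All stated thresholds (250 raw reads, 500 rpm, cloning ratio 0.9,
two-fold change, p < 0.05) are inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

STRUCTURAL_CLASSES = ("structural",)
RPM_SCALE = 1_000_000.0

#: classes pooled in the siRNA length-distribution panel
SIRNA_CLASSES = ("22G", "26G", "siRNA_other")


# ---------------------------------------------------------------------------
# rpm normalization


@dataclass
class LibrarySummary:
    """Per-class raw and rpm-normalized counts for one library.

    rpm is computed over non-structural reads only; those classes sum
    to one million by construction.  ``conversion_factor`` is the
    rpm-per-raw-read multiplier.
    """

    library_id: str
    raw: Dict[str, float]
    rpm: Dict[str, float]
    conversion_factor: float


def class_counts(annotated: pd.DataFrame) -> Dict[str, float]:
    """Weighted read count per rna_class."""
    return annotated.groupby("rna_class")["weight"].sum().to_dict()


def normalize_rpm(
    raw_counts: Mapping[str, float],
    library_id: str = "library",
    structural_classes: Sequence[str] = STRUCTURAL_CLASSES,
) -> LibrarySummary:
    """Reads-per-million over non-structural classes.

    Structural (rRNA/tRNA-matching) reads are excluded from the
    denominator and carry no rpm value.
    """
    non_structural = {
        c: v for c, v in raw_counts.items() if c not in structural_classes
    }
    total = float(sum(non_structural.values()))
    if total <= 0:
        raise ValueError("no non-structural reads; rpm undefined")
    factor = RPM_SCALE / total
    rpm = {c: v * factor for c, v in non_structural.items()}
    return LibrarySummary(
        library_id=library_id, raw=dict(raw_counts), rpm=rpm, conversion_factor=factor
    )


def ratio_21u_to_mirna(counts: Mapping[str, float] | LibrarySummary) -> float:
    """Total 21U reads normalized to total miRNA reads."""
    raw = counts.raw if isinstance(counts, LibrarySummary) else counts
    mirna = float(raw.get("miRNA", 0.0))
    if mirna <= 0:
        raise ValueError("zero miRNA reads; 21U:miRNA ratio undefined")
    return float(raw.get("21U", 0.0)) / mirna


# ---------------------------------------------------------------------------
# 21U length profiles


def length_profiles(annotated: pd.DataFrame, min_raw: float = 250.0) -> pd.DataFrame:
    """Per-21U-locus 20-mer/21-mer counts and 20-mer fraction.

    ``fraction_20 = count_20 / (count_20 + count_21)``; loci pass the
    filter when their raw (unnormalized, weighted) 20+21-mer total is
    at least ``min_raw`` (inclusive).
    """
    sub = annotated
    if "rna_class" in sub.columns:
        sub = sub[sub["rna_class"] == "21U"]
    rows = []
    for locus_id, grp in sub.groupby("locus_id"):
        c20 = float(grp.loc[grp["templated_length"] == 20, "weight"].sum())
        c21 = float(grp.loc[grp["templated_length"] == 21, "weight"].sum())
        total = c20 + c21
        if total <= 0:
            continue
        rows.append(
            {
                "locus_id": locus_id,
                "count_20": c20,
                "count_21": c21,
                "total_2021": total,
                "fraction_20": c20 / total,
                "passes_filter": total >= min_raw,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "count_20", "count_21", "total_2021",
                 "fraction_20", "passes_filter"],
    ).sort_values("locus_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# tail frequencies


@dataclass(frozen=True)
class TailFrequencyTable:
    """Non-templated addition frequencies as % of the class read count."""

    rna_class: str
    u_trim_pct: float
    a_trim_pct: float
    other_pct: float

    @property
    def tailed_pct(self) -> float:
        return self.u_trim_pct + self.a_trim_pct + self.other_pct


def tail_frequency(annotated: pd.DataFrame, rna_class: str | None = None) -> TailFrequencyTable:
    """Percentage of reads of one class carrying each tail type."""
    sub = annotated
    if rna_class is not None and "rna_class" in sub.columns:
        sub = sub[sub["rna_class"] == rna_class]
    total = float(sub["weight"].sum())
    if total <= 0:
        raise ValueError("empty class; tail frequencies undefined")
    by_tail = sub.groupby("tail_class")["weight"].sum()
    pct = {t: 100.0 * float(by_tail.get(t, 0.0)) / total
           for t in ("U_TRIM", "A_TRIM", "OTHER")}
    return TailFrequencyTable(
        rna_class=rna_class or "all",
        u_trim_pct=pct["U_TRIM"], a_trim_pct=pct["A_TRIM"], other_pct=pct["OTHER"],
    )


# ---------------------------------------------------------------------------
# length distributions and subclass ratios


def length_distribution(
    annotated: pd.DataFrame, lo: int = 18, hi: int = 30
) -> pd.Series:
    """Weighted histogram of templated lengths (bins ``lo``..``hi``).

    Lengths outside the range extend the index so that the bins always
    sum to the category total.
    """
    lengths = annotated["templated_length"]
    if len(lengths):
        lo = min(lo, int(lengths.min()))
        hi = max(hi, int(lengths.max()))
    idx = pd.Index(range(lo, hi + 1), name="templated_length")
    hist = annotated.groupby("templated_length")["weight"].sum()
    return hist.reindex(idx, fill_value=0.0)


def subclass_ratio(annotated_26g: pd.DataFrame) -> float:
    """Weighted ALG-3/4 : ERGO-1 ratio of 26G reads (unassigned excluded)."""
    sub = annotated_26g
    if "rna_class" in sub.columns:
        sub = sub[sub["rna_class"] == "26G"]
    by = sub.groupby("ago_subclass")["weight"].sum()
    ergo = float(by.get("ERGO-1", 0.0))
    alg = float(by.get("ALG-3/4", 0.0))
    if ergo <= 0:
        raise ValueError(
            "zero ERGO-1 26G reads; the ratio is undefined — report raw "
            f"counts instead (ALG-3/4: {alg})"
        )
    return alg / ergo


# ---------------------------------------------------------------------------
# target selection and DE calls


def select_csr1_targets(
    table: pd.DataFrame,
    min_rpm: float = 500.0,
    min_ratio: float = 0.9,
    *,
    gene_col: str = "gene_id",
    rpm_col: str = "rpm",
    ratio_col: str = "cloning_ratio",
) -> Set[str]:
    """Top-ranking CSR-1 targets: IP cloning frequency >= ``min_rpm``
    rpm AND cloning ratio >= ``min_ratio`` (both inclusive)."""
    for col in (gene_col, rpm_col, ratio_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    mask = (table[rpm_col] >= min_rpm) & (table[ratio_col] >= min_ratio)
    return set(table.loc[mask, gene_col])


@dataclass(frozen=True)
class DECall:
    """Two-replicate differential-expression call for one gene."""

    gene_id: str
    ratio_rep1: float
    ratio_rep2: float
    p_rep1: float
    p_rep2: float
    call: str  # up | down | unchanged


def call_de(
    table: pd.DataFrame, fold: float = 2.0, alpha: float = 0.05
) -> List[DECall]:
    """Call genes changed when both replicate p-values are below
    ``alpha`` and both expression ratios change at least ``fold``-fold
    in the same direction; discordant replicates are unchanged."""
    required = ("gene_id", "ratio_rep1", "ratio_rep2", "p_rep1", "p_rep2")
    for col in required:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if (table[["ratio_rep1", "ratio_rep2"]] <= 0).any().any():
        raise ValueError("expression ratios must be positive")
    calls = []
    for row in table.itertuples(index=False):
        sig = row.p_rep1 < alpha and row.p_rep2 < alpha
        if sig and row.ratio_rep1 >= fold and row.ratio_rep2 >= fold:
            call = "up"
        elif sig and row.ratio_rep1 <= 1.0 / fold and row.ratio_rep2 <= 1.0 / fold:
            call = "down"
        else:
            call = "unchanged"
        calls.append(
            DECall(row.gene_id, float(row.ratio_rep1), float(row.ratio_rep2),
                   float(row.p_rep1), float(row.p_rep2), call)
        )
    return calls


# ---------------------------------------------------------------------------
# grouped coverage comparisons


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Wilcoxon signed-rank test on paired vectors.

    Exact null distribution for n <= 25 without zeros/ties, otherwise a
    normal approximation with continuity correction; zero differences
    are rank-split; identical vectors give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    nz = d[d != 0]
    exact_ok = (
        len(d) <= 25
        and len(nz) == len(d)
        and len(np.unique(np.abs(nz))) == len(nz)
    )
    res = sps.wilcoxon(
        x, y, zero_method="zsplit", correction=True,
        method="exact" if exact_ok else "approx",
    )
    return float(res.statistic), float(res.pvalue)


def unpaired_ranksum(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney U) test, mid-ranks for ties."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """Per-group 22G coverage vectors and Wilcoxon test results."""

    groups: Dict[str, pd.DataFrame]
    paired: Dict[str, Tuple[float, float]]
    unpaired: Dict[Tuple[str, str, str], Tuple[float, float]]


def coverage_by_group(
    coverage: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
    lib_cols: Sequence[str] | None = None,
    *,
    gene_col: str = "gene_id",
) -> GroupComparison:
    """Compare per-gene 22G coverage between two libraries across gene
    groups.

    For each group a paired Wilcoxon test compares the two libraries
    over the group's genes; within each library, unpaired rank-sum
    tests compare every pair of groups.
    """
    if gene_col in coverage.columns:
        coverage = coverage.set_index(gene_col)
    if lib_cols is None:
        lib_cols = list(coverage.columns)
    if len(lib_cols) != 2:
        raise ValueError("exactly two library columns are required")
    group_frames: Dict[str, pd.DataFrame] = {}
    for name, genes in groups.items():
        genes = [g for g in genes if g in coverage.index]
        if len(genes) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 genes")
        group_frames[name] = coverage.loc[genes, list(lib_cols)]
    paired = {
        name: paired_wilcoxon(df[lib_cols[0]], df[lib_cols[1]])
        for name, df in group_frames.items()
    }
    unpaired: Dict[Tuple[str, str, str], Tuple[float, float]] = {}
    names = sorted(group_frames)
    for lib in lib_cols:
        for i, g1 in enumerate(names):
            for g2 in names[i + 1:]:
                unpaired[(lib, g1, g2)] = unpaired_ranksum(
                    group_frames[g1][lib], group_frames[g2][lib]
                )
    return GroupComparison(groups=group_frames, paired=paired, unpaired=unpaired)


# ---------------------------------------------------------------------------
# basic statistics


def chi_squared_counts(table) -> Tuple[float, float]:
    """Pearson chi-squared on an r x c contingency table of counts
    (no continuity correction), df = (r-1)(c-1)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; chi-squared undefined")
    stat, p, _, expected = sps.chi2_contingency(arr, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must all be positive")
    return float(stat), float(p)


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("R^2 undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
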
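"""Simulation of small-RNA sequencing libraries with ground truth.

The generator emulates the steady-state fate of small-RNA molecules
whose 3' ends may or may not be protected by 2'-O-methylation:

* each molecule originates from an annotated locus (miRNA, 21U piRNA,
  26G or 22G antisense siRNA, or a structural-RNA fragment), with
  log-normal per-locus abundance weights;
* it is methylated with a class- and genotype-dependent probability;
* unmethylated molecules may decay (Bernoulli survival), lose 3'
  nucleotides (trimming, with a locus-intrinsic Beta-distributed
  propensity) and/or acquire a non-templated 3' tail whose base
  composition is class specific (U-biased for 26G species);
* library treatment determines clonability: periodate oxidation leaves
  unmethylated molecules unclonable (small residual survival), and
  5'-triphosphate 22G species clone efficiently only after TAP
  treatment.

Sequencing attempts whose molecule is unclonable yield adaptor-only
reads and are not emitted; fixing the attempted depth therefore lets a
treatment change library *composition* without touching the absolute
yield of clonable (e.g. methylated) molecules — the mechanism behind
oxidation "enrichment".

The emitted FASTQ read is ``barcode + insert + 3' adapter`` padded to a
fixed read length; a truth table records, per emitted read, its origin
locus, class, methylation state, templated length and tail.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeBundle, LocusAnnotation, revcomp

#: simulated molecule classes (26G split by hosting Argonaute)
SIM_CLASSES = ("miRNA", "21U", "26G_ERGO1", "26G_ALG34", "22G", "structural")

#: classes carrying a 5'-triphosphate (RdRP products)
TRIPHOSPHATE_CLASSES = frozenset({"22G"})

#: Illumina-style small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_TAIL_BASES = np.frombuffer(b"TACG", dtype=np.uint8)  # order: U, A, C, G


def _validate_prob(name, p):
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ClassParams:
    """Per-class simulation parameters.

    ``tail_comp`` is the tail base composition (pi_U, pi_A, pi_C, pi_G);
    trim and tail lengths follow truncated geometric distributions with
    success parameters ``q_trim`` / ``q_tail`` (P(length = 1) before
    truncation) capped at ``max_trim`` / ``max_tail``.
    """

    weight: float
    methylation: float
    survival_unmeth: float
    p_trim: float
    p_tail: float
    tail_comp: Tuple[float, float, float, float]
    q_trim: float = 0.8
    max_trim: int = 3
    q_tail: float = 0.6
    max_tail: int = 4

    def __post_init__(self):
        for name in ("methylation", "survival_unmeth", "p_trim", "p_tail", "q_trim", "q_tail"):
            _validate_prob(name, getattr(self, name))
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if abs(sum(self.tail_comp) - 1.0) > 1e-9:
            raise ValueError("tail_comp must sum to 1 within 1e-9")


@dataclass(frozen=True)
class GenotypeParams:
    """Full parameterization of one genotype.

    ``trim_beta`` gives the Beta(alpha, beta) spread of locus-intrinsic
    trim propensities (None disables the spread, propensity 1 for all
    loci); methylated molecules use the near-zero ``baseline_trim`` /
    ``baseline_tail`` rates regardless of class.
    """

    name: str
    classes: Mapping[str, ClassParams]
    sigma_abund: float = 0.75
    trim_beta: Tuple[float, float] | None = (2.0, 8.0)
    baseline_trim: float = 0.005
    baseline_tail: float = 0.01

    def __post_init__(self):
        for c in self.classes:
            if c not in SIM_CLASSES:
                raise ValueError(f"unknown simulation class {c!r}")
        _validate_prob("baseline_trim", self.baseline_trim)
        _validate_prob("baseline_tail", self.baseline_tail)


@dataclass(frozen=True)
class TreatmentSpec:
    """Library treatment flags and their clonability parameters."""

    oxidized: bool = False
    tap_treated: bool = False
    unmethylated_ox_survival: float = 0.05
    triphosphate_clonability: float = 0.05
    extra_adaptor_loss: float = 0.0

    def __post_init__(self):
        _validate_prob("unmethylated_ox_survival", self.unmethylated_ox_survival)
        _validate_prob("triphosphate_clonability", self.triphosphate_clonability)
        _validate_prob("extra_adaptor_loss", self.extra_adaptor_loss)

    @property
    def effective_triphosphate_clonability(self) -> float:
        return 1.0 if self.tap_treated else self.triphosphate_clonability


# ---------------------------------------------------------------------------
# genotype presets

GENOTYPES = ("wild-type", "hypomorph", "null")
_METHYLATION_BY_GENOTYPE = {"wild-type": 0.98, "hypomorph": 0.5, "null": 0.0}


def genotype_preset(name: str) -> GenotypeParams:
    """Built-in genotype presets.

    ``wild-type``, ``hypomorph`` and ``null`` differ only in the
    methylation probability of the HEN1-substrate classes (21U and
    ERGO-1-bound 26G); ALG-3/4-bound 26G RNAs are never methylated but
    remain stable, and 22G/miRNA/structural species are unmethylated in
    all genotypes.
    """
    if name not in _METHYLATION_BY_GENOTYPE:
        raise ValueError(f"unknown genotype preset {name!r}; choose from {GENOTYPES}")
    mu = _METHYLATION_BY_GENOTYPE[name]
    classes = {
        "miRNA": ClassParams(
            weight=0.40, methylation=0.0, survival_unmeth=1.0,
            p_trim=0.02, p_tail=0.05, tail_comp=(0.4, 0.3, 0.15, 0.15),
        ),
        "21U": ClassParams(
            weight=0.15, methylation=mu, survival_unmeth=0.9,
            p_trim=1.0, p_tail=0.08, tail_comp=(0.3, 0.3, 0.2, 0.2),
        ),
        "26G_ERGO1": ClassParams(
            weight=0.06, methylation=mu, survival_unmeth=0.25,
            p_trim=0.3, p_tail=0.4, tail_comp=(0.7, 0.15, 0.075, 0.075),
        ),
        "26G_ALG34": ClassParams(
            weight=0.03, methylation=0.0, survival_unmeth=0.95,
            p_trim=0.05, p_tail=0.1, tail_comp=(0.5, 0.25, 0.125, 0.125),
        ),
        "22G": ClassParams(
            weight=0.25, methylation=0.0, survival_unmeth=1.0,
            p_trim=0.02, p_tail=0.05, tail_comp=(0.4, 0.3, 0.15, 0.15),
        ),
        "structural": ClassParams(
            weight=0.11, methylation=0.0, survival_unmeth=1.0,
            p_trim=0.0, p_tail=0.0, tail_comp=(0.25, 0.25, 0.25, 0.25),
        ),
    }
    return GenotypeParams(name=name, classes=classes)


# ---------------------------------------------------------------------------
# locus-intrinsic properties (stable across libraries)


def _locus_rng(locus_id: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(locus_id.encode("ascii")) & 0x7FFFFFFF)


def locus_abundance_weight(locus_id: str, sigma: float) -> float:
    """Log-normal abundance weight intrinsic to a locus."""
    rng = _locus_rng(locus_id)
    return float(np.exp(sigma * rng.standard_normal()))


def locus_trim_propensity(locus_id: str, alpha: float, beta: float) -> float:
    """Beta-distributed trim propensity intrinsic to a locus.

    Shared by every library simulated from the same genome, so that
    per-locus length-variant fractions are reproducible between
    independent libraries.
    """
    rng = _locus_rng(locus_id)
    rng.standard_normal()  # keep the abundance draw in its own slot
    return float(rng.beta(alpha, beta))


# ---------------------------------------------------------------------------
# mature-sequence pools


def _antisense_g_windows(chrom_seq: str, locus: LocusAnnotation, length: int) -> List[str]:
    """All antisense windows of ``length`` fully inside the locus whose
    read (antisense to the mRNA) starts with a 5' G."""
    out = []
    if locus.strand == "+":
        # read on '-': 5' end at genome pos j; needs complement(seq[j]) == G
        for j in range(locus.start + length - 1, locus.end):
            if chrom_seq[j] == "C":
                out.append(revcomp(chrom_seq[j - length + 1:j + 1]))
    else:
        for s in range(locus.start, locus.end - length + 1):
            if chrom_seq[s] == "G":
                out.append(chrom_seq[s:s + length])
    return out


@dataclass
class _ClassPool:
    loci: List[LocusAnnotation]
    candidates: List[List[str]]  # mature 5'->3' sequences per locus
    weights: np.ndarray
    propensity: np.ndarray


def _build_pools(bundle: GenomeBundle, params: GenotypeParams) -> Dict[str, _ClassPool]:
    a_b = params.trim_beta
    pools: Dict[str, _ClassPool] = {}

    def make_pool(loci, cand_fn):
        kept_loci, cands = [], []
        for loc in loci:
            c = cand_fn(loc)
            if c:
                kept_loci.append(loc)
                cands.append(c)
        if not kept_loci:
            return None
        w = np.array([locus_abundance_weight(l.locus_id, params.sigma_abund) for l in kept_loci])
        prop = (
            np.array([locus_trim_propensity(l.locus_id, *a_b) for l in kept_loci])
            if a_b is not None
            else np.ones(len(kept_loci))
        )
        return _ClassPool(kept_loci, cands, w / w.sum(), prop)

    chrom = bundle.chromosomes

    spec = {
        "miRNA": (bundle.loci_of("miRNA"), lambda l: [l.sequence(chrom)]),
        "21U": (bundle.loci_of("21U"), lambda l: [l.sequence(chrom)]),
        "26G_ERGO1": (
            [l for l in bundle.loci_of("mRNA") if l.ago_target == "ERGO-1"],
            lambda l: _pick_one(l, _antisense_g_windows(chrom[l.chrom], l, 26)),
        ),
        "26G_ALG34": (
            [l for l in bundle.loci_of("mRNA") if l.ago_target == "ALG-3/4"],
            lambda l: _pick_one(l, _antisense_g_windows(chrom[l.chrom], l, 26)),
        ),
        "22G": (
            bundle.loci_of("mRNA"),
            lambda l: _antisense_g_windows(chrom[l.chrom], l, 22),
        ),
        "structural": (bundle.loci_of("rRNA", "tRNA"), lambda l: [l.sequence(chrom)]),
    }
    for cname, (loci, fn) in spec.items():
        cp = params.classes.get(cname)
        if cp is None or cp.weight == 0:
            continue
        pool = make_pool(loci, fn)
        if pool is None:
            raise ValueError(
                f"class {cname!r} has weight {cp.weight} but no usable loci in the genome"
            )
        pools[cname] = pool
    return pools


def _pick_one(locus: LocusAnnotation, windows: List[str]) -> List[str]:
    """Fix a single 26G species per target gene, chosen deterministically."""
    if not windows:
        return []
    rng = _locus_rng(locus.locus_id + ":26G")
    return [windows[int(rng.integers(0, len(windows)))]]


def _trunc_geom(rng: np.random.Generator, q: float, kmax: int, n: int) -> np.ndarray:
    """Truncated-geometric lengths 1..kmax with pmf ~ q * (1-q)**(k-1)."""
    ks = np.arange(1, kmax + 1)
    pmf = q * (1.0 - q) ** (ks - 1)
    cdf = np.cumsum(pmf / pmf.sum())
    return 1 + np.searchsorted(cdf, rng.random(n), side="right").clip(max=kmax - 1)


def truncated_geometric_pmf(q: float, kmax: int) -> np.ndarray:
    """Renormalized pmf over lengths 1..kmax (index 0 is length 1)."""
    ks = np.arange(1, kmax + 1)
    pmf = q * (1.0 - q) ** (ks - 1)
    return pmf / pmf.sum()


# ---------------------------------------------------------------------------
# library simulation

TRUTH_COLUMNS = [
    "read_id", "locus_id", "sim_class", "genotype", "methylated",
    "templated_length", "tail", "expected_class", "expected_subclass",
    "oxidized", "tap_treated",
]


@dataclass
class SimulatedLibrary:
    """Reads plus ground truth for one simulated library."""

    reads: List[Tuple[str, str]]  # (read_id, sequence)
    truth: pd.DataFrame
    stats: Dict[str, int]
    barcode: str
    adapter: str

    def write_fastq(self, path, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _expected_annotation(sim_class: str, templated_length: int) -> Tuple[str, str]:
    if sim_class == "structural":
        return "structural", "unassigned"
    if sim_class == "miRNA":
        return "miRNA", "unassigned"
    if sim_class == "21U":
        return ("21U" if 18 <= templated_length <= 21 else "other"), "unassigned"
    if sim_class == "26G_ERGO1":
        return ("26G", "ERGO-1") if templated_length == 26 else ("siRNA_other", "unassigned")
    if sim_class == "26G_ALG34":
        return ("26G", "ALG-3/4") if templated_length == 26 else ("siRNA_other", "unassigned")
    if sim_class == "22G":
        return ("22G" if templated_length == 22 else "siRNA_other"), "unassigned"
    raise ValueError(sim_class)


def simulate_library(
    bundle: GenomeBundle,
    params: GenotypeParams,
    treatment: TreatmentSpec,
    depth: int,
    *,
    barcode: str = "ACTA",
    adapter: str = DEFAULT_ADAPTER,
    read_length: int = 50,
    seed: int = 0,
) -> SimulatedLibrary:
    """Simulate one sequencing library of ``depth`` attempted reads.

    Deterministic given ``seed``.  The random stream is consumed
    identically for every treatment, so two runs with the same seed and
    different treatments simulate the *same* molecules and differ only
    in which ones are clonable.
    """
    if len(barcode) != 4 or any(b not in "ACGT" for b in barcode):
        raise ValueError("barcode must be a 4-nt ACGT string")
    if not adapter or any(b not in "ACGT" for b in adapter):
        raise ValueError("adapter must be a non-empty ACGT string")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    rng = np.random.default_rng(seed)
    pools = _build_pools(bundle, params)
    classes = [c for c in SIM_CLASSES if c in pools]
    probs = np.array([params.classes[c].weight for c in classes], dtype=float)
    probs /= probs.sum()

    cls_draw = rng.choice(len(classes), size=depth, p=probs)

    inserts: List[str | None] = [None] * depth
    truth_rows: List[tuple] = []
    slot_truth: Dict[int, tuple] = {}

    for ci, cname in enumerate(classes):
        idx = np.flatnonzero(cls_draw == ci)
        n = len(idx)
        if n == 0:
            continue
        cp = params.classes[cname]
        pool = pools[cname]
        li = rng.choice(len(pool.loci), size=n, p=pool.weights)
        n_cand = np.array([len(c) for c in pool.candidates])
        cand = np.floor(rng.random(n) * n_cand[li]).astype(int)
        frag_u = rng.random(n)  # structural fragment lengths
        meth = rng.random(n) < cp.methylation
        u_surv = rng.random(n)
        u_trim = rng.random(n)
        u_tail = rng.random(n)
        trim_len_draw = _trunc_geom(rng, cp.q_trim, cp.max_trim, n)
        tail_len_draw = _trunc_geom(rng, cp.q_tail, cp.max_tail, n)
        u_tri = rng.random(n)
        u_ox = rng.random(n)
        u_loss = rng.random(n)

        survive = meth | (u_surv < cp.survival_unmeth)
        p_trim_eff = np.where(
            meth, params.baseline_trim, cp.p_trim * pool.propensity[li]
        )
        do_trim = u_trim < p_trim_eff
        p_tail_eff = np.where(meth, params.baseline_tail, cp.p_tail)
        do_tail = u_tail < p_tail_eff

        clonable = survive.copy()
        if cname in TRIPHOSPHATE_CLASSES:
            clonable &= u_tri < treatment.effective_triphosphate_clonability
        if treatment.oxidized:
            clonable &= meth | (u_ox < treatment.unmethylated_ox_survival)
            if treatment.extra_adaptor_loss > 0:
                clonable &= u_loss >= treatment.extra_adaptor_loss

        # tail sequences (drawn for all tailed molecules, emitted or not,
        # to keep the stream treatment-independent)
        tail_lens = np.where(do_tail, tail_len_draw, 0)
        total_tail = int(tail_lens.sum())
        tail_bases = rng.choice(4, size=total_tail, p=np.asarray(cp.tail_comp))
        tail_str_all = _TAIL_BASES[tail_bases].tobytes().decode("ascii")
        offsets = np.concatenate([[0], np.cumsum(tail_lens)]).astype(int)

        for k in range(n):
            if not clonable[k]:
                continue
            seq0 = pool.candidates[li[k]][cand[k]]
            if cname == "structural":
                max_frag = min(26, len(seq0))
                frag = 18 + int(frag_u[k] * (max_frag - 18 + 1))
                seq0 = seq0[:min(frag, len(seq0))]
            tlen = len(seq0)
            if do_trim[k]:
                tlen = max(18, tlen - int(trim_len_draw[k]))
            tail = tail_str_all[offsets[k]:offsets[k + 1]]
            slot = int(idx[k])
            inserts[slot] = seq0[:tlen] + tail
            exp_cls, exp_sub = _expected_annotation(cname, tlen)
            slot_truth[slot] = (
                pool.loci[li[k]].locus_id, cname, params.name, bool(meth[k]),
                tlen, tail, exp_cls, exp_sub,
                treatment.oxidized, treatment.tap_treated,
            )

    reads: List[Tuple[str, str]] = []
    for slot in range(depth):
        ins = inserts[slot]
        if ins is None:
            continue
        rid = f"sim_{slot:07d}"
        full = (barcode + ins + adapter)[:read_length]
        full = full + "A" * (read_length - len(full))
        reads.append((rid, full))
        truth_rows.append((rid,) + slot_truth[slot])

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    stats = {
        "depth": depth,
        "emitted": len(reads),
        "adaptor_only_or_lost": depth - len(reads),
    }
    return SimulatedLibrary(reads=reads, truth=truth, stats=stats,
                            barcode=barcode, adapter=adapter)
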
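"""Synthetic genome and library generator: determinism, packing,
parameter recovery and treatment semantics."""

import numpy as np
import pytest
from scipy import stats as sps

from tailmap.genome import GenomeBundle, PackingError, generate_genome
from tailmap.simulate import (
    ClassParams,
    GenotypeParams,
    TreatmentSpec,
    genotype_preset,
    locus_trim_propensity,
    simulate_library,
    truncated_geometric_pmf,
)

PLAN = {"21U": 30, "miRNA": 5, "mRNA": 10, "rRNA": 1, "tRNA": 2}


def single_class_params(name, **kw):
    """A one-class genotype with direct control of the fate parameters."""
    cp = ClassParams(
        weight=1.0,
        methylation=kw.get("methylation", 0.0),
        survival_unmeth=kw.get("survival_unmeth", 1.0),
        p_trim=kw.get("p_trim", 0.0),
        p_tail=kw.get("p_tail", 0.0),
        tail_comp=kw.get("tail_comp", (0.25, 0.25, 0.25, 0.25)),
        q_trim=kw.get("q_trim", 0.8),
        q_tail=kw.get("q_tail", 0.6),
    )
    return GenotypeParams(name="custom", classes={name: cp},
                          trim_beta=kw.get("trim_beta"))


class TestGenerateGenome:
    def test_locus_counts_and_disjointness(self, toy_bundle):
        assert len(toy_bundle.loci) == sum(PLAN.values()) == 48
        ivs = sorted((l.chrom, l.start, l.end) for l in toy_bundle.loci)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2, "loci must not overlap"
        for l in toy_bundle.loci:
            if l.locus_class == "21U":
                assert l.length == 21
                assert l.sequence(toy_bundle.chromosomes)[0] == "T"

    def test_deterministic_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_genome(1, [50_000], PLAN, seed=7, write_dir=d1)
        generate_genome(1, [50_000], PLAN, seed=7, write_dir=d2)
        assert (d1 / "genome.fa").read_bytes() == (d2 / "genome.fa").read_bytes()
        assert (d1 / "loci.gff3").read_bytes() == (d2 / "loci.gff3").read_bytes()

    def test_infeasible_packing_names_class(self):
        with pytest.raises(PackingError, match="mRNA"):
            generate_genome(1, [1000], {"mRNA": 500}, seed=3)

    def test_21u_loci_clustered_on_first_chromosome(self):
        b = generate_genome(2, [40_000, 40_000], PLAN, seed=5)
        u21 = b.loci_of("21U")
        assert {l.chrom for l in u21} == {"chr1"}
        # clustered: mean nearest-neighbour gap far below random expectation
        starts = sorted(l.start for l in u21)
        gaps = np.diff(starts)
        assert np.median(gaps) < 200

    def test_gff3_roundtrip(self, toy_bundle, tmp_path):
        toy_bundle.to_fasta(tmp_path / "g.fa")
        toy_bundle.to_gff3(tmp_path / "l.gff3")
        back = GenomeBundle.from_files(tmp_path / "g.fa", tmp_path / "l.gff3")
        assert back.chromosomes == toy_bundle.chromosomes
        assert back.loci == toy_bundle.loci


class TestSimulateLibrary:
    def test_truth_matches_fastq_and_determinism(self, toy_bundle, null_library):
        sim = null_library
        assert len(sim.reads) == len(sim.truth)
        again = simulate_library(
            toy_bundle, genotype_preset("null"), TreatmentSpec(), 20_000, seed=1
        )
        assert again.reads == sim.reads
        assert again.truth.equals(sim.truth)

    def test_forced_methylation(self, toy_bundle):
        params = genotype_preset("wild-type")
        cp = params.classes["21U"]
        params.classes["21U"] = ClassParams(
            weight=cp.weight, methylation=1.0, survival_unmeth=cp.survival_unmeth,
            p_trim=cp.p_trim, p_tail=cp.p_tail, tail_comp=cp.tail_comp,
        )
        sim = simulate_library(
            toy_bundle, params, TreatmentSpec(oxidized=True), 5000, seed=2
        )
        u21 = sim.truth[sim.truth.sim_class == "21U"]
        assert len(u21) > 0
        assert u21.methylated.all()

    def test_zero_survival_under_oxidation(self, toy_bundle):
        params = genotype_preset("null")  # methylation 0 for all classes
        treatment = TreatmentSpec(oxidized=True, unmethylated_ox_survival=0.0)
        sim = simulate_library(toy_bundle, params, treatment, 5000, seed=3)
        classes = set(sim.truth.sim_class)
        assert not classes & {"21U", "26G_ERGO1", "26G_ALG34"}

    def test_tailed_fraction_binomial(self, toy_bundle):
        p_tail, pi_u, q_tail, depth = 0.4, 0.7, 0.6, 20_000
        params = single_class_params(
            "26G_ERGO1", p_tail=p_tail, tail_comp=(pi_u, 0.15, 0.075, 0.075),
            q_tail=q_tail,
        )
        sim = simulate_library(toy_bundle, params, TreatmentSpec(), depth, seed=4)
        truth = sim.truth
        n = len(truth)
        obs = (truth["tail"] != "").mean()
        se = np.sqrt(p_tail * (1 - p_tail) / n)
        assert abs(obs - p_tail) < 3 * se
        # all-U tails: closed-form over the truncated-geometric tail lengths
        pmf = truncated_geometric_pmf(q_tail, 4)
        p_all_u = p_tail * sum(pmf[k - 1] * pi_u**k for k in range(1, 5))
        obs_u = truth["tail"].map(lambda t: bool(t) and set(t) == {"T"}).mean()
        se_u = np.sqrt(p_all_u * (1 - p_all_u) / n)
        assert abs(obs_u - p_all_u) < 3 * se_u

    def test_oxidation_preserves_methylated_yield(self, toy_bundle):
        """At fixed attempted depth and seed, oxidation only removes
        unmethylated molecules: methylated-origin reads are identical."""
        params = genotype_preset("wild-type")
        kw = dict(depth=10_000, seed=5)
        plain = simulate_library(toy_bundle, params, TreatmentSpec(), **kw)
        ox = simulate_library(toy_bundle, params, TreatmentSpec(oxidized=True), **kw)
        meth_plain = plain.truth[plain.truth.methylated]
        meth_ox = ox.truth[ox.truth.methylated]
        assert list(meth_plain.read_id) == list(meth_ox.read_id)

    def test_emitted_26g_nondecreasing_in_methylation(self, toy_bundle):
        counts = []
        for m in (0.0, 0.5, 1.0):
            total = 0
            for s in range(20):
                params = single_class_params(
                    "26G_ERGO1", methylation=m, survival_unmeth=0.2
                )
                sim = simulate_library(toy_bundle, params, TreatmentSpec(),
                                       2000, seed=100 + s)
                total += len(sim.truth)
            counts.append(total)
        assert counts[0] <= counts[1] <= counts[2]

    def test_trim_propensity_follows_beta(self):
        alpha, beta = 2.0, 8.0
        props = [locus_trim_propensity(f"u21-{i:04d}", alpha, beta)
                 for i in range(200)]
        res = sps.kstest(props, sps.beta(alpha, beta).cdf)
        assert res.pvalue > 0.01

    def test_input_validation(self, toy_bundle):
        params = genotype_preset("wild-type")
        with pytest.raises(ValueError, match="barcode"):
            simulate_library(toy_bundle, params, TreatmentSpec(), 10, barcode="ACT")
        with pytest.raises(ValueError, match="adapter"):
            simulate_library(toy_bundle, params, TreatmentSpec(), 10,
                             adapter="TGGAANN")
        with pytest.raises(ValueError, match="depth"):
            simulate_library(toy_bundle, params, TreatmentSpec(), 0)
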
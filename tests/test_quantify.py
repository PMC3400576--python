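"""Summaries, rule-based operations and statistical tests."""

import numpy as np
import pandas as pd
import pytest

from tailmap.quantify import (
    call_de,
    chi_squared_counts,
    correlation_r2,
    coverage_by_group,
    length_distribution,
    length_profiles,
    normalize_rpm,
    ratio_21u_to_mirna,
    select_csr1_targets,
    subclass_ratio,
    tail_frequency,
)


def frame(rows, columns=("locus_id", "templated_length", "weight", "rna_class",
                         "tail_class", "ago_subclass")):
    return pd.DataFrame(rows, columns=columns)


class TestNormalizeRpm:
    def test_structural_excluded_from_denominator(self):
        counts = {"miRNA": 600_000, "21U": 300_000, "other": 100_000,
                  "structural": 500_000}
        s = normalize_rpm(counts)
        assert s.rpm == {"miRNA": 600_000, "21U": 300_000, "other": 100_000}
        assert "structural" not in s.rpm
        assert s.conversion_factor == 1.0

    def test_all_structural_rejected(self):
        with pytest.raises(ValueError, match="non-structural"):
            normalize_rpm({"structural": 1000})

    def test_sum_is_one_million(self):
        rng = np.random.default_rng(0)
        counts = {c: float(v) for c, v in
                  zip("abcdef", rng.integers(1, 10_000, 6))}
        counts["structural"] = 5000.0
        s = normalize_rpm(counts)
        assert abs(sum(s.rpm.values()) - 1_000_000) < 0.5


class TestRatio21UMiRNA:
    def test_examples(self):
        assert ratio_21u_to_mirna({"21U": 200, "miRNA": 400}) == 0.5
        assert ratio_21u_to_mirna({"21U": 300, "miRNA": 300}) == 1.0

    def test_zero_mirna_rejected(self):
        with pytest.raises(ValueError, match="miRNA"):
            ratio_21u_to_mirna({"21U": 10, "miRNA": 0})


class TestLengthProfiles:
    def test_boundary_inclusive_at_250(self):
        rows = [("locA", 20, 50.0, "21U", "NONE", "unassigned"),
                ("locA", 21, 200.0, "21U", "NONE", "unassigned"),
                ("locB", 21, 10.0, "21U", "NONE", "unassigned")]
        prof = length_profiles(frame(rows), min_raw=250.0).set_index("locus_id")
        assert prof.loc["locA", "fraction_20"] == pytest.approx(0.2)
        assert bool(prof.loc["locA", "passes_filter"])
        assert not bool(prof.loc["locB", "passes_filter"])

    def test_zero_twenty_mers(self):
        rows = [("locA", 21, 100.0, "21U", "NONE", "unassigned")]
        prof = length_profiles(frame(rows), min_raw=50.0)
        assert prof["fraction_20"].iloc[0] == 0.0


class TestTailFrequency:
    def test_percentages_of_class_total(self):
        rows = (
            [("l", 21, 1.0, "21U", "U_TRIM", "unassigned")] * 7
            + [("l", 21, 1.0, "21U", "A_TRIM", "unassigned")] * 3
            + [("l", 21, 1.0, "21U", "OTHER", "unassigned")] * 2
            + [("l", 21, 1.0, "21U", "NONE", "unassigned")] * 88
        )
        t = tail_frequency(frame(rows), "21U")
        assert (t.u_trim_pct, t.a_trim_pct, t.other_pct) == (7.0, 3.0, 2.0)

    def test_no_tails(self):
        rows = [("l", 21, 5.0, "21U", "NONE", "unassigned")]
        t = tail_frequency(frame(rows), "21U")
        assert t.tailed_pct == 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tail_frequency(frame([]), "26G")


class TestLengthDistribution:
    def test_histogram_sums_to_total(self):
        rows = [("l", L, w, "22G", "NONE", "unassigned")
                for L, w in [(22, 10.0), (26, 5.5), (19, 1.0)]]
        hist = length_distribution(frame(rows))
        assert hist.sum() == pytest.approx(16.5)
        assert hist.loc[22] == 10.0

    def test_empty_input_all_zero(self):
        hist = length_distribution(frame([]))
        assert (hist == 0).all()
        assert list(hist.index) == list(range(18, 31))


class TestSubclassRatio:
    def test_examples(self):
        rows = (
            [("g1", 26, 1.0, "26G", "NONE", "ALG-3/4")] * 30
            + [("g2", 26, 1.0, "26G", "NONE", "ERGO-1")] * 60
            + [("g3", 26, 1.0, "26G", "NONE", "unassigned")] * 9
        )
        assert subclass_ratio(frame(rows)) == pytest.approx(0.5)

    def test_zero_ergo1_reports_counts(self):
        rows = [("g1", 26, 2.0, "26G", "NONE", "ALG-3/4")]
        with pytest.raises(ValueError, match="counts"):
            subclass_ratio(frame(rows))


class TestSelectCsr1Targets:
    def test_thresholds_inclusive(self):
        table = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e"],
                "rpm": [600, 600, 400, 500, 499.9],
                "cloning_ratio": [0.95, 0.85, 0.95, 0.9, 0.9],
            }
        )
        assert select_csr1_targets(table) == {"a", "d"}

    def test_empty_table(self):
        table = pd.DataFrame(columns=["gene_id", "rpm", "cloning_ratio"])
        assert select_csr1_targets(table) == set()

    def test_missing_column(self):
        with pytest.raises(ValueError, match="cloning_ratio"):
            select_csr1_targets(pd.DataFrame({"gene_id": [], "rpm": []}))


class TestCallDE:
    @pytest.mark.parametrize(
        "r1,r2,p1,p2,expected",
        [
            (2.1, 2.3, 0.01, 0.04, "up"),
            (2.1, 1.8, 0.01, 0.01, "unchanged"),
            (0.4, 0.45, 0.03, 0.02, "down"),
            (2.5, 2.5, 0.01, 0.06, "unchanged"),
            (2.5, 0.4, 0.01, 0.01, "unchanged"),
        ],
    )
    def test_two_replicate_rule(self, r1, r2, p1, p2, expected):
        table = pd.DataFrame(
            {"gene_id": ["g"], "ratio_rep1": [r1], "ratio_rep2": [r2],
             "p_rep1": [p1], "p_rep2": [p2]}
        )
        assert call_de(table)[0].call == expected

    def test_non_positive_ratio_rejected(self):
        table = pd.DataFrame(
            {"gene_id": ["g"], "ratio_rep1": [0.0], "ratio_rep2": [2.0],
             "p_rep1": [0.01], "p_rep2": [0.01]}
        )
        with pytest.raises(ValueError, match="positive"):
            call_de(table)


class TestCoverageByGroup:
    def _coverage(self, seed=0, n=200, down_scale=1.0, noise=0.3):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        base = rng.lognormal(5, 1, n)
        lib1 = base * rng.lognormal(0, noise, n)
        lib2 = base * down_scale * rng.lognormal(0, noise, n)
        return pd.DataFrame({"gene_id": genes, "wt": lib1, "mut": lib2})

    def test_identical_libraries_null_paired(self):
        cov = self._coverage()
        cov["mut"] = cov["wt"]
        res = coverage_by_group(cov, {"all": cov["gene_id"]})
        stat, p = res.paired["all"]
        assert p == 1.0

    def test_group_against_itself_unpaired_null(self):
        cov = self._coverage()
        res = coverage_by_group(
            cov, {"all": cov["gene_id"], "also_all": cov["gene_id"]}
        )
        for (lib, g1, g2), (stat, p) in res.unpaired.items():
            assert p > 0.95

    def test_small_group_rejected(self):
        cov = self._coverage()
        with pytest.raises(ValueError, match="fewer than 2"):
            coverage_by_group(cov, {"tiny": ["g0"]})

    def test_paired_power_under_30pct_drop(self):
        """A consistent 30% coverage drop over 200 genes is detected at
        alpha = 0.01 in at least 95% of seeded simulations."""
        rejections = 0
        for seed in range(100):
            cov = self._coverage(seed=seed, down_scale=0.7)
            res = coverage_by_group(cov, {"down": cov["gene_id"]})
            _, p = res.paired["down"]
            rejections += p < 0.01
        assert rejections >= 95


class TestChiSquared:
    def test_hand_computed_statistic(self):
        stat, p = chi_squared_counts([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, abs=1e-4)  # 6.6667, df = 1

    def test_zero_for_expected_table(self):
        stat, _ = chi_squared_counts([[15, 15], [15, 15]])
        assert stat == 0.0

    def test_doubling_cells_doubles_statistic(self):
        t = np.array([[12, 30, 8], [25, 9, 16]])
        s1, _ = chi_squared_counts(t)
        s2, _ = chi_squared_counts(2 * t)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared_counts([[0, 0], [5, 10]])


class TestCorrelationR2:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert correlation_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert correlation_r2(x, y) < 0.01

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert correlation_r2(x, y) == pytest.approx(correlation_r2(y, x))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
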
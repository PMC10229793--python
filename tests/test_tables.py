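"""Exact contingency tests, rank-sum, Wilson intervals, cohort tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dntp.tables import (ContingencyTable, EnumerationBoundError, fisher_2x2,
                         fisher_rxc, build_cohort_table, format_percent,
                         wilcoxon_rank_sum, wilson_ci)


class TestFisher2x2:
    @pytest.mark.parametrize("table,expected", [
        ([[25, 7], [12, 20]], 0.002),   # treatment x preference group
        ([[12, 11], [20, 21]], 1.000),  # Gleason < 8 / >= 8
        ([[12, 20], [20, 12]], 0.079),  # N stage
        ([[17, 20], [15, 12]], 0.613),  # biochemical recurrence
    ])
    def test_published_cohort_tables(self, table, expected):
        """Two-sided exact p-values match the printed clinical-table values
        at 3 decimals (minimum-likelihood two-sided rule)."""
        assert fisher_2x2(table) == pytest.approx(expected, abs=5e-4)

    def test_matches_direct_hypergeometric_enumeration(self):
        """Oracle sweep: p equals the explicit sum over the hypergeometric
        support for every 2x2 with small totals."""
        for a, b, c, d in itertools.product(range(5), repeat=4):
            tab = np.array([[a, b], [c, d]])
            if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                continue
            r1, c1, n = a + b, a + c, tab.sum()
            support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            probs = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in support}
            p_obs = probs[a]
            expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))
            assert fisher_2x2(tab) == pytest.approx(min(expected, 1.0), abs=1e-10)

    def test_zero_margin_defined_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_2x2([[0, 0], [3, 4]]) == 1.0

    def test_transpose_invariance(self):
        tab = np.array([[5, 9], [12, 3]])
        assert fisher_2x2(tab) == pytest.approx(fisher_2x2(tab.T), abs=1e-12)


class TestFisherRxC:
    def test_published_initial_psa_4x2(self):
        """The 4x2 initial-PSA table reproduces the printed 0.040."""
        table = [[1, 1], [1, 1], [11, 21], [19, 9]]
        assert fisher_rxc(table) == pytest.approx(0.040, abs=5e-4)

    def test_published_t_stage_4x2(self):
        table = [[1, 2], [7, 14], [13, 8], [11, 8]]
        assert fisher_rxc(table) == pytest.approx(0.210, abs=5e-4)

    def test_reduces_to_2x2(self):
        for tab in ([[3, 5], [8, 2]], [[25, 7], [12, 20]], [[1, 9], [9, 1]]):
            assert fisher_rxc(tab) == pytest.approx(fisher_2x2(tab), abs=1e-12)

    def test_zero_row_dropped(self):
        with_zero = [[4, 6], [0, 0], [7, 3]]
        without = [[4, 6], [7, 3]]
        assert fisher_rxc(with_zero) == pytest.approx(fisher_rxc(without),
                                                      abs=1e-12)

    def test_transpose_invariance(self):
        tab = np.array([[2, 5, 1], [6, 2, 4]])
        assert fisher_rxc(tab) == pytest.approx(fisher_rxc(tab.T), abs=1e-12)

    def test_enumeration_bound_is_explicit(self):
        big = (np.ones((5, 5), dtype=int) * 40)
        with pytest.raises(EnumerationBoundError):
            fisher_rxc(big, max_tables=1000)


class TestWilcoxon:
    def test_extreme_ranking_exact(self):
        """x={1,2,3} vs y={4,5,6}: the most extreme of C(6,3)=20 rank
        splits, two-sided exact p = 2/20 = 0.1."""
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_null(self):
        p = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_null_p_distribution_uniform(self):
        """Under the null the p-values are ~Uniform(0,1) (KS check)."""
        rng = np.random.default_rng(8)
        ps = [wilcoxon_rank_sum(rng.normal(size=25), rng.normal(size=25))
              for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestWilson:
    def test_zero_successes(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert hi == pytest.approx(0.2775, abs=5e-4)  # closed-form Wilson

    def test_half_is_centred(self):
        lo, hi = wilson_ci(5, 10)
        assert lo + hi == pytest.approx(1.0, abs=1e-10)

    def test_contains_bcr_proportion(self):
        lo, hi = wilson_ci(37, 64)
        assert lo < 37 / 64 < hi

    def test_invalid(self):
        with pytest.raises(ValueError):
            wilson_ci(11, 10)


class TestFormatting:
    @pytest.mark.parametrize("frac,expected", [
        (17 / 32, "53.12%"), (37 / 64, "57.81%"), (0.5, "50.00%"),
        (0.03125, "3.12%"), (0.055, "5.50%"),
    ])
    def test_round_half_even(self, frac, expected):
        assert format_percent(frac) == expected


class TestCohortTable:
    def test_counts_sum_to_group_n(self, default_cohort):
        clin = default_cohort.clinical.assign(
            arm=default_cohort.clinical["treatment"].map({0: "NCHT", 1: "NHT"}))
        table = build_cohort_table(clin, "arm",
                                   categorical=["gleason_cat", "n_stage"],
                                   continuous=["age"])
        n0 = (clin["arm"] == "NCHT").sum()
        gleason = table[table["variable"] == "gleason_cat"]
        col = [c for c in table.columns if c.startswith("NCHT")][0]
        counts = gleason[col].str.extract(r"^(\d+)")[0].astype(int)
        assert counts.sum() == n0

    def test_recurrence_percentage_style(self):
        clin = pd.DataFrame({
            "arm": ["NCHT"] * 32 + ["NHT"] * 32,
            "bcr": ["Yes"] * 17 + ["No"] * 15 + ["Yes"] * 20 + ["No"] * 12})
        table = build_cohort_table(clin, "arm", categorical=["bcr"])
        cell = table.loc[table["level"] == "Yes", "NCHT(n = 32)"].iloc[0]
        assert cell == "17 (53.12%)"
        p = table.loc[table["level"] == "Yes", "p"].iloc[0]
        assert p == "0.613(fisher.test)"

    def test_missing_excluded_from_test_but_displayed(self):
        clin = pd.DataFrame({
            "arm": ["A"] * 6 + ["B"] * 6,
            "var": ["x", "x", "y", "y", "y", "Missing"] * 2})
        table = build_cohort_table(clin, "arm", categorical=["var"])
        assert "Missing" in set(table["level"])
        # symmetric 2x2 after dropping Missing: p = 1
        assert table.loc[table["level"] == "x", "p"].iloc[0].startswith("1.000")

    def test_single_level_grouping_rejected(self):
        clin = pd.DataFrame({"arm": ["A", "A"], "v": ["x", "y"]})
        with pytest.raises(ValueError):
            build_cohort_table(clin, "arm", categorical=["v"])
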
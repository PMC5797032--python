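import numpy as np
import pytest

from nlmedrc import (
    GroupAssignment,
    ScenarioSpec,
    bonferroni_adjust,
    early_stop_threshold,
    fit_nlme_pooled,
    llr_from_logliks,
    llr_statistic,
    median_split,
    nlme_ic50_assoc,
    omnibus_perm_test,
    perm_pvalue,
    simulate_screen,
    trad_assoc,
)


class TestFormulas:
    def test_llr_arithmetic(self):
        assert llr_from_logliks(-100.0, -40.0, -45.0) == pytest.approx(30.0)

    @pytest.mark.parametrize("c, n, p", [(0, 100, 1 / 101), (100, 100, 1.0), (0, 9999, 1e-4)])
    def test_perm_pvalue(self, c, n, p):
        assert perm_pvalue(c, n) == pytest.approx(p)

    @pytest.mark.parametrize("c, n", [(-1, 100), (101, 100), (0, 0)])
    def test_perm_pvalue_bounds(self, c, n):
        with pytest.raises(ValueError):
            perm_pvalue(c, n)

    def test_early_stop_threshold_default_protocol(self):
        # at 100 permutations and alpha 0.05, p = (1+5)/101 > 0.05: stop at 5
        assert early_stop_threshold(100, 0.05) == 5
        assert perm_pvalue(5, 100) > 0.05
        assert perm_pvalue(4, 100) < 0.05

    def test_bonferroni(self):
        assert bonferroni_adjust([0.001] * 1)[0] * 345 == pytest.approx(0.345)
        assert bonferroni_adjust([0.001, 0.5, 0.2]) == pytest.approx([0.003, 1.0, 0.6])
        assert bonferroni_adjust([]) == []
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


class TestGroups:
    def test_median_split_even_no_ties(self):
        feats = {f"L{i}": float(i) for i in range(40)}
        g = median_split(feats)
        assert len(g.lines("plus")) == len(g.lines("minus")) == 20

    def test_median_split_tie_goes_minus(self):
        g = median_split({"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0})
        assert g.labels["b"] == g.labels["c"] == "minus"
        assert g.labels["d"] == "plus"

    def test_one_sided_assignment_rejected(self):
        with pytest.raises(ValueError):
            GroupAssignment({"a": "plus", "b": "plus"})
        with pytest.raises(ValueError):
            GroupAssignment({"a": "plus", "b": "up"})


class TestIC50Assoc:
    def test_perfect_correlation(self):
        vals = {f"L{i}": float(i) for i in range(5)}
        r, p = trad_assoc(vals, vals, mode="pearson")
        assert r == pytest.approx(1.0)

    def test_pearson_needs_three_pairs(self):
        with pytest.raises(ValueError):
            trad_assoc({"a": 1.0, "b": 2.0}, {"a": 0.1, "b": 0.2}, mode="pearson")

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            trad_assoc({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1, "b": 2, "c": 3}, mode="pearson")

    def test_ttest_group_sizes(self):
        ic50 = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.raises(ValueError):
            trad_assoc(ic50, {"a": "plus", "b": "minus", "c": "minus"}, mode="ttest")

    def test_missing_lines_dropped_pairwise(self):
        ic50 = {f"L{i}": float(i) for i in range(6)}
        feat = {f"L{i}": float(i) + 0.1 for i in range(1, 9)}
        r, _ = trad_assoc(ic50, feat, mode="pearson")
        assert r == pytest.approx(1.0)

    def test_nlme_assoc_deterministic(self, null_screen_50, null_fit_50):
        g = median_split(null_screen_50.expression)
        out1 = nlme_ic50_assoc(null_fit_50, g.labels, mode="ttest")
        out2 = nlme_ic50_assoc(null_fit_50, g.labels, mode="ttest")
        assert out1 == out2


def _small_groups(sim):
    return median_split(sim.expression)


class TestOmnibus:
    @pytest.fixture()
    def small_alt(self, shifted_screen_20):
        return shifted_screen_20

    def test_llr_nonnegative_and_separates(self, small_alt, null_screen_50):
        """LLR is ~0-ish for an arbitrary null split but large when the groups
        truly differ in x-mid."""
        g_alt = _small_groups(small_alt)
        llr_alt = llr_statistic(small_alt.screen, "drug1", g_alt)
        assert llr_alt >= -1e-6
        lines = sorted(null_screen_50.expression)[:20]
        g_null = GroupAssignment({l: ("plus" if i % 2 else "minus") for i, l in enumerate(lines)})
        sub = null_screen_50.screen[null_screen_50.screen["cell_line"].isin(lines)]
        llr_null = llr_statistic(sub, "drug1", g_null)
        assert llr_null >= -1e-6
        assert llr_alt > llr_null

    def test_llr_group_size_precondition(self, small_alt):
        lines = sorted(small_alt.expression)
        labels = {l: "minus" for l in lines}
        labels[lines[0]] = "plus"
        with pytest.raises(ValueError, match=">= 2"):
            llr_statistic(small_alt.screen, "drug1", GroupAssignment(labels))

    def test_omnibus_reproducible_and_consistent(self, small_alt):
        g = _small_groups(small_alt)
        r1 = omnibus_perm_test(small_alt.screen, "drug1", g, n_perm=19,
                               adaptive_n=None, seed=7)
        r2 = omnibus_perm_test(small_alt.screen, "drug1", g, n_perm=19,
                               adaptive_n=None, seed=7)
        assert r1 == r2
        assert r1.p_value == pytest.approx(perm_pvalue(r1.exceed_count, r1.n_perm))

    def test_omnibus_detects_xmid_shift(self, small_alt):
        g = _small_groups(small_alt)
        res = omnibus_perm_test(small_alt.screen, "drug1", g, n_perm=19,
                                adaptive_n=None, seed=3)
        assert res.p_value <= 0.10  # smallest attainable is 1/20

    def test_omnibus_escalates_when_significant(self, small_alt):
        g = _small_groups(small_alt)
        res = omnibus_perm_test(small_alt.screen, "drug1", g, n_perm=19,
                                adaptive_n=39, seed=3)
        assert res.escalated
        assert res.n_perm <= 39
        assert res.p_value == pytest.approx(perm_pvalue(res.exceed_count, res.n_perm))

    def test_omnibus_early_stops_on_null_split(self):
        sim = simulate_screen(ScenarioSpec(n_lines=12, seed=33))
        res = omnibus_perm_test(sim.screen, "drug1", _small_groups(sim), n_perm=99,
                                adaptive_n=None, seed=5)
        if res.stopped_early:  # expected for a null grouping
            assert res.n_perm < 99
            assert res.p_value > 0.05
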
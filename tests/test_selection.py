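import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microbiometab.datasets import clinical_summary, reference_selection, summary_groups
from microbiometab.selection import (annotate_direction, anova_from_summary,
                                     anova_oneway, select_metabolites,
                                     shapiro_wilk)


class TestShapiroWilk:
    def test_statistic_in_unit_interval(self, rng):
        w, p = shapiro_wilk(rng.normal(size=50))
        assert 0 < w <= 1

    def test_normal_samples_rarely_rejected(self):
        rejections = sum(shapiro_wilk(np.random.default_rng(s).normal(size=50))[1] < 0.05
                         for s in range(200))
        rate = rejections / 200
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200) + 0.01

    def test_exponential_samples_rejected(self):
        rejections = sum(shapiro_wilk(np.random.default_rng(s).exponential(size=100))[1] < 0.05
                         for s in range(100))
        assert rejections / 100 >= 0.9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([2.0] * 10)


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        assert anova_oneway(values, labels).f == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        values = rng.normal(size=14)
        labels = np.array(["a"] * 6 + ["b"] * 8)
        res = anova_oneway(values, labels)
        t, _ = stats.ttest_ind(values[:6], values[6:], equal_var=True)
        assert res.f == pytest.approx(t ** 2, abs=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        values = rng.normal(size=21)
        labels = np.repeat(["a", "b", "c"], 7)
        res = anova_oneway(values, labels)
        f, p = stats.f_oneway(*(values[labels == g] for g in "abc"))
        assert res.f == pytest.approx(f, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_summary_route_equals_raw_route(self, rng):
        for _ in range(20):
            values = rng.normal(size=24)
            labels = np.repeat(["a", "b", "c"], 8)
            raw = anova_oneway(values, labels)
            ns = [8, 8, 8]
            means = [values[labels == g].mean() for g in "abc"]
            sds = [values[labels == g].std(ddof=1) for g in "abc"]
            summ = anova_from_summary(ns, means, sds, list("abc"))
            assert summ.f == pytest.approx(raw.f, abs=1e-10)
            assert summ.p == pytest.approx(raw.p, abs=1e-10)
            pd.testing.assert_frame_equal(raw.tukey, summ.tukey, rtol=1e-10)

    def test_tukey_matches_scipy_tukey_hsd(self, rng):
        values = rng.normal(size=18)
        labels = np.repeat(["a", "b", "c"], 6)
        res = anova_oneway(values, labels)
        ref = stats.tukey_hsd(*(values[labels == g] for g in "abc"))
        # pair order: (a,b), (a,c), (b,c)
        ours = res.tukey["p_adj"].to_numpy()
        theirs = np.array([ref.pvalue[0, 1], ref.pvalue[0, 2], ref.pvalue[1, 2]])
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_tukey_adjusted_p_dominates_pairwise_t(self, rng):
        for _ in range(10):
            values = rng.normal(size=15)
            labels = np.repeat(["a", "b", "c"], 5)
            res = anova_oneway(values, labels)
            for _, row in res.tukey.iterrows():
                a = values[labels == row["group_1"]]
                b = values[labels == row["group_2"]]
                _, p_t = stats.ttest_ind(a, b, equal_var=True)
                assert row["p_adj"] >= p_t - 1e-12


class TestPublishedSummaries:
    @pytest.mark.parametrize("variable, printed_f", [("body_weight_kg", 39.59),
                                                     ("ede_restraint", 146.07)])
    def test_summary_anova_reproduces_printed_f(self, variable, printed_f):
        """Group mean/SD/n summaries reproduce the published F within
        the tolerance implied by 1-decimal rounding of the inputs."""
        row = clinical_summary().loc[variable]
        ns, means, sds, names = summary_groups(row)
        res = anova_from_summary(ns, means, sds, names)
        assert res.df_between == 2 and res.df_within == 40
        assert res.f == pytest.approx(printed_f, rel=0.02)


class TestSelectionRule:
    def _series(self, d):
        return pd.Series(d)

    def test_boundary_vip_not_selected(self):
        idx = ["m1"]
        out = select_metabolites(pd.Series([1.5], index=idx), pd.Series([0.1], index=idx),
                                 pd.Series([0.5], index=idx))
        assert len(out.selected) == 0

    def test_single_flag_selection(self):
        idx = ["m1"]
        out = select_metabolites(pd.Series([2.1], index=idx), pd.Series([0.2], index=idx),
                                 pd.Series([0.3], index=idx))
        row = out.selected.iloc[0]
        assert row["flag_plsda_3class"] and not row["flag_plsda_2class"] and not row["flag_anova"]

    def test_reference_fixture_reproduces_published_counts(self):
        """The encoded published selection outcome: 13 three-class flags,
        12 two-class flags, 28 selected metabolites in total."""
        ref = reference_selection()
        out = select_metabolites(ref["vip_3class"], ref["vip_2class"], ref["anova_p"],
                                 hmdb=ref["hmdb"])
        counts = out.counts()
        assert counts["plsda_3class"] == 13
        assert counts["plsda_2class"] == 12
        assert counts["total"] == 28
        pd.testing.assert_series_equal(out.table["flag_plsda_3class"],
                                       ref["flag_3class"], check_names=False)
        pd.testing.assert_series_equal(out.table["flag_anova"],
                                       ref["flag_anova"], check_names=False)

    def test_selection_monotone_in_vip(self, rng):
        idx = [f"m{i}" for i in range(20)]
        vip3 = pd.Series(rng.uniform(0, 3, 20), index=idx)
        vip2 = pd.Series(rng.uniform(0, 3, 20), index=idx)
        ps = pd.Series(rng.uniform(0, 1, 20), index=idx)
        before = set(select_metabolites(vip3, vip2, ps).selected.index)
        after = set(select_metabolites(vip3 + 0.5, vip2, ps).selected.index)
        assert before <= after


class TestDirections:
    def _values(self, ctrl, anr, anbp):
        idx = ([f"c{i}" for i in range(4)] + [f"r{i}" for i in range(4)]
               + [f"b{i}" for i in range(4)])
        vals = pd.DataFrame({"m": [ctrl] * 4 + [anr] * 4 + [anbp] * 4}, index=idx)
        labels = {**{f"c{i}": "CTRL" for i in range(4)},
                  **{f"r{i}": "ANR" for i in range(4)},
                  **{f"b{i}": "ANBP" for i in range(4)}}
        return vals, labels

    def test_both_below_control_lower_gets_double_arrow(self):
        vals, labels = self._values(ctrl=10.0, anr=8.0, anbp=5.0)
        out = annotate_direction(vals, labels)
        assert out.loc["m", "ANR"] == "down"
        assert out.loc["m", "ANBP"] == "down-down"

    def test_opposite_directions(self):
        vals, labels = self._values(ctrl=10.0, anr=12.0, anbp=4.0)
        out = annotate_direction(vals, labels)
        assert out.loc["m", "ANR"] == "up"
        assert out.loc["m", "ANBP"] == "down-down"

    def test_invariant_under_monotone_rescaling(self, rng):
        vals, labels = self._values(ctrl=10.0, anr=8.0, anbp=5.0)
        vals2 = vals * 3.5 + 1.0
        pd.testing.assert_frame_equal(annotate_direction(vals, labels),
                                      annotate_direction(vals2, labels))

    def test_planted_rhamnose_pattern_recovered(self, small_processed):
        """met_0001 is planted down in ANR and further down in ANBP."""
        processed, _, labels, truth = small_processed
        out = annotate_direction(processed.values, {s: labels[s] for s in processed.sample_ids})
        assert out.loc["met_0001", "ANR"] == "down"
        assert out.loc["met_0001", "ANBP"] == "down-down"
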
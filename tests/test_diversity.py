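import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microbiometab.datamodel import CohortLabels
from microbiometab.diversity import (alpha_group_test, bray_curtis, chao1,
                                     chao1_per_sample, nmds, permanova)
from microbiometab.preprocess import relative_abundance


class TestChao1:
    def test_worked_example(self):
        # S_obs=7, F1=3, F2=2 -> 7 + 3*2/6 = 8
        assert chao1([5, 3, 1, 1, 1, 2, 2]) == 8.0

    def test_no_singletons_collapses_to_observed(self):
        assert chao1([5, 2, 3, 2]) == 4.0

    def test_single_singleton(self):
        assert chao1([1]) == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty"):
            chao1([0, 0])

    @given(st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=50)
           .filter(lambda c: sum(c) > 0))
    @settings(max_examples=100, deadline=None)
    def test_at_least_observed_richness(self, counts):
        est = chao1(counts)
        s_obs = sum(1 for c in counts if c > 0)
        f1 = sum(1 for c in counts if c == 1)
        assert est >= s_obs
        assert (est == s_obs) == (f1 * (f1 - 1) == 0)

    def test_matches_skbio(self, small_cohort):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        otu = small_cohort[0]
        ours = chao1_per_sample(otu)
        for sid in otu.sample_ids:
            ref = skbio_alpha.chao1(otu.values.loc[sid].to_numpy(), bias_corrected=True)
            assert ours[sid] == pytest.approx(ref)


class TestAlphaGroupTest:
    def test_identical_groups_p_one(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                         index=[f"s{i}" for i in range(6)])
        labels = CohortLabels({f"s{i}": ("ANR" if i < 3 else "CTRL") for i in range(6)})
        out = alpha_group_test(vals, labels)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_group_order_does_not_change_p(self, rng):
        vals = pd.Series(rng.normal(size=8), index=[f"s{i}" for i in range(8)])
        l1 = CohortLabels({f"s{i}": ("ANR" if i < 4 else "CTRL") for i in range(8)})
        l2 = CohortLabels({f"s{i}": ("CTRL" if i < 4 else "ANR") for i in range(8)})
        assert alpha_group_test(vals, l1)["p"].iloc[0] == pytest.approx(
            alpha_group_test(vals, l2)["p"].iloc[0])

    def test_shifted_groups_detected(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15)])
            series = pd.Series(vals, index=[f"s{i}" for i in range(30)])
            labels = CohortLabels({f"s{i}": ("ANR" if i < 15 else "CTRL") for i in range(30)})
            hits += alpha_group_test(series, labels)["p"].iloc[0] < 0.01
        assert hits / 60 >= 0.95


class TestBrayCurtis:
    def test_identity_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert bray_curtis(df).loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        df = pd.DataFrame([[2.0, 0.0], [0.0, 2.0]], index=["a", "b"])
        assert bray_curtis(df).loc["a", "b"] == 1.0

    def test_worked_example_one_third(self):
        df = pd.DataFrame([[1.0, 1.0], [1.0, 3.0]], index=["a", "b"])
        assert bray_curtis(df).loc["a", "b"] == pytest.approx(1 / 3)

    def test_matrix_symmetric_zero_diag_unit_range(self, small_cohort):
        rel = relative_abundance(small_cohort[0])
        d = bray_curtis(rel).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_scale_invariance_on_relative_rows(self, rng):
        u = rng.random(6)
        v = rng.random(6)
        base = pd.DataFrame([u / u.sum(), v / v.sum()], index=["a", "b"])
        # relative abundances already row-normalised: scaling raw totals is a no-op
        assert bray_curtis(base).loc["a", "b"] == pytest.approx(
            bray_curtis(base * 1.0).loc["a", "b"])


class TestNmds:
    def test_three_equidistant_points_embed_exactly(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = nmds(d, k=2, n_starts=5, seed=0)
        assert res.stress < 1e-6

    def test_planar_configuration_recovers_low_stress(self, rng):
        x = rng.normal(size=(8, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dd = pd.DataFrame(d, index=range(8), columns=range(8))
        res = nmds(dd, k=2, n_starts=10, seed=1)
        assert res.stress < 1e-4

    def test_stress_non_increasing_within_a_start(self, rng):
        x = rng.normal(size=(10, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dd = pd.DataFrame(d, index=range(10), columns=range(10))
        res = nmds(dd, k=2, n_starts=1, seed=2)
        assert (np.diff(res.stress_trace) <= 1e-12).all()

    def test_coordinates_centered(self, small_cohort):
        rel = relative_abundance(small_cohort[0])
        res = nmds(bray_curtis(rel), k=2, n_starts=3, seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)


class TestPermanova:
    @pytest.fixture
    def four_points(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        d = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]),
                         index=list("abcd"), columns=list("abcd"))
        labels = CohortLabels({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        return d, labels

    def test_hand_partition_pseudo_f(self, four_points):
        d, labels = four_points
        res = permanova(d, labels, exhaustive=True)
        assert res.pseudo_f == pytest.approx(200.0)

    def test_exhaustive_p_one_third(self, four_points):
        d, labels = four_points
        assert permanova(d, labels, exhaustive=True).p_value == pytest.approx(1 / 3)

    def test_p_within_support_and_relabel_invariant(self, small_cohort):
        rel = relative_abundance(small_cohort[0])
        d = bray_curtis(rel)
        labels = small_cohort[2]
        res = permanova(d, labels, n_permutations=99, seed=5)
        assert 1 / 100 <= res.p_value <= 1
        renamed = CohortLabels({s: {"ANR": "x1", "ANBP": "x2", "CTRL": "x3"}[labels[s]]
                                for s in labels.sample_ids})
        res2 = permanova(d, renamed, n_permutations=99, seed=5)
        assert res2.pseudo_f == pytest.approx(res.pseudo_f)
        assert res2.p_value == pytest.approx(res.p_value)

    def test_matches_skbio_pseudo_f(self, small_cohort):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rel = relative_abundance(small_cohort[0])
        d = bray_curtis(rel)
        labels = small_cohort[2]
        ours = permanova(d, labels, n_permutations=9, seed=0)
        dm = skbio_stats.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        ref = skbio_stats.permanova(dm, grouping=[labels[s] for s in d.index],
                                    permutations=9)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_singleton_group_rejected(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        labels = CohortLabels.__new__(CohortLabels)
        labels._series = pd.Series({"a": "g1", "b": "g1", "c": "g2"})
        with pytest.raises(ValueError, match="size 1"):
            permanova(d, labels, n_permutations=9)
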
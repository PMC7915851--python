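import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microbiometab.datamodel import CohortLabels, FeatureTable
from microbiometab.integration import (CorrelationGrid, build_grids, concordance,
                                       spearman)


class TestSpearman:
    def test_monotone_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0

    def test_antitone_minus_one(self):
        rho, p = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == -1.0 and p == 0.0

    def test_tied_instance_matches_midrank_pearson(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        rho, _ = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_matches_scipy_spearmanr(self, rng):
        for _ in range(10):
            x = rng.integers(0, 5, size=12).astype(float)  # plenty of ties
            y = rng.normal(size=12)
            if np.ptp(x) == 0:
                continue
            rho, p = spearman(x, y)
            ref_rho, ref_p = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref_rho, abs=1e-12)
            assert p == pytest.approx(ref_p, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y ** 3 + 5 * y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_vector_missing_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1.0] * 5, [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)


def _grid_tables(rng, n_per=5, n_fam=4, n_met=3, groups=("ANR", "ANBP", "CTRL")):
    samples = [f"{g}_{i}" for g in groups for i in range(n_per)]
    fam = pd.DataFrame(rng.random((len(samples), n_fam)) + 0.01,
                       index=samples, columns=[f"F{j}" for j in range(n_fam)])
    met = pd.DataFrame(rng.normal(size=(len(samples), n_met)),
                       index=samples, columns=[f"m{j}" for j in range(n_met)])
    labels = CohortLabels({s: s.split("_")[0] for s in samples})
    fam_t = FeatureTable(fam.div(fam.sum(axis=1), axis=0), "relative_abundance")
    met_t = FeatureTable(met, "metabolite_processed")
    return fam_t, met_t, labels


class TestBuildGrids:
    def test_cell_count_is_product_of_dimensions(self, rng):
        fam_t, met_t, labels = _grid_tables(rng, n_fam=22, n_met=28)
        grids = build_grids(fam_t, met_t, labels)
        assert all(g.n_cells == 616 for g in grids.values())

    def test_planted_monotone_cell_perfect_in_one_group(self, rng):
        fam_t, met_t, labels = _grid_tables(rng)
        met = met_t.values.copy()
        anr = [s for s in met.index if s.startswith("ANR")]
        met.loc[anr, "m0"] = fam_t.values.loc[anr, "F0"] * 2 + 1  # monotone link
        grids = build_grids(fam_t, FeatureTable(met, "metabolite_processed"), labels)
        assert grids["ANR"].rho.loc["F0", "m0"] == pytest.approx(1.0)
        assert abs(grids["CTRL"].rho.loc["F0", "m0"]) < 1.0

    def test_sample_order_invariance(self, rng):
        fam_t, met_t, labels = _grid_tables(rng)
        grids1 = build_grids(fam_t, met_t, labels)
        perm = fam_t.values.sample(frac=1, random_state=3).index
        fam_p = FeatureTable(fam_t.values.loc[perm], "relative_abundance")
        met_p = FeatureTable(met_t.values.loc[perm], "metabolite_processed")
        grids2 = build_grids(fam_p, met_p, labels)
        for g in grids1:
            pd.testing.assert_frame_equal(grids1[g].rho, grids2[g].rho)

    def test_small_group_skipped_with_warning(self, rng):
        fam_t, met_t, labels = _grid_tables(rng, n_per=5)
        keep = [s for s in fam_t.sample_ids if not (s.startswith("ANBP") and s.endswith(("3", "4")))]
        fam_k = FeatureTable(fam_t.values.loc[keep], "relative_abundance")
        met_k = FeatureTable(met_t.values.loc[keep], "metabolite_processed")
        with pytest.warns(UserWarning, match="ANBP"):
            grids = build_grids(fam_k, met_k, labels.subset(keep))
        assert "ANBP" not in grids

    def test_shared_clustering_order_across_groups(self, rng):
        fam_t, met_t, labels = _grid_tables(rng, n_fam=6, n_met=5)
        grids = build_grids(fam_t, met_t, labels)
        orders = {(tuple(g.row_order), tuple(g.col_order)) for g in grids.values()}
        assert len(orders) == 1
        row_order, col_order = orders.pop()
        assert sorted(row_order) == sorted(fam_t.feature_ids)
        assert sorted(col_order) == sorted(met_t.feature_ids)


def _null_grid_pair(rng, cells=600):
    idx = [f"F{i}" for i in range(20)]
    cols = [f"m{j}" for j in range(cells // 20)]
    def one(g):
        rho = pd.DataFrame(rng.uniform(-1, 1, (len(idx), len(cols))), index=idx, columns=cols)
        p = pd.DataFrame(rng.uniform(0, 1, (len(idx), len(cols))), index=idx, columns=cols)
        return CorrelationGrid(g, rho, p, p < 0.05, idx, cols)
    return one("A"), one("B")


class TestConcordance:
    def test_grid_vs_itself_fully_concordant(self, rng):
        a, _ = _null_grid_pair(rng)
        b = CorrelationGrid("B", a.rho.copy(), a.p.copy(), a.mask.copy(),
                            a.row_order, a.col_order)
        out = concordance({"A": a, "B": b})
        assert out.per_pair["fraction_same_sign"].iloc[0] == 1.0

    def test_grid_vs_negation_zero_concordance(self, rng):
        a, _ = _null_grid_pair(rng)
        b = CorrelationGrid("B", -a.rho, a.p.copy(), a.mask.copy(),
                            a.row_order, a.col_order)
        out = concordance({"A": a, "B": b})
        assert out.per_pair["fraction_same_sign"].iloc[0] == 0.0

    def test_independent_null_grids_near_half(self):
        fracs = [concordance(dict(zip("AB", _null_grid_pair(np.random.default_rng(s)))))
                 .per_pair["fraction_same_sign"].iloc[0] for s in range(50)]
        se = np.sqrt(0.25 / 600)
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_mismatched_cell_sets_rejected(self, rng):
        a, b = _null_grid_pair(rng)
        b.rho = b.rho.iloc[:, :-1]
        b.p = b.p.iloc[:, :-1]
        with pytest.raises(ValueError, match="different cell sets"):
            concordance({"A": a, "B": b})

    def test_null_significance_fraction_near_alpha(self, rng):
        """Grid significance under a fully null simulation stays near 0.05."""
        fam_t, met_t, labels = _grid_tables(rng, n_per=10, n_fam=10, n_met=10,
                                            groups=("ANR", "CTRL"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grids = build_grids(fam_t, met_t, labels)
        fracs = [g.mask.to_numpy().mean() for g in grids.values()]
        n_cells = 100
        se = np.sqrt(0.05 * 0.95 / n_cells)
        for f in fracs:
            assert abs(f - 0.05) < 4 * se
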
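"""Group-wise Spearman correlation grids between taxon families and
selected metabolites, dual hierarchical clustering, and concordance
summaries.

Each group gets a families x metabolites grid of Spearman rho (midranks
for ties) with t-distribution p-values and a p < alpha significance mask.
Rows and columns are ordered by average-linkage hierarchical clustering on
(1 - rho) distance computed on the control grid; the same ordering is
reused across groups so the heatmaps stay visually comparable (per-group
clustering by flag). Concordance summaries report, per group, the
fraction of positive and significant correlations, and per group pair the
fraction of cells with the same rho sign (zero matches nothing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from microbiometab.datamodel import CohortLabels, FeatureTable


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (midranks) with the t-approximation p-value.

    rho is the Pearson correlation of midranks; p comes from
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom, with p = 0
    at |rho| = 1. Constant inputs yield NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; Spearman rho undefined")
        return np.nan, np.nan
    rho = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


@dataclass
class CorrelationGrid:
    group: str
    rho: pd.DataFrame      # families x metabolites
    p: pd.DataFrame
    mask: pd.DataFrame     # p < alpha
    row_order: list
    col_order: list

    @property
    def n_cells(self) -> int:
        return int(self.rho.size)


def _cluster_order(grid: pd.DataFrame, axis: int) -> list:
    """Average-linkage leaf order on (1 - rho) distances along *axis*."""
    data = grid if axis == 0 else grid.T
    labels_ax = list(data.index)
    if len(labels_ax) < 3:
        return sorted(labels_ax)
    filled = data.fillna(0.0)
    # (1 - rho) distance between profiles via their correlation
    corr = np.corrcoef(filled.to_numpy())
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = average(squareform(dist, checks=False))
    return [labels_ax[i] for i in leaves_list(link)]


def build_grids(family_table: FeatureTable, metabolite_table: FeatureTable,
                labels: CohortLabels, alpha: float = 0.05,
                cluster_on: str = "CTRL", per_group_clustering: bool = False,
                min_group_size: int = 4) -> dict[str, CorrelationGrid]:
    """Per-group Spearman grids with shared dual clustering order.

    Both tables must cover the same samples; the metabolite table should
    already be restricted to the selected metabolites and the taxon table
    aggregated at the family rank. Groups smaller than *min_group_size*
    are skipped with a warning.
    """
    shared = [s for s in family_table.sample_ids if s in set(metabolite_table.sample_ids)]
    if not shared:
        raise ValueError("tables share no samples")
    fam = family_table.values.loc[shared]
    met = metabolite_table.values.loc[shared]
    y = labels.as_array(shared)

    grids = {}
    for g in labels.groups:
        members = np.flatnonzero(y == g)
        if len(members) < min_group_size:
            warnings.warn(f"group {g} has n < {min_group_size}; grid skipped")
            continue
        fam_g = fam.iloc[members]
        met_g = met.iloc[members]
        rho = pd.DataFrame(index=fam.columns, columns=met.columns, dtype=float)
        pmat = pd.DataFrame(index=fam.columns, columns=met.columns, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for f in fam.columns:
                for m in met.columns:
                    r, p = spearman(fam_g[f], met_g[m])
                    rho.loc[f, m] = r
                    pmat.loc[f, m] = p
        grids[g] = CorrelationGrid(g, rho, pmat, pmat < alpha, [], [])

    if not grids:
        raise ValueError("no group large enough for a correlation grid")
    ref = grids.get(cluster_on, next(iter(grids.values())))
    if not per_group_clustering:
        row_order = _cluster_order(ref.rho, axis=0)
        col_order = _cluster_order(ref.rho, axis=1)
    for g, grid in grids.items():
        if per_group_clustering:
            row_order = _cluster_order(grid.rho, axis=0)
            col_order = _cluster_order(grid.rho, axis=1)
        grid.row_order = list(row_order)
        grid.col_order = list(col_order)
    return grids


@dataclass
class ConcordanceSummary:
    per_group: pd.DataFrame   # group, n_cells, fraction_positive, fraction_significant
    per_pair: pd.DataFrame    # group_1, group_2, fraction_same_sign


def concordance(grids: dict[str, CorrelationGrid]) -> ConcordanceSummary:
    """Positive/significant fractions per group and same-sign fractions per pair.

    Missing (NaN) cells are excluded from both numerator and denominator;
    a rho of exactly zero counts as not-same-sign against anything.
    """
    if len(grids) < 2:
        raise ValueError("need at least 2 grids")
    shapes = {g: (tuple(gr.rho.index), tuple(gr.rho.columns)) for g, gr in grids.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError("grids cover different cell sets")
    group_rows = []
    for g, gr in grids.items():
        rho = gr.rho.to_numpy(dtype=float).ravel()
        sig = gr.mask.to_numpy(dtype=bool).ravel()
        ok = ~np.isnan(rho)
        group_rows.append({"group": g, "n_cells": int(ok.sum()),
                           "fraction_positive": float((rho[ok] > 0).mean()),
                           "fraction_significant": float(sig[ok].mean())})
    pair_rows = []
    for g1, g2 in combinations(grids, 2):
        r1 = grids[g1].rho.to_numpy(dtype=float).ravel()
        r2 = grids[g2].rho.to_numpy(dtype=float).ravel()
        ok = ~np.isnan(r1) & ~np.isnan(r2)
        same = (np.sign(r1[ok]) == np.sign(r2[ok])) & (np.sign(r1[ok]) != 0)
        pair_rows.append({"group_1": g1, "group_2": g2,
                          "n_cells": int(ok.sum()),
                          "fraction_same_sign": float(same.mean())})
    return ConcordanceSummary(pd.DataFrame(group_rows), pd.DataFrame(pair_rows))
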
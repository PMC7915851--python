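"""Phylum comparisons, Bacteroidetes/Firmicutes ratio, and LEfSe-style
differential abundance with LDA effect sizes.

The LEfSe construction: taxa are aggregated at every rank from phylum to
genus, per-sample abundances scaled to sum 1e6 (the LEfSe convention);
stage 1 screens each clade with a Kruskal-Wallis test; stage 2 scores the
survivors with bootstrapped two-class linear discriminant analysis
(enriched group vs the rest) and reports

    effect = log10( mean over rounds of (|projected mean diff| + |raw mean diff|) / 2 )

floored at 1 before the log, so reported effects are >= 0 on the log10
scale. A clade is called differential when effect >= the LDA threshold
(default 2.0) and the screen p is below the display threshold (0.01).
The subclass (within-group strata) stage of the original tool is omitted:
this study design has no strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from microbiometab.datamodel import RANKS, CohortLabels, FeatureTable
from microbiometab.preprocess import aggregate_rank

LEFSE_SCALE = 1e6


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) and chi-square p.

    Degenerate all-tied input returns H = 0, p = 1 rather than erroring.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class LefseResult:
    """Per-clade screen and effect-size table plus the taxon->parent edges."""

    table: pd.DataFrame  # taxon, rank, H, p, enriched_group, lda_effect, significant
    edges: pd.DataFrame  # child, parent (for cladogram export)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _clade_matrix(relative_table: FeatureTable, ranks=None) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """All-rank clade abundance matrix scaled to 1e6 per sample per rank."""
    ranks = list(ranks or RANKS[1:])  # phylum .. genus
    blocks, rank_of, edge_rows = [], {}, []
    for rank in ranks:
        agg = aggregate_rank(relative_table, rank)
        block = agg.values * LEFSE_SCALE
        block.columns = [f"{rank[0]}|{c}" for c in block.columns]
        blocks.append(block)
        for c in block.columns:
            rank_of[c] = rank
    # parent edges via shared lineage prefixes
    lineages = relative_table.lineages()
    for lin in lineages:
        prev = None
        for rank in ranks:
            name = f"{rank[0]}|{lin.name_at(rank)}"
            if prev is not None:
                edge_rows.append({"child": name, "parent": prev})
            prev = name
    edges = pd.DataFrame(edge_rows).drop_duplicates().reset_index(drop=True)
    return pd.concat(blocks, axis=1), pd.Series(rank_of), edges


def lefse(relative_table: FeatureTable, labels: CohortLabels, screen_alpha: float = 0.05,
          display_alpha: float = 0.01, lda_threshold: float = 2.0, n_bootstrap: int = 30,
          bootstrap_fraction: float = 2 / 3, seed: int = 0) -> LefseResult:
    """LEfSe-style differential abundance across all taxonomic ranks."""
    matrix, rank_of, edges = _clade_matrix(relative_table)
    y = labels.as_array(matrix.index.tolist())
    rng = np.random.default_rng(seed)
    rows = []
    for clade in matrix.columns:
        v = matrix[clade].to_numpy()
        h, p = kruskal_wallis(v, y)
        row = {"taxon": clade, "rank": rank_of[clade], "H": h, "p": p,
               "enriched_group": "", "lda_effect": np.nan, "significant": False}
        if p < screen_alpha:
            means = {g: v[y == g].mean() for g in np.unique(y)}
            enriched = max(sorted(means), key=means.get)
            effect = _lda_effect(v, y == enriched, rng, n_bootstrap, bootstrap_fraction)
            if effect is None:
                warnings.warn(f"all bootstrap rounds skipped for {clade}; dropped")
                continue
            row.update(enriched_group=enriched, lda_effect=effect,
                       significant=bool(effect >= lda_threshold and p < display_alpha))
        rows.append(row)
    return LefseResult(pd.DataFrame(rows), edges)


def _lda_effect(values: np.ndarray, in_class: np.ndarray, rng, n_bootstrap: int,
                fraction: float) -> float | None:
    """Bootstrapped one-vs-rest LDA effect size for one clade."""
    n = len(values)
    size = max(2, int(round(fraction * n)))
    scores = []
    for _ in range(n_bootstrap):
        idx = rng.choice(n, size=size, replace=False)
        cls = in_class[idx]
        if cls.sum() < 3 or (~cls).sum() < 3:
            continue
        x = values[idx, None]
        raw_diff = abs(x[cls].mean() - x[~cls].mean())
        if np.ptp(x) == 0:
            proj_diff = 0.0
        else:
            lda = LinearDiscriminantAnalysis(solver="eigen")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    z = lda.fit(x, cls.astype(int)).transform(x).ravel()
                    proj_diff = abs(z[cls].mean() - z[~cls].mean())
                except Exception:
                    proj_diff = 0.0
        scores.append(0.5 * (proj_diff + raw_diff))
    if not scores:
        return None
    return float(np.log10(max(np.mean(scores), 1.0)))


def phylum_compare(relative_table: FeatureTable, labels: CohortLabels) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per group pair per phylum; raw p-values."""
    phyla = aggregate_rank(relative_table, "phylum")
    y = labels.as_array(phyla.sample_ids)
    rows = []
    for phylum in phyla.feature_ids:
        v = phyla.values[phylum].to_numpy(dtype=float)
        if (v == 0).all():
            continue
        for g1, g2 in combinations(labels.groups, 2):
            a, b = v[y == g1], v[y == g2]
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"phylum": phylum, "group_1": g1, "group_2": g2,
                         "U": float(u), "p": float(p),
                         "median_1": float(np.median(a)), "median_2": float(np.median(b))})
    return pd.DataFrame(rows)


def bf_ratio(relative_table: FeatureTable, labels: CohortLabels) -> tuple[pd.Series, float, float]:
    """Bacteroidetes-to-Firmicutes ratio per sample plus a Kruskal-Wallis test.

    Zero Firmicutes values are replaced by half the smallest positive
    Firmicutes abundance before the division.
    """
    phyla = aggregate_rank(relative_table, "phylum")
    for needed in ("Bacteroidetes", "Firmicutes"):
        if needed not in phyla.feature_ids:
            raise ValueError(f"phylum {needed!r} absent from table")
    bact = phyla.values["Bacteroidetes"].astype(float)
    firm = phyla.values["Firmicutes"].astype(float)
    if (firm == 0).any():
        positive = firm[firm > 0]
        if positive.empty:
            raise ValueError("Firmicutes absent from every sample")
        firm = firm.where(firm > 0, positive.min() / 2.0)
    ratio = (bact / firm).rename("bf_ratio")
    h, p = kruskal_wallis(ratio.to_numpy(), labels.as_array(ratio.index.tolist()))
    return ratio, h, p
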
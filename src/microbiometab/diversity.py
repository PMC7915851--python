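"""Alpha diversity (Chao1), Bray-Curtis beta diversity, NMDS, PERMANOVA.

Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)), robust when
no doubletons are observed. Group contrasts on alpha diversity are Welch
two-sample t-tests per group pair, reported as raw (uncorrected) p-values.
NMDS minimises Kruskal stress-1 by alternating isotonic regression of the
disparities with SMACOF majorisation steps, best of several random starts.
PERMANOVA follows Anderson's partition of the squared distances with a
label-permutation null; p = (1 + #{F_perm >= F_obs}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from microbiometab.datamodel import CohortLabels, FeatureTable


def chao1(sample_counts) -> float:
    """Bias-corrected Chao1 richness of one sample's count vector."""
    counts = np.asarray(sample_counts)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("empty sample")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def chao1_per_sample(table: FeatureTable) -> pd.Series:
    return pd.Series({sid: chao1(table.values.loc[sid]) for sid in table.sample_ids},
                     name="chao1")


def alpha_group_test(values: pd.Series, labels: CohortLabels) -> pd.DataFrame:
    """Welch two-sided t-test for every group pair; raw p-values.

    No multiplicity correction is applied — each pairwise contrast is
    reported on its own, as is conventional for a small number of
    planned diversity comparisons.
    """
    rows = []
    for g1, g2 in combinations(labels.groups, 2):
        a = values.loc[labels.group_members(g1)]
        b = values.loc[labels.group_members(g2)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group with fewer than 2 samples in pair ({g1}, {g2})")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"group_1": g1, "group_2": g2, "t": t, "p": p,
                     "mean_1": a.mean(), "mean_2": b.mean()})
    return pd.DataFrame(rows)


def bray_curtis(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = 1 - 2*sum(min)/(sum_u + sum_v)."""
    values = table.values if isinstance(table, FeatureTable) else table
    x = values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    totals = x.sum(axis=1)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[i], x[i + 1:]).sum(axis=1)
        denom = totals[i] + totals[i + 1:]
        if (denom == 0).any():
            raise ValueError("two all-zero samples")
        d[i, i + 1:] = d[i + 1:, i] = 1.0 - 2.0 * shared / denom
    return pd.DataFrame(d, index=values.index, columns=values.index)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    stress_trace: np.ndarray


def _stress1(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = (dist ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dist) ** 2).sum() / denom))


def nmds(distances: pd.DataFrame, k: int = 2, n_starts: int = 20, max_iter: int = 300,
         tol: float = 1e-7, seed: int = 0) -> NmdsResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Alternates isotonic regression of the disparities on the observed
    dissimilarity ranks with a SMACOF (Guttman transform) update of the
    configuration; keeps the lowest-stress solution over *n_starts* random
    initialisations. Coordinates are centered.
    """
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    if d.shape[1] != n or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distances must be a symmetric zero-diagonal square matrix")
    if k >= n:
        raise ValueError("k must be < n")
    iu = np.triu_indices(n, 1)
    delta = d[iu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression()
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_starts):
        x = rng.normal(size=(n, k))
        trace = []
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dist_full = np.sqrt((diff ** 2).sum(axis=2))
            dist = dist_full[iu]
            # monotone disparities: isotonic fit of distances on dissimilarity rank
            dhat = np.empty_like(dist)
            dhat[order] = iso.fit_transform(np.arange(len(order)), dist[order])
            # scale disparities to the configuration (Kruskal's normalisation)
            scale = (dist ** 2).sum() / max((dhat * dist).sum(), 1e-300)
            dhat_s = dhat * scale
            s = _stress1(dhat_s, dist)
            trace.append(s)
            if prev - s < tol:
                converged = True
                break
            prev = s
            # Guttman transform with disparities dhat_s
            dmat = np.zeros((n, n))
            dmat[iu] = dhat_s
            dmat = dmat + dmat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist_full > 0, dmat / dist_full, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = b @ x / n
        if best is None or trace[-1] < best[1]:
            best = (x, trace[-1], converged, np.array(trace))
    x, stress, converged, trace = best
    x = x - x.mean(axis=0)
    coords = pd.DataFrame(x, index=distances.index,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return NmdsResult(coords, stress, converged, trace)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def permanova(distances: pd.DataFrame, labels: CohortLabels, n_permutations: int = 999,
              seed: int = 0, exhaustive: bool = False) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous per-group
    terms; pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)). The p-value
    comes from random label permutations, with the observed statistic
    included in the null (add-one rule); with ``exhaustive=True`` every
    distinct labelling is enumerated instead and p is the exact fraction
    with F >= F_obs (feasible only for small cohorts).
    """
    d2 = distances.to_numpy(dtype=float) ** 2
    ids = list(distances.index)
    groups = labels.as_array(ids)
    n = len(ids)
    uniq, inv = np.unique(groups, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise ValueError("groups of size 1 are not allowed")
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")

    def pseudo_f(assign: np.ndarray) -> float:
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in range(k):
            idx = np.flatnonzero(assign == g)
            ss_within += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = pseudo_f(inv)
    if exhaustive:
        from itertools import permutations as _perms
        seen = set()
        fs = []
        for perm in _perms(range(n)):
            assign = inv[list(perm)]
            key = tuple(assign)
            if key in seen:
                continue
            seen.add(key)
            fs.append(pseudo_f(assign))
        fs = np.array(fs)
        p = float((fs >= f_obs - 1e-12).sum() / len(fs))
        return PermanovaResult(float(f_obs), p, len(fs))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(p), n_permutations)
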
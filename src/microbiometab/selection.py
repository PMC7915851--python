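"""Univariate metabolite statistics and the dual VIP/ANOVA selection rule.

The dual selection rule: a metabolite enters the
reported table when its 3-class PLS-DA VIP exceeds 1.5, its 2-class
(patient-subtype) VIP exceeds 1.5, or its one-way ANOVA p is below 0.05
(raw; no multiplicity correction by default, matching the convention of
reporting unadjusted p-values — a Benjamini-Hochberg switch exists).
Directions are annotated per AN group against the control mean:
up-arrow for above control, down-arrow for below, and a double down-arrow
when the group mean is below both the control and the other AN subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP, DOWN, DOUBLE_DOWN = "up", "down", "down-down"


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's approximation via scipy)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("constant input")
    w, p = stats.shapiro(values)
    return float(w), float(p)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # group_1, group_2, difference, q, p_adj
    degenerate: bool = False


def _anova_core(ns, means, sds, group_names) -> AnovaResult:
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("negative standard deviation")
    k, n = len(ns), ns.sum()
    grand = (ns * means).sum() / n
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds ** 2).sum()
    df_b, df_w = k - 1, int(n - k)
    ms_between = ss_between / df_b
    degenerate = ss_within == 0
    if degenerate:
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        ms_within = ss_within / df_w
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_b, df_w))
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if degenerate:
            q = np.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            # Tukey-Kramer studentized range statistic
            se = np.sqrt(ss_within / df_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group_1": group_names[i], "group_2": group_names[j],
                     "difference": float(diff), "q": float(q),
                     "p_adj": min(max(p_adj, 0.0), 1.0)})
    return AnovaResult(float(f), df_b, df_w, float(p), pd.DataFrame(rows), degenerate)


def anova_oneway(values, labels) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD (Tukey-Kramer) post hoc."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = [int((labels == g).sum()) for g in groups]
    means = [values[labels == g].mean() for g in groups]
    sds = [values[labels == g].std(ddof=1) for g in groups]
    return _anova_core(ns, means, sds, list(groups))


def anova_from_summary(ns, means, sds, group_names=None) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, sd) summaries.

    Algebraically identical to :func:`anova_oneway` on matching raw data:
    SS_between = sum n_i (m_i - m)^2, SS_within = sum (n_i - 1) s_i^2.
    Useful for recomputing F statistics from published summary tables.
    """
    if group_names is None:
        group_names = [f"group_{i + 1}" for i in range(len(ns))]
    return _anova_core(ns, means, sds, list(group_names))


@dataclass
class SelectionTable:
    """Per-metabolite selection flags, VIPs, ANOVA p, and direction symbols."""

    table: pd.DataFrame

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table[["flag_plsda_3class", "flag_plsda_2class", "flag_anova"]].any(axis=1)]

    def counts(self) -> dict:
        sel = self.selected
        return {
            "plsda_3class": int(sel["flag_plsda_3class"].sum()),
            "plsda_2class": int(sel["flag_plsda_2class"].sum()),
            "anova": int(sel["flag_anova"].sum()),
            "total": int(len(sel)),
        }


def select_metabolites(vip3: pd.Series, vip2: pd.Series, anova_ps: pd.Series,
                       vip_threshold: float = 1.5, anova_alpha: float = 0.05,
                       hmdb: pd.Series | None = None,
                       adjust: bool = False) -> SelectionTable:
    """Dual VIP/ANOVA selection.

    Flags use strict inequalities (VIP strictly above the threshold); a
    metabolite appears in the selected view iff at least one flag is set.
    ``adjust=True`` applies Benjamini-Hochberg to the ANOVA p's first.
    """
    idx = vip3.index
    if not (idx.equals(vip2.index) and idx.equals(anova_ps.index)):
        raise ValueError("inputs must share the same metabolite index")
    ps = anova_ps.astype(float)
    if adjust:
        ps = pd.Series(multipletests(ps.to_numpy(), method="fdr_bh")[1], index=idx)
    table = pd.DataFrame({
        "hmdb": hmdb.reindex(idx) if hmdb is not None else "",
        "vip_3class": vip3.astype(float),
        "vip_2class": vip2.astype(float),
        "anova_p": ps,
        "flag_plsda_3class": vip3.astype(float) > vip_threshold,
        "flag_plsda_2class": vip2.astype(float) > vip_threshold,
        "flag_anova": ps < anova_alpha,
    })
    return SelectionTable(table)


def annotate_direction(metabolite_values: pd.DataFrame, labels, control: str = "CTRL",
                       an_groups: tuple = ("ANR", "ANBP")) -> pd.DataFrame:
    """Direction symbols per metabolite per AN group, relative to controls.

    ``up`` if the group mean exceeds the control mean, else ``down``;
    upgraded to ``down-down`` when the mean is strictly below both the
    control and the other AN group. Exact ties break toward ``down``.
    """
    y = np.asarray([labels[s] for s in metabolite_values.index])
    means = {g: metabolite_values[y == g].mean(axis=0) for g in (control, *an_groups)}
    out = {}
    for g in an_groups:
        other = [h for h in an_groups if h != g][0]
        symbols = []
        for met in metabolite_values.columns:
            mg, mc, mo = means[g][met], means[control][met], means[other][met]
            if mg > mc:
                symbols.append(UP)
            elif mg < mc and mg < mo:
                symbols.append(DOUBLE_DOWN)
            else:
                symbols.append(DOWN)
        out[g] = symbols
    return pd.DataFrame(out, index=metabolite_values.columns)
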
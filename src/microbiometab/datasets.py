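"""Bundled reference tables.

``clinical_summary`` holds the published per-group clinical summaries
(n, mean, SD per group) with the printed F and p values, usable as input
to :func:`microbiometab.selection.anova_from_summary`.

``reference_selection`` is a synthetic fixture encoding the published
metabolite selection outcome: the real metabolite names, HMDB codes,
selection flags, and direction symbols, paired with synthetic VIP and
ANOVA-p columns constructed to be consistent with those flags (the
original statistics are not public). It exercises the selection-rule
bookkeeping, not the underlying model fits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

GROUP_ORDER = ("ANR", "ANBP", "CTRL")


def _data_path(name: str):
    return resources.files("microbiometab") / "data" / name


def clinical_summary() -> pd.DataFrame:
    """Published clinical summary statistics, one row per variable."""
    return pd.read_csv(_data_path("clinical_summary.tsv"), sep="\t", index_col=0)


def summary_groups(row: pd.Series) -> tuple[list, list, list, list]:
    """Unpack one clinical_summary row into (ns, means, sds, group names)."""
    ns = [int(row[f"n_{g}"]) for g in GROUP_ORDER]
    means = [float(row[f"mean_{g}"]) for g in GROUP_ORDER]
    sds = [float(row[f"sd_{g}"]) for g in GROUP_ORDER]
    return ns, means, sds, list(GROUP_ORDER)


def reference_selection() -> pd.DataFrame:
    """Synthetic fixture encoding the published selection flags/directions."""
    df = pd.read_csv(_data_path("reference_selection.tsv"), sep="\t", index_col=0)
    for c in ("flag_3class", "flag_2class", "flag_anova"):
        df[c] = df[c].astype(bool)
    return df
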
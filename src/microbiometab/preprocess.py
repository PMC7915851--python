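"""Metabolite normalisation/scaling and OTU rarefaction/aggregation.

Metabolite route: internal-standard division -> zero replacement (half the
smallest positive value per metabolite) -> natural log -> autoscale (mean 0,
sd 1 with the n-1 denominator). The log is applied before autoscaling:
autoscaled data contain negatives on which a log is undefined, so this is
the only coherent order. Constant columns are flagged, not fatal.

OTU route: rarefaction (subsampling without replacement to a common depth),
relative abundance, and lineage-prefix aggregation to any rank with empty
rank names pooled as ``unclassified_<parent>``.

Every transform appends a ``(name, params)`` entry to the table's
transform record; :func:`replay` re-applies a record to the raw table and
reproduces the processed table exactly (rarefaction is seeded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from microbiometab.datamodel import RANKS, FeatureTable
from microbiometab.simulate import INTERNAL_STANDARD


def normalize_internal_standard(table: FeatureTable, is_column: str = INTERNAL_STANDARD) -> FeatureTable:
    """Divide each sample's peak areas by its internal-standard area.

    Removes injection variability; the internal-standard column is dropped
    from the result.
    """
    if is_column not in table.values.columns:
        raise ValueError(f"internal-standard column {is_column!r} not in table")
    is_values = table.values[is_column]
    bad = is_values.index[is_values <= 0]
    if len(bad):
        raise ValueError(f"non-positive internal standard in sample {bad[0]!r}")
    values = table.values.drop(columns=[is_column]).div(is_values, axis=0)
    return table.with_values(values, kind="metabolite_processed",
                             record=("normalize_internal_standard", {"is_column": is_column}))


def log_then_autoscale(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Half-minimum zero replacement, natural log, then per-column autoscale.

    Returns the processed table and the list of constant (flagged) columns,
    which are centered but left unscaled.
    """
    values = table.values.astype(float).copy()
    if (values.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative values")
    pseudo = {}
    for col in values.columns:
        v = values[col]
        if (v == 0).any():
            positive = v[v > 0]
            if positive.empty:
                raise ValueError(f"metabolite {col!r} is all zero")
            pseudo[col] = positive.min() / 2.0
            values[col] = v.where(v > 0, pseudo[col])
    logged = np.log(values)
    means = logged.mean(axis=0)
    sds = logged.std(axis=0, ddof=1)
    constant = list(sds.index[(sds == 0) | sds.isna()])
    scale = sds.replace(0, 1.0).fillna(1.0)
    scaled = (logged - means) / scale
    out = table.with_values(scaled, kind="metabolite_processed",
                            record=("log_then_autoscale", {"pseudo_values": pseudo,
                                                           "constant_columns": constant}))
    return out, constant


def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> FeatureTable:
    """Subsample each sample without replacement to exactly *depth* reads.

    Defaults to the minimum sample total. Samples with fewer reads than
    *depth* are dropped (with the standard rarefaction caveat that this
    discards data).
    """
    if table.kind != "otu_counts":
        raise ValueError("rarefaction requires an OTU count table")
    totals = table.values.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    keep = totals.index[totals >= depth]
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(0, index=keep, columns=table.values.columns, dtype=np.int64)
    for sid in keep:
        counts = table.values.loc[sid].to_numpy()
        total = counts.sum()
        if total == depth:
            out.loc[sid] = counts
            continue
        # multivariate hypergeometric draw = subsampling reads without replacement
        out.loc[sid] = rng.multivariate_hypergeometric(counts, depth)
    return table.with_values(out, record=("rarefy", {"depth": depth, "seed": seed}))


def relative_abundance(table: FeatureTable) -> FeatureTable:
    totals = table.values.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample {zero[0]!r}")
    values = table.values.div(totals, axis=0)
    return table.with_values(values, kind="relative_abundance",
                             record=("relative_abundance", {}))


def aggregate_rank(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum features sharing the lineage prefix up to *rank*.

    The aggregated table is indexed by the resolved rank name
    (``unclassified_<parent>`` for empty ranks); mass is conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    lineages = table.lineages()
    keys = {fid: lineages[fid].prefix_key(rank) for fid in table.feature_ids}
    names = {fid: keys[fid][-1] for fid in table.feature_ids}
    # disambiguate identical leaf names under different parents
    leaf_to_keys: dict[str, set] = {}
    for fid in table.feature_ids:
        leaf_to_keys.setdefault(names[fid], set()).add(keys[fid])
    columns = {}
    for fid in table.feature_ids:
        leaf = names[fid]
        label = leaf if len(leaf_to_keys[leaf]) == 1 else ";".join(keys[fid])
        columns.setdefault(label, []).append(fid)
    data = {label: table.values[fids].sum(axis=1) for label, fids in columns.items()}
    values = pd.DataFrame(data, index=table.values.index)
    kind = table.kind if table.kind in ("otu_counts", "relative_abundance") else table.kind
    return FeatureTable(values, kind, transform_record=table.transform_record + [("aggregate_rank", {"rank": rank})])


_REPLAYERS = {
    "normalize_internal_standard": lambda t, p: normalize_internal_standard(t, **p),
    "log_then_autoscale": lambda t, p: log_then_autoscale(t)[0],
    "rarefy": lambda t, p: rarefy(t, **p),
    "relative_abundance": lambda t, p: relative_abundance(t),
    "aggregate_rank": lambda t, p: aggregate_rank(t, **p),
}


def replay(raw_table: FeatureTable, record: list[tuple[str, dict]]) -> FeatureTable:
    """Re-apply a transform record to a raw table.

    Reproduces the processed table exactly (rarefaction seeds are part of
    the record).
    """
    table = raw_table
    for name, params in record:
        if name not in _REPLAYERS:
            raise ValueError(f"unknown transform {name!r}")
        params = {k: v for k, v in params.items() if k not in ("pseudo_values", "constant_columns")}
        table = _REPLAYERS[name](table, params)
    return table
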
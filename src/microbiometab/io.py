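"""Readers and writers for the on-disk table schemas.

OTU tables are TSV with samples as columns, one row per OTU and a final
``taxonomy`` column holding the semicolon-delimited lineage. Metabolite
tables are CSV with samples as rows. Metadata is a two-column TSV
(``sample_id``, ``group``). Result files carry a header comment line
declaring the config hash and seed so every output is traceable to its run.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from microbiometab.datamodel import GROUPS, CohortLabels, FeatureTable, TaxonLineage

TAXONOMY_COLUMN = "taxonomy"


def read_metadata(path) -> CohortLabels:
    """Read the sample -> group metadata TSV; unknown groups are rejected."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return CohortLabels(meta.set_index("sample_id")["group"], allowed_groups=GROUPS)


def read_otu_table(path, metadata_path) -> tuple[FeatureTable, CohortLabels]:
    """Read an OTU count TSV (taxa-major) plus group metadata.

    Returns the table oriented samples x features, with parsed
    :class:`TaxonLineage` metadata per OTU.
    """
    labels = read_metadata(metadata_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate OTU ids")
    if TAXONOMY_COLUMN not in df.columns:
        raise ValueError(f"OTU table must end with a {TAXONOMY_COLUMN!r} column")
    lineages = df[TAXONOMY_COLUMN].astype(str).map(TaxonLineage.parse)
    counts = df.drop(columns=[TAXONOMY_COLUMN])
    unlabeled = set(counts.columns) - set(labels.sample_ids)
    if unlabeled:
        raise ValueError(f"samples missing from metadata: {sorted(unlabeled)}")
    values = counts.T  # samples x features
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValueError("non-numeric OTU counts")
    meta = pd.DataFrame({"lineage": lineages})
    table = FeatureTable(numeric, "otu_counts", feature_meta=meta)
    return table, labels.subset(table.sample_ids)


def write_otu_table(table: FeatureTable, path) -> None:
    """Write an OTU table in the taxa-major TSV schema (round-trips)."""
    df = table.values.T.copy()
    df[TAXONOMY_COLUMN] = [lin.to_string() for lin in table.lineages()]
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_metabolite_table(path, metadata_path) -> tuple[FeatureTable, CohortLabels]:
    """Read a metabolite CSV (samples as rows) plus group metadata."""
    labels = read_metadata(metadata_path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(header) != len(set(header)):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate metabolite columns: {dupes}")
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    unlabeled = set(df.index) - set(labels.sample_ids)
    if unlabeled:
        raise ValueError(f"samples missing from metadata: {sorted(unlabeled)}")
    table = FeatureTable(df, "metabolite_raw")
    return table, labels.subset(table.sample_ids)


def write_metabolite_table(table: FeatureTable, path) -> None:
    df = table.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path)


def write_metadata(labels: CohortLabels, path) -> None:
    out = labels.series.rename("group").rename_axis("sample_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


def result_header(config_hash: str, seed: int) -> str:
    return f"# config_hash={config_hash} seed={seed}\n"


def write_result_tsv(df: pd.DataFrame, path, config_hash: str = "na", seed: int = 0,
                     index: bool = True) -> None:
    """Write a result table with the traceability header comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(result_header(config_hash, seed) + buf.getvalue())


def read_result_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
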
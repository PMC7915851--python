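"""Core containers: taxonomic lineages, feature tables, labels, configuration.

All matrices are oriented samples x features throughout the package; on-disk
layouts differ per format (OTU tables are taxa-major, mirroring the common
tab-separated convention) and are handled by :mod:`microbiometab.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")
GROUPS = ("ANR", "ANBP", "CTRL")

TABLE_KINDS = (
    "otu_counts",
    "relative_abundance",
    "metabolite_raw",
    "metabolite_processed",
)


@dataclass(frozen=True)
class TaxonLineage:
    """Greengenes-style six-rank lineage; lower ranks may be empty strings."""

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""

    @classmethod
    def parse(cls, lineage: str) -> "TaxonLineage":
        """Parse a semicolon-delimited lineage string.

        Accepts Greengenes rank prefixes (``k__Bacteria;p__Firmicutes;...``)
        or unprefixed names, in which case rank is inferred by position.
        """
        names = [""] * len(RANKS)
        parts = [p.strip() for p in lineage.split(";")] if lineage.strip() else []
        for i, part in enumerate(parts):
            if i >= len(RANKS):
                break
            if len(part) >= 3 and part[1:3] == "__" and part[0] in "kpcofg":
                idx = RANK_PREFIXES.index(part[:3])
                names[idx] = part[3:]
            else:
                names[i] = part
        return cls(*names)

    def to_string(self) -> str:
        """Serialise with Greengenes prefixes; round-trips through parse."""
        return ";".join(p + n for p, n in zip(RANK_PREFIXES, self.ranks()))

    def ranks(self) -> tuple[str, ...]:
        return (self.kingdom, self.phylum, self.class_, self.order, self.family, self.genus)

    def name_at(self, rank: str) -> str:
        """Name at *rank*; empty ranks fall back to ``unclassified_<parent>``."""
        idx = RANKS.index(rank)
        names = self.ranks()
        if names[idx]:
            return names[idx]
        for j in range(idx - 1, -1, -1):
            if names[j]:
                return f"unclassified_{names[j]}"
        return "unclassified"

    def prefix_key(self, rank: str) -> tuple[str, ...]:
        """Aggregation key: resolved names from kingdom down to *rank*."""
        idx = RANKS.index(rank)
        return tuple(self.name_at(r) for r in RANKS[: idx + 1])


class CohortLabels:
    """Sample -> group assignment with at least two samples per group."""

    def __init__(self, mapping: dict[str, str] | pd.Series, allowed_groups=None):
        series = pd.Series(dict(mapping) if not isinstance(mapping, pd.Series) else mapping, dtype=object)
        if series.index.has_duplicates:
            raise ValueError("duplicate sample ids in labels")
        if allowed_groups is not None:
            unknown = set(series) - set(allowed_groups)
            if unknown:
                raise ValueError(f"unknown group labels: {sorted(unknown)}")
        counts = series.value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ValueError(f"groups with fewer than 2 samples: {list(small.index)}")
        self._series = series

    @property
    def series(self) -> pd.Series:
        return self._series.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._series.index)

    @property
    def groups(self) -> list[str]:
        """Group names, in the canonical order where applicable."""
        present = list(pd.unique(self._series))
        canon = [g for g in GROUPS if g in present]
        return canon + sorted(set(present) - set(canon))

    def __getitem__(self, sample_id: str) -> str:
        return self._series[sample_id]

    def __len__(self) -> int:
        return len(self._series)

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortLabels) and self._series.equals(other._series)

    def subset(self, sample_ids) -> "CohortLabels":
        return CohortLabels(self._series.loc[list(sample_ids)])

    def group_members(self, group: str) -> list[str]:
        return list(self._series.index[self._series == group])

    def as_array(self, sample_ids=None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return self._series.loc[ids].to_numpy()


class FeatureTable:
    """Samples x features numeric matrix with per-feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are feature ids.
    kind
        One of ``otu_counts``, ``relative_abundance``, ``metabolite_raw``,
        ``metabolite_processed``. Invariants are validated per kind.
    feature_meta
        Optional DataFrame indexed by feature id. OTU tables carry a
        ``lineage`` column of :class:`TaxonLineage`; metabolite tables may
        carry an ``hmdb`` column.
    transform_record
        Ordered list of ``(transform_name, params)`` applied so far.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        kind: str,
        feature_meta: pd.DataFrame | None = None,
        transform_record: list[tuple[str, dict]] | None = None,
    ):
        if kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {kind!r}")
        if values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if values.isna().any().any():
            sample = values.index[values.isna().any(axis=1)][0]
            feat = values.columns[values.isna().any(axis=0)][0]
            raise ValueError(f"missing value at sample {sample!r}, feature {feat!r}")
        arr = values.to_numpy()
        if kind == "otu_counts":
            if (arr < 0).any():
                raise ValueError("otu counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("otu counts must be integers")
            values = values.astype(np.int64)
        elif kind == "relative_abundance":
            if (arr < 0).any():
                raise ValueError("relative abundances must be non-negative")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("relative abundance rows must sum to 1")
        elif kind == "metabolite_raw":
            if (arr < 0).any():
                raise ValueError("negative peak areas")
        if feature_meta is not None:
            missing = set(values.columns) - set(feature_meta.index)
            if missing:
                raise ValueError(f"feature_meta missing features: {sorted(missing)[:5]}")
            feature_meta = feature_meta.loc[list(values.columns)]
        self.values = values
        self.kind = kind
        self.feature_meta = feature_meta
        self.transform_record = list(transform_record or [])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def lineages(self) -> pd.Series:
        if self.feature_meta is None or "lineage" not in self.feature_meta:
            raise ValueError("table has no lineage metadata")
        return self.feature_meta["lineage"]

    def with_values(self, values: pd.DataFrame, kind: str | None = None,
                    record: tuple[str, dict] | None = None) -> "FeatureTable":
        meta = None
        if self.feature_meta is not None:
            keep = [f for f in values.columns if f in self.feature_meta.index]
            if len(keep) == len(values.columns):
                meta = self.feature_meta.loc[keep]
        rec = self.transform_record + ([record] if record else [])
        return FeatureTable(values, kind or self.kind, meta, rec)

    def check_aligned(self, labels: CohortLabels) -> None:
        unlabeled = set(self.sample_ids) - set(labels.sample_ids)
        if unlabeled:
            raise ValueError(f"samples without group label: {sorted(unlabeled)[:5]}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureTable)
            and self.kind == other.kind
            and self.values.equals(other.values)
        )


@dataclass
class AnalysisConfig:
    """Thresholds and scheme parameters shared across pipeline stages."""

    vip_threshold: float = 1.5
    anova_alpha: float = 0.05
    lefse_screen_alpha: float = 0.05
    lefse_display_alpha: float = 0.01
    lda_threshold: float = 2.0
    correlation_alpha: float = 0.05
    n_permutations: int = 1000
    permanova_permutations: int = 999
    cv_folds: int = 5
    cv_repeats: int = 10
    max_components: int = 10
    ga_population: int = 50
    ga_generations: int = 100
    ga_crossover_rate: float = 0.8
    ga_mutation_rate: float | None = None  # None -> 1/p
    ga_elitism: int = 2
    ga_tournament: int = 3
    metacost_models: int = 30
    metacost_fraction: float = 0.67
    nmds_starts: int = 20
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-7
    correlation_rank: str = "family"
    seed: int = 0

    def __post_init__(self):
        for name in ("anova_alpha", "lefse_screen_alpha", "lefse_display_alpha", "correlation_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.permanova_permutations < 1:
            raise ValueError("permanova_permutations must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        import hashlib, json

        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
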
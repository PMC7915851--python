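"""Synthetic three-group cohort generator with planted, recoverable effects.

Emulates the statistical structure the analysis stages assume: a 17/6/20
(ANR/ANBP/CTRL) cohort with Dirichlet-multinomial 16S OTU counts and
log-normal GC-MS-like metabolite peak areas carrying a per-sample
internal-standard injection factor. Group effects are planted
multiplicatively — on baseline proportions for taxa, on median peak areas
for metabolites — and recorded in a :class:`GroundTruth` object so recovery
tests can score every selection stage against what was actually planted.

The generator does not attempt chromatograms, reads, retention-time drift,
or missingness (optional left-censoring aside); it reproduces the
moment structure (composition, overdispersion, sample-depth inhomogeneity,
injection variability) that the diversity, differential-abundance, PLS-DA
and correlation stages are sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microbiometab.datamodel import CohortLabels, FeatureTable, TaxonLineage

INTERNAL_STANDARD = "internal_standard"

# Deterministic taxonomy scaffold: (phylum, class, order, family, genus)
# templates cycled over when naming simulated OTUs. Includes the taxa the
# downstream comparisons single out (Bifidobacterium, Odoribacter,
# Haemophilus, Bacteroidetes/Firmicutes members, Verrucomicrobia).
_TAXONOMY_TEMPLATES = [
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Eubacteriaceae", "Eubacterium"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", "Dialister"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae", "Odoribacter"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes"),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella"),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Escherichia"),
    ("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae", "Bilophila"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", "Akkermansia"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
]

# Default planted taxa: direction structure of the reported
# ANBP-vs-ANR differential taxa (Bifidobacterium lineage up in ANBP,
# Odoribacter / Haemophilus lineages down in ANBP) plus a modest global
# richness depression in both patient groups handled via planted negatives.
_DEFAULT_PLANTED_TAXA = [
    ("taxon_0010", {"ANBP": 2.5}),   # Bifidobacterium template slot
    ("taxon_0007", {"ANBP": -2.5}),  # Odoribacter slot
    ("taxon_0012", {"ANBP": -2.5}),  # Haemophilus slot
    ("taxon_0003", {"ANBP": -2.0}),  # Eubacteriaceae slot
    ("taxon_0015", {"ANR": 2.0}),    # Akkermansia slot (Verrucomicrobia up in ANR)
    ("taxon_0026", {"ANR": -2.0, "ANBP": -2.0}),
    ("taxon_0042", {"ANR": 2.0}),
    ("taxon_0058", {"ANR": -2.0, "ANBP": -2.5}),
]

# Default planted metabolites: the arrow-pattern mix of the published
# selection table — roughly 2/5 opposite directions in the two AN
# subtypes, the rest decreased in both with one subtype lower — at effect
# sizes the selection stages are specified to recover (|log2FC| >= 1.5).
# The many opposite-direction pairs are what make the two AN subtypes
# separable from each other, not just from controls.
_DEFAULT_PLANTED_METABOLITES = [
    ("met_0001", {"ANR": -1.5, "ANBP": -2.5}),  # rhamnose-like: down / down-down
    ("met_0002", {"ANR": -1.5, "ANBP": -2.5}),  # xylose-like
    ("met_0003", {"ANR": -2.5, "ANBP": -1.5}),  # tagatose-like: down-down / down
    ("met_0004", {"ANR": -2.5, "ANBP": -1.5}),  # sorbose-like
    ("met_0005", {"ANR": -1.5, "ANBP": 1.5}),   # glycerol-like: opposite signs
    ("met_0006", {"ANR": -1.5, "ANBP": 1.5}),   # succinate-like
    ("met_0007", {"ANR": -1.5, "ANBP": -2.5}),  # isoleucine-like
    ("met_0008", {"ANR": -1.5, "ANBP": -2.5}),  # valine-like
    ("met_0009", {"ANR": 1.5, "ANBP": 1.5}),
    ("met_0010", {"ANR": -2.0, "ANBP": -2.0}),
    ("met_0011", {"ANR": -1.5, "ANBP": 1.5}),   # threonine-like
    ("met_0012", {"ANR": -1.5, "ANBP": 1.5}),   # lactose-like
    ("met_0013", {"ANR": -1.5, "ANBP": 1.5}),   # acetic-acid-like
    ("met_0014", {"ANR": -1.5, "ANBP": 1.5}),   # sebacic-acid-like
    ("met_0015", {"ANR": -2.0, "ANBP": 2.0}),   # homogentisic-like
    ("met_0016", {"ANR": -2.0, "ANBP": 2.0}),   # scyllo-inositol-like
    ("met_0017", {"ANR": -1.5, "ANBP": -2.5}),  # deoxycytidine-like
    ("met_0018", {"ANR": -2.0, "ANBP": -3.0}),  # arabinose-like
    ("met_0019", {"ANR": -2.5, "ANBP": -1.5}),  # palmitic-like
    ("met_0020", {"ANR": -1.5, "ANBP": -1.5}),  # GABA-like: down / down
]


@dataclass
class SimulationParams:
    """Cohort-level generative parameters; defaults mirror the study design."""

    group_sizes: dict = field(default_factory=lambda: {"ANR": 17, "ANBP": 6, "CTRL": 20})
    n_taxa: int = 150
    n_metabolites: int = 224
    sigma_base: float = 1.5          # log-sd of baseline taxon proportions
    theta: float = 200.0             # Dirichlet concentration (overdispersion)
    depth_range: tuple = (5000, 15000)
    planted_taxa: list = field(default_factory=lambda: list(_DEFAULT_PLANTED_TAXA))
    planted_metabolites: list = field(default_factory=lambda: list(_DEFAULT_PLANTED_METABOLITES))
    planted_base_proportion: float = 0.02  # baseline abundance given to planted taxa
    metabolite_sigma: float = 0.4    # log-normal noise sd (natural log scale)
    is_mean: float = 1.0e5           # internal-standard mean peak area
    is_cv: float = 0.25              # per-sample injection variability
    censor_quantile: float = 0.0     # optional left-censoring of peak areas
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least 2 samples")
        if self.depth_range[0] < 1:
            raise ValueError("sequencing depth must be >= 1")
        for _, fcs in list(self.planted_taxa) + list(self.planted_metabolites):
            if not all(np.isfinite(list(fcs.values()))):
                raise ValueError("planted fold changes must be finite")


@dataclass
class GroundTruth:
    """Planted feature ids with signed per-group log2 fold changes."""

    taxa: dict
    metabolites: dict

    def planted_taxon_ids(self, min_abs_lfc: float = 0.0) -> list[str]:
        return [t for t, fcs in self.taxa.items()
                if any(abs(v) >= min_abs_lfc for v in fcs.values())]

    def planted_metabolite_ids(self, min_abs_lfc: float = 0.0) -> list[str]:
        return [m for m, fcs in self.metabolites.items()
                if any(abs(v) >= min_abs_lfc for v in fcs.values())]


def _taxon_ids(n: int) -> list[str]:
    return [f"taxon_{i + 1:04d}" for i in range(n)]


def _metabolite_ids(n: int) -> list[str]:
    return [f"met_{i + 1:04d}" for i in range(n)]


def _build_lineages(n: int) -> pd.Series:
    lineages = []
    for i in range(n):
        phylum, cls, order, family, genus = _TAXONOMY_TEMPLATES[i % len(_TAXONOMY_TEMPLATES)]
        copy = i // len(_TAXONOMY_TEMPLATES)
        genus_name = genus if copy == 0 else f"{genus}_{copy}"
        lineages.append(TaxonLineage("Bacteria", phylum, cls, order, family, genus_name))
    return pd.Series(lineages, index=_taxon_ids(n))


def simulate_cohort(params: SimulationParams | None = None):
    """Draw one cohort.

    Returns ``(otu_table, metabolite_table, labels, ground_truth)``.

    OTU counts: per sample in group g, p ~ Dirichlet(theta * pi_g) and
    counts ~ Multinomial(depth, p), where pi_g is the log-normal baseline
    composition with the group's planted log2 fold changes applied and
    renormalised. Metabolites: peak area = mu_m * 2^lfc_g * exp(sigma * Z)
    scaled by the sample's internal-standard injection factor; the
    internal-standard column itself carries only the injection factor, so
    dividing by it recovers the biology.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)

    groups, sizes = zip(*sorted(params.group_sizes.items()))
    sample_ids, label_map = [], {}
    for g, n in zip(groups, sizes):
        for i in range(n):
            sid = f"{g}_{i + 1:02d}"
            sample_ids.append(sid)
            label_map[sid] = g
    labels = CohortLabels(label_map)

    taxon_ids = _taxon_ids(params.n_taxa)
    base = rng.lognormal(mean=0.0, sigma=params.sigma_base, size=params.n_taxa)
    base /= base.sum()

    planted_taxa = {t: dict(fcs) for t, fcs in params.planted_taxa if t in taxon_ids}
    if planted_taxa and params.planted_base_proportion > 0:
        # pin planted taxa at a moderate baseline abundance: the taxa the
        # differential stage is meant to flag are community members in the
        # percent range, not rare dust at the detection limit
        pb = params.planted_base_proportion
        idx = [taxon_ids.index(t) for t in planted_taxa]
        if len(idx) * pb < 1.0:
            others = np.setdiff1d(np.arange(params.n_taxa), idx)
            base[others] *= (1.0 - len(idx) * pb) / base[others].sum()
            base[idx] = pb
    group_props = {}
    for g in groups:
        pi = base.copy()
        for t, fcs in planted_taxa.items():
            if g in fcs:
                pi[taxon_ids.index(t)] *= 2.0 ** fcs[g]
        group_props[g] = pi / pi.sum()

    depths = rng.integers(params.depth_range[0], params.depth_range[1] + 1, size=len(sample_ids))
    counts = np.empty((len(sample_ids), params.n_taxa), dtype=np.int64)
    for i, sid in enumerate(sample_ids):
        p = rng.dirichlet(params.theta * group_props[label_map[sid]])
        counts[i] = rng.multinomial(depths[i], p)
    otu_values = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    otu_meta = pd.DataFrame({"lineage": _build_lineages(params.n_taxa)})
    otu_table = FeatureTable(otu_values, "otu_counts", feature_meta=otu_meta)

    met_ids = _metabolite_ids(params.n_metabolites)
    planted_mets = {m: dict(fcs) for m, fcs in params.planted_metabolites if m in met_ids}
    mu = rng.lognormal(mean=12.0, sigma=1.5, size=params.n_metabolites)
    is_sigma = np.sqrt(np.log1p(params.is_cv ** 2))
    is_factor = rng.lognormal(mean=-0.5 * is_sigma ** 2, sigma=is_sigma, size=len(sample_ids))

    areas = np.empty((len(sample_ids), params.n_metabolites))
    for i, sid in enumerate(sample_ids):
        g = label_map[sid]
        mean_i = mu.copy()
        for m, fcs in planted_mets.items():
            if g in fcs:
                mean_i[met_ids.index(m)] *= 2.0 ** fcs[g]
        noise = rng.lognormal(mean=0.0, sigma=params.metabolite_sigma, size=params.n_metabolites)
        areas[i] = mean_i * noise * is_factor[i]
    if params.censor_quantile > 0:
        lod = np.quantile(areas, params.censor_quantile, axis=0)
        areas = np.where(areas < lod, 0.0, areas)

    met_values = pd.DataFrame(areas, index=sample_ids, columns=met_ids)
    met_values[INTERNAL_STANDARD] = params.is_mean * is_factor
    met_meta = pd.DataFrame(
        {"hmdb": [f"HMDB{9000000 + i + 1:07d}" for i in range(params.n_metabolites)] + [""]},
        index=met_ids + [INTERNAL_STANDARD],
    )
    met_table = FeatureTable(met_values, "metabolite_raw", feature_meta=met_meta)

    truth = GroundTruth(taxa=planted_taxa, metabolites=planted_mets)
    return otu_table, met_table, labels, truth


def fixture_small():
    """Deterministic tiny cohort (3/3/4 samples, 12 taxa, 15 metabolites).

    Contains exactly 2 planted taxa and 3 planted metabolites; used
    throughout the test suite wherever full-scale simulation is overkill.
    """
    params = SimulationParams(
        group_sizes={"ANR": 3, "ANBP": 3, "CTRL": 4},
        n_taxa=12,
        n_metabolites=15,
        depth_range=(800, 1200),
        planted_taxa=[
            ("taxon_0005", {"ANBP": 3.0}),
            ("taxon_0002", {"ANR": -3.0, "ANBP": -3.0}),
        ],
        planted_metabolites=[
            ("met_0001", {"ANR": -2.0, "ANBP": -3.0}),
            ("met_0002", {"ANR": 2.0, "ANBP": 2.0}),
            ("met_0003", {"ANR": -2.0, "ANBP": 2.0}),
        ],
        seed=20210204,
    )
    return simulate_cohort(params)
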
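"""MetPa-style pathway analysis: hypergeometric over-representation plus
topology impact via relative betweenness centrality.

For each pathway, over-representation of the selected metabolites is
scored by the exact hypergeometric upper tail P(X >= k) with background N
fixed to the measured, library-mappable metabolome. Topological impact is
the fraction of the pathway's total relative betweenness centrality
carried by the hit compounds; pathway graphs are directed, and centrality
is normalised by (N-1)(N-2) over ordered node pairs. A small built-in toy
library (HMDB-coded directed graphs, including a branched-chain
amino-acid pathway) supports tests and examples; real libraries load from
an edge-list + membership TSV pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PathwayGraph:
    """Directed compound graph with a (possibly larger) membership set."""

    pathway_id: str
    name: str
    graph: nx.DiGraph
    membership: set = field(default_factory=set)

    def __post_init__(self):
        self.membership = set(self.membership) | set(self.graph.nodes)


def hypergeom_enrich(selected: set, pathway: PathwayGraph, background: set) -> tuple[int, float]:
    """Exact hypergeometric upper-tail p for pathway over-representation.

    Background N = measured metabolites mappable to the library; only the
    pathway members inside the background count toward M, and only
    selected metabolites inside the background toward n.
    """
    background = set(background)
    members = pathway.membership & background
    sel = set(selected) & background
    n_draw, m_size, n_bg = len(sel), len(members), len(background)
    k = len(sel & members)
    assert k <= min(m_size, n_draw)
    if k == 0:
        return 0, 1.0
    p = float(stats.hypergeom.sf(k - 1, n_bg, m_size, n_draw))
    return k, min(p, 1.0)


def relative_betweenness(graph: nx.DiGraph) -> dict:
    """Betweenness centrality normalised by (N-1)(N-2) ordered pairs."""
    n = graph.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=True)


def pathway_impact(pathway: PathwayGraph, hits: set) -> tuple[float, bool]:
    """Fraction of total pathway centrality carried by the hit compounds.

    Returns ``(impact, degenerate)``; degenerate marks pathways whose
    total centrality is zero (edgeless or too small), scored 0.
    """
    hits = set(hits) & pathway.membership
    bc = relative_betweenness(pathway.graph)
    total = sum(bc.values())
    if total == 0:
        return 0.0, True
    return sum(bc.get(v, 0.0) for v in hits) / total, False


def analyze_pathways(selected: set, library: list[PathwayGraph],
                     background: set | None = None) -> pd.DataFrame:
    """Per-pathway enrichment p and topology impact, sorted by p.

    When *background* is omitted it defaults to the union of library
    memberships (every mappable compound); metabolites outside it are
    logged into the ``unmapped`` attribute of no pathway — they simply do
    not contribute.
    """
    if background is None:
        background = set().union(*(pw.membership for pw in library)) if library else set()
    rows = []
    for pw in library:
        members = pw.membership & background
        k, p = hypergeom_enrich(selected, pw, background)
        impact, degenerate = pathway_impact(pw, set(selected) & background)
        rows.append({"pathway_id": pw.pathway_id, "name": pw.name,
                     "hits": k, "pathway_size": len(members),
                     "background": len(background),
                     "selected": len(set(selected) & background),
                     "p": p, "neg_log10_p": -np.log10(max(p, 1e-300)),
                     "impact": impact, "degenerate_topology": degenerate})
    return (pd.DataFrame(rows)
            .sort_values(["p", "pathway_id"], kind="stable")
            .reset_index(drop=True))


def load_library(edges_path, membership_path) -> list[PathwayGraph]:
    """Load a pathway library from edge-list and membership TSVs.

    Edge TSV columns: pathway_id, source, target. Membership TSV columns:
    pathway_id, compound, plus an optional ``name`` column naming the
    pathway.
    """
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    members = pd.read_csv(membership_path, sep="\t", dtype=str)
    library = []
    for pid in members["pathway_id"].unique():
        g = nx.DiGraph()
        sub = edges[edges["pathway_id"] == pid]
        g.add_edges_from(zip(sub["source"], sub["target"]))
        mem = set(members.loc[members["pathway_id"] == pid, "compound"])
        name = pid
        if "name" in members.columns:
            names = members.loc[members["pathway_id"] == pid, "name"].dropna()
            if len(names):
                name = names.iloc[0]
        library.append(PathwayGraph(pid, name, g, mem))
    return library


def save_library(library: list[PathwayGraph], edges_path, membership_path) -> None:
    edge_rows, member_rows = [], []
    for pw in library:
        for s, t in pw.graph.edges:
            edge_rows.append({"pathway_id": pw.pathway_id, "source": s, "target": t})
        for c in sorted(pw.membership):
            member_rows.append({"pathway_id": pw.pathway_id, "compound": c, "name": pw.name})
    pd.DataFrame(edge_rows).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame(member_rows).to_csv(membership_path, sep="\t", index=False)


def _chain(pid: str, name: str, codes: list[str], extra_edges=()) -> PathwayGraph:
    g = nx.DiGraph()
    g.add_edges_from(zip(codes[:-1], codes[1:]))
    g.add_edges_from(extra_edges)
    return PathwayGraph(pid, name, g)


def toy_library() -> list[PathwayGraph]:
    """Built-in toy pathway library (synthetic HMDB-coded directed graphs).

    Five small pathways, including a branched-chain amino-acid pathway
    with a branch point, used for tests and worked examples. The codes are
    synthetic stand-ins in the simulated-metabolome namespace, not curated
    database content.
    """
    m = lambda i: f"HMDB{9000000 + i:07d}"
    bcaa = _chain("toy_bcaa", "branched-chain amino acid biosynthesis (toy)",
                  [m(20), m(7), m(8)], extra_edges=[(m(20), m(11)), (m(11), m(12))])
    sugars = _chain("toy_pentose", "pentose interconversions (toy)",
                    [m(1), m(2), m(13), m(14)])
    tca = _chain("toy_tca", "citrate cycle (toy)",
                 [m(6), m(15), m(16), m(17), m(6)])
    tyr = _chain("toy_tyrosine", "tyrosine metabolism (toy)",
                 [m(18), m(9), m(19)])
    lipid = _chain("toy_glycerolipid", "glycerolipid metabolism (toy)",
                   [m(5), m(21), m(22)])
    return [bcaa, sugars, tca, tyr, lipid]
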
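"""Term-overlap networks linking biological processes to TF targets.

Enriched biological-process (BP) terms and TF-target (TFT) terms are
joined into one network whose edges mark statistically surprising
sharing of enriched genes: for each term pair the upper-tail
hypergeometric p of their enriched-gene overlap is computed against
the enrichment universe and an edge is kept when p falls below a
stringent threshold (1e-8 by default).  Edge communities are then
found with the link-community procedure: edges sharing a node are
scored by the Jaccard similarity of the inclusive neighborhoods of
their non-shared endpoints, single-linkage clustered, and the
dendrogram is cut at the height maximizing the partition density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

EdgeKey = tuple[str, str]


def _edge_key(a: str, b: str) -> EdgeKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class TermNetwork:
    graph: nx.Graph
    universe_size: int
    p_threshold: float
    communities: dict[EdgeKey, int] = field(default_factory=dict)
    partition_density: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            key = _edge_key(u, v)
            rows.append(
                {
                    "term_a": key[0],
                    "term_b": key[1],
                    "overlap": d["overlap"],
                    "p": d["p"],
                    "weight": d["weight"],
                    "shared_genes": ",".join(d["shared_genes"]),
                    "community": self.communities.get(key, -1),
                }
            )
        return pd.DataFrame(rows)


def build_overlap_network(
    bp_results: pd.DataFrame,
    tft_results: pd.DataFrame,
    universe_size: int,
    p_threshold: float = 1e-8,
) -> TermNetwork:
    """Hypergeometric term-overlap network over enriched BP/TFT terms.

    Both inputs are over-representation tables carrying an
    ``enriched_genes`` column (the query-intersected members used for
    enrichment).  Every term pair — BP-BP, BP-TFT and TFT-TFT — is
    tested; edges are kept when the overlap p-value is below
    ``p_threshold`` and weighted by -log10 p.
    """
    members: dict[str, tuple[set[str], str]] = {}
    for table, fallback in ((bp_results, "BP"), (tft_results, "TFT")):
        if table is None or len(table) == 0:
            continue
        for term, row in table.iterrows():
            genes = set(row["enriched_genes"])
            if not genes:
                logger.warning("term %s has no enriched genes; excluded", term)
                continue
            if term in members:
                raise ValueError(f"duplicate term name across inputs: {term!r}")
            members[term] = (genes, row.get("type", fallback) or fallback)

    g = nx.Graph()
    for term, (genes, ttype) in sorted(members.items()):
        g.add_node(term, type=ttype, size=len(genes))

    terms = sorted(members)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            ga, gb = members[a][0], members[b][0]
            shared = sorted(ga & gb)
            p = float(
                stats.hypergeom.sf(len(shared) - 1, universe_size, len(ga), len(gb))
            )
            p = min(p, 1.0)
            if p < p_threshold:
                weight = -np.log10(max(p, 1e-320))
                g.add_edge(
                    a, b, overlap=len(shared), p=p, weight=float(weight),
                    shared_genes=tuple(shared),
                )
    return TermNetwork(graph=g, universe_size=universe_size, p_threshold=p_threshold)


def partition_density(
    graph: nx.Graph, communities: dict[EdgeKey, int]
) -> float:
    """Average link density over edge communities.

    D = (2/M) * sum_c m_c * (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1));
    communities spanning only two nodes contribute zero.
    """
    m_total = graph.number_of_edges()
    if m_total == 0:
        raise ValueError("edgeless network")
    groups: dict[int, list[EdgeKey]] = {}
    for key, cid in communities.items():
        groups.setdefault(cid, []).append(key)
    total = 0.0
    for edges in groups.values():
        m_c = len(edges)
        nodes = {n for e in edges for n in e}
        n_c = len(nodes)
        if n_c > 2:
            total += m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / m_total


def link_communities(network: TermNetwork) -> tuple[dict[EdgeKey, int], float]:
    """Ahn-style link communities by single-linkage edge clustering.

    Similarity is defined for edge pairs sharing a node k as the
    Jaccard index of the inclusive neighborhoods (node plus its
    neighbors) of the two non-shared endpoints; non-adjacent edges
    have similarity zero.  The dendrogram is swept over all merge
    heights and cut where the partition density peaks (ties resolve
    to the finest partition).  Results are stored on the network and
    returned.
    """
    g = network.graph
    edges = sorted(_edge_key(u, v) for u, v in g.edges())
    m = len(edges)
    if m == 0:
        raise ValueError("edgeless network")
    if m == 1:
        communities = {edges[0]: 1}
        network.communities = communities
        network.partition_density = 0.0
        return communities, 0.0

    neigh = {n: set(g.neighbors(n)) | {n} for n in g.nodes()}
    dist = np.ones((m, m))
    np.fill_diagonal(dist, 0.0)
    index = {e: i for i, e in enumerate(edges)}
    for node in sorted(g.nodes()):
        incident = sorted(_edge_key(node, other) for other in g.neighbors(node))
        for i, e1 in enumerate(incident):
            for e2 in incident[i + 1 :]:
                a = e1[0] if e1[1] == node else e1[1]
                b = e2[0] if e2[1] == node else e2[1]
                na, nb = neigh[a], neigh[b]
                jac = len(na & nb) / len(na | nb)
                d = 1.0 - jac
                ia, ib = index[e1], index[e2]
                if d < dist[ia, ib]:
                    dist[ia, ib] = dist[ib, ia] = d

    z = linkage(squareform(dist, checks=False), method="single")
    heights = sorted(set(np.round(z[:, 2], 12)) | {0.0})
    best_labels = None
    best_d = -np.inf
    for h in heights:
        labels = fcluster(z, t=h, criterion="distance")
        comms = {e: int(l) for e, l in zip(edges, labels)}
        d = partition_density(g, comms)
        if d > best_d + 1e-12:
            best_d = d
            best_labels = comms
    network.communities = best_labels
    network.partition_density = float(best_d)
    return best_labels, float(best_d)


def export_network(
    network: TermNetwork, path: str | Path, fmt: str = "graphml"
) -> None:
    """Write the network as GraphML or an edge TSV."""
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for n, d in network.graph.nodes(data=True):
            g.add_node(n, type=d.get("type", ""), size=int(d.get("size", 0)))
        for u, v, d in network.graph.edges(data=True):
            key = _edge_key(u, v)
            attrs = {
                "overlap": int(d["overlap"]),
                "p": float(d["p"]),
                "weight": float(d["weight"]),
                "shared_genes": ",".join(d["shared_genes"]),
            }
            if network.communities:
                attrs["community"] = int(network.communities.get(key, -1))
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        network.edge_table().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graphml(path: str | Path) -> TermNetwork:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes()})
    for u, v, d in g.edges(data=True):
        if isinstance(d.get("shared_genes"), str):
            d["shared_genes"] = tuple(s for s in d["shared_genes"].split(",") if s)
    communities = {}
    for u, v, d in g.edges(data=True):
        if "community" in d:
            communities[_edge_key(u, v)] = int(d["community"])
    return TermNetwork(
        graph=g, universe_size=0, p_threshold=1.0, communities=communities
    )
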
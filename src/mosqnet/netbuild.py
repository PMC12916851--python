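"""Co-occurrence network construction and topology metrics.

Networks are undirected signed weighted graphs over taxa: an edge carries the
correlation estimate ``r`` (its sign is an attribute, not a filter) and the
absolute value ``absweight`` used wherever a non-negative weight is needed
(Louvain modularity, eigenvector centrality, weighted degree).  Only taxa
with at least one incident edge are nodes ("connected nodes").
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Graph from a signed edge list (columns taxon_a, taxon_b, r, sign).

    Isolated taxa are not represented; an empty edge list yields an empty
    graph.  Each unordered pair may appear at most once.
    """
    g = nx.Graph()
    seen = set()
    for row in edges.itertuples(index=False):
        a, b = str(row.taxon_a), str(row.taxon_b)
        if a == b:
            raise ValueError(f"self-loop on {a}")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate edge {a}--{b}")
        seen.add(key)
        r = float(row.r)
        g.add_edge(a, b, r=r, sign=int(np.sign(r)) or 1, absweight=abs(r))
    return g


@dataclass
class TopologySummary:
    """The standard topology metric bundle for one network.

    ``average_degree`` is 2E/N; ``weighted_degree`` the mean over nodes of the
    summed |r| of incident edges; ``clustering_coefficient`` the unweighted
    mean local clustering coefficient (degree < 2 contributes 0); ``diameter``
    the longest shortest path within the largest connected component;
    modularity and module count from seeded Louvain on |r| weights.
    """

    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    pct_positive: float
    pct_negative: float
    modularity: float
    diameter: int
    average_degree: float
    weighted_degree: float
    clustering_coefficient: float
    n_modules: int
    global_transitivity: float = float("nan")

    def as_row(self) -> dict:
        """Reporting conventions: percentages to 1 decimal, degrees to 3."""
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "pct_positive": round(self.pct_positive, 1),
            "pct_negative": round(self.pct_negative, 1),
            "modularity": round(self.modularity, 3),
            "diameter": self.diameter,
            "average_degree": round(self.average_degree, 3),
            "weighted_degree": round(self.weighted_degree, 3),
            "clustering_coefficient": round(self.clustering_coefficient, 3),
            "n_modules": self.n_modules,
        }


def _empty_summary() -> TopologySummary:
    nan = float("nan")
    return TopologySummary(0, 0, 0, 0, nan, nan, nan, 0, nan, nan, nan, 0, nan)


def topology_summary(net: nx.Graph, seed: int = 0,
                     resolution: float = 1.0) -> TopologySummary:
    """Compute the topology metric bundle; empty network -> all-missing."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        return _empty_summary()
    signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = e - n_pos
    comms = nx.community.louvain_communities(
        net, weight="absweight", seed=seed, resolution=resolution)
    modularity = (nx.community.modularity(net, comms, weight="absweight")
                  if e else 0.0)
    lcc = max(nx.connected_components(net), key=len)
    diameter = (nx.diameter(net.subgraph(lcc)) if len(lcc) > 1 else 0)
    wdeg = np.mean([sum(d["absweight"] for _, _, d in net.edges(v, data=True))
                    for v in net.nodes])
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        n_positive=n_pos,
        n_negative=n_neg,
        pct_positive=100.0 * n_pos / e if e else float("nan"),
        pct_negative=100.0 * n_neg / e if e else float("nan"),
        modularity=float(modularity),
        diameter=int(diameter),
        average_degree=2.0 * e / n,
        weighted_degree=float(wdeg),
        clustering_coefficient=float(np.mean(
            list(nx.clustering(net).values()))),
        n_modules=len(comms),
        global_transitivity=float(nx.transitivity(net)),
    )


def centralities(net: nx.Graph, eig_tol: float = 1e-8) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness and eigenvector centrality.

    Betweenness and closeness are unweighted; betweenness is normalized;
    closeness uses the plain per-component convention (no Wasserman-Faust
    cross-component scaling).  Eigenvector centrality uses |r| weights with
    power iteration to ``eig_tol``.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=True)
    clo = nx.closeness_centrality(net, wf_improved=False)
    try:
        eig = nx.eigenvector_centrality(net, weight="absweight",
                                        max_iter=5000, tol=eig_tol)
    except nx.PowerIterationFailedConvergence:
        eig = nx.eigenvector_centrality_numpy(net, weight="absweight")
    df = pd.DataFrame({
        "degree": pd.Series(deg, dtype=float),
        "betweenness": pd.Series(btw),
        "closeness": pd.Series(clo),
        "eigenvector": pd.Series(eig),
    })
    df.index.name = "taxon_id"
    return df.sort_index()


@dataclass
class EgoSubnetwork:
    graph: nx.Graph
    focal_taxon: str
    absent: bool


def ego_subnetwork(net: nx.Graph, focal_taxon: str,
                   radius: int = 1) -> EgoSubnetwork:
    """Induced subgraph on the focal taxon's closed neighborhood.

    If the focal taxon has no edges (e.g. a dominant, low-variance genus that
    never enters the inferred network) an empty subnetwork with the ``absent``
    flag set is returned.
    """
    if focal_taxon not in net:
        return EgoSubnetwork(nx.Graph(), focal_taxon, absent=True)
    sub = nx.ego_graph(net, focal_taxon, radius=radius)
    return EgoSubnetwork(nx.Graph(sub), focal_taxon, absent=False)


def annotate_network(net: nx.Graph, seed: int = 0) -> nx.Graph:
    """Attach module assignment and centralities as node attributes."""
    if net.number_of_nodes() == 0:
        return net
    comms = nx.community.louvain_communities(net, weight="absweight",
                                             seed=seed)
    for k, comm in enumerate(comms):
        for v in comm:
            net.nodes[v]["module"] = k
    cent = centralities(net)
    for col in cent.columns:
        for v, val in cent[col].items():
            net.nodes[v][col] = float(val)
    return net


def export_graphml(net: nx.Graph, path, drop_negative: bool = False) -> None:
    """GraphML export (Gephi-compatible); optionally positive edges only."""
    g = net
    if drop_negative:
        g = nx.Graph(((u, v, d) for u, v, d in net.edges(data=True)
                      if d.get("sign", 1) > 0))
    nx.write_graphml(g, path)


def export_gexf(net: nx.Graph, path) -> None:
    nx.write_gexf(net, path)
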
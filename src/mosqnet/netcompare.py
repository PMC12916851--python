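"""Cross-network comparison: Jaccard indices of most-central node sets with an
exact hypergeometric null, multi-criterion hub identification and differential
edge partitions.

The "most central" set for a measure contains the nodes strictly above the
empirical 75th percentile of that measure (linear-interpolation quantile; ties
at the threshold are excluded).  Under the null both sets are drawn uniformly
without replacement from the shared name universe with their observed sizes,
so the overlap is hypergeometric and P(J <= j) / P(J >= j) are exact tail
sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .netbuild import centralities

HUB_MEASURES = ("degree", "betweenness", "eigenvector")


def top_central_set(values: pd.Series, percentile: float = 75.0) -> set[str]:
    """Nodes with centrality strictly above the empirical percentile."""
    if len(values) == 0:
        raise ValueError("empty centrality vector")
    cut = float(np.percentile(values.to_numpy(float), percentile))
    return set(values.index[values > cut])


@dataclass
class JaccardEntry:
    measure: str
    jaccard: float
    p_le: float
    p_ge: float
    size_a: int
    size_b: int
    overlap: int


def jaccard_with_null(set_a, set_b, universe) -> JaccardEntry:
    """Jaccard index of two node-name sets with exact two-tailed null p's.

    ``universe`` is the common name universe (typically the union of both
    networks' node sets).  p_le = P(J <= j) and p_ge = P(J >= j) under the
    hypergeometric overlap null, both including the observed value.
    """
    a, b = set(set_a), set(set_b)
    u = set(universe) | a | b
    n = len(u)
    if len(a | b) == 0:
        return JaccardEntry("", float("nan"), float("nan"), float("nan"),
                            0, 0, 0)
    k_obs = len(a & b)
    j_obs = k_obs / len(a | b)
    rv = hypergeom(n, len(a), len(b))
    ks = np.arange(max(0, len(a) + len(b) - n), min(len(a), len(b)) + 1)
    pmf = rv.pmf(ks)
    pmf = pmf / pmf.sum()
    js = np.where(len(a) + len(b) - ks > 0,
                  ks / np.maximum(len(a) + len(b) - ks, 1), 1.0)
    p_le = float(pmf[js <= j_obs + 1e-12].sum())
    p_ge = float(pmf[js >= j_obs - 1e-12].sum())
    return JaccardEntry("", float(j_obs), p_le, p_ge, len(a), len(b), k_obs)


def hub_taxa(net: nx.Graph, percentile: float = 75.0,
             measures=HUB_MEASURES) -> set[str]:
    """Nodes above the percentile simultaneously for all given measures."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    cent = centralities(net)
    sets = [top_central_set(cent[m], percentile) for m in measures]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def compare_networks(net_a: nx.Graph, net_b: nx.Graph,
                     percentile: float = 75.0) -> pd.DataFrame:
    """Jaccard comparison table over the four centralities plus hub taxa."""
    universe = set(net_a.nodes) | set(net_b.nodes)
    cent_a, cent_b = centralities(net_a), centralities(net_b)
    rows = []
    for measure in ("degree", "betweenness", "closeness", "eigenvector"):
        entry = jaccard_with_null(
            top_central_set(cent_a[measure], percentile),
            top_central_set(cent_b[measure], percentile), universe)
        entry.measure = measure
        rows.append(entry)
    entry = jaccard_with_null(hub_taxa(net_a, percentile),
                              hub_taxa(net_b, percentile), universe)
    entry.measure = "hub"
    rows.append(entry)
    return pd.DataFrame(
        [(e.measure, e.jaccard, e.p_le, e.p_ge, e.size_a, e.size_b, e.overlap)
         for e in rows],
        columns=["measure", "jaccard", "p_le", "p_ge",
                 "size_a", "size_b", "overlap"])


def differential_edges(net_a: nx.Graph, net_b: nx.Graph) -> dict:
    """Partition edges into A-only, B-only, shared-same-sign, shared-sign-flip."""
    def edge_map(g):
        return {frozenset((u, v)): d.get("sign", 1)
                for u, v, d in g.edges(data=True)}

    ea, eb = edge_map(net_a), edge_map(net_b)
    shared = set(ea) & set(eb)
    out = {
        "a_only": sorted(tuple(sorted(e)) for e in set(ea) - set(eb)),
        "b_only": sorted(tuple(sorted(e)) for e in set(eb) - set(ea)),
        "shared_same_sign": sorted(tuple(sorted(e)) for e in shared
                                   if ea[e] == eb[e]),
        "shared_sign_flip": sorted(tuple(sorted(e)) for e in shared
                                   if ea[e] != eb[e]),
    }
    return out
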
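"""Network robustness: targeted/random node-removal attacks and node-addition
growth curves, with paired statistical comparison.

Connectivity loss after removing k nodes is the pair-connectivity functional
1 - (connected pairs remaining) / (connected pairs initially), which is
well defined on fragmented graphs and monotone along any removal sequence.
An LCC-based loss (1 - |LCC|/|LCC_0|) is emitted alongside for reference.

Node addition follows the simplest random-introduction rule: each new node is
attached by a single edge to a uniformly chosen existing node; the largest
connected component (LCC) and the average path length within it (APL) are
recorded after each addition.  APL is evaluated through igraph's C core so
the published grid sizes (up to 1000 additions) stay tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

STRATEGIES = ("random", "degree", "betweenness", "cascading")


def _connected_pairs(g: nx.Graph) -> int:
    return sum(len(c) * (len(c) - 1) // 2 for c in nx.connected_components(g))


def _lcc_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


@dataclass
class AttackCurve:
    """Connectivity loss as a function of the fraction of nodes removed."""

    strategy: str
    fraction_removed: np.ndarray
    connectivity_loss: np.ndarray
    lcc_loss: np.ndarray
    removal_order: list
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strategy": self.strategy,
            "fraction_removed": self.fraction_removed,
            "connectivity_loss": self.connectivity_loss,
            "lcc_loss": self.lcc_loss,
        })


def attack(net: nx.Graph, strategy: str, seed=None) -> AttackCurve:
    """Remove nodes one at a time and track connectivity loss.

    Strategies: ``random`` (uniform order, seeded), ``degree`` and
    ``betweenness`` (static ranking precomputed on the intact network, ties
    broken by node name), ``cascading`` (highest current betweenness,
    recomputed after every removal).
    """
    if net.number_of_edges() == 0:
        raise ValueError("attack undefined on a network with no edges")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    g = nx.Graph(net)
    n0 = g.number_of_nodes()
    pairs0 = _connected_pairs(g)
    lcc0 = _lcc_size(g)
    order = []
    if strategy == "random":
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes, key=str)
        order = [nodes[k] for k in rng.permutation(len(nodes))]
    elif strategy in ("degree", "betweenness"):
        score = (dict(g.degree()) if strategy == "degree"
                 else nx.betweenness_centrality(g, normalized=True))
        order = sorted(g.nodes, key=lambda v: (-score[v], str(v)))
    fracs = [0.0]
    loss = [0.0]
    lloss = [0.0]
    for k in range(n0):
        if strategy == "cascading":
            btw = nx.betweenness_centrality(g, normalized=True)
            victim = min(g.nodes, key=lambda v: (-btw[v], str(v)))
        else:
            victim = order[k]
        g.remove_node(victim)
        if strategy == "cascading":
            order.append(victim)
        fracs.append((k + 1) / n0)
        loss.append(1.0 - _connected_pairs(g) / pairs0)
        lloss.append(1.0 - _lcc_size(g) / lcc0)
    return AttackCurve(strategy=strategy,
                       fraction_removed=np.array(fracs),
                       connectivity_loss=np.array(loss),
                       lcc_loss=np.array(lloss),
                       removal_order=order if strategy != "random" else order,
                       seed=seed if strategy == "random" else None)


def pct_disconnection_point(curve: AttackCurve, level: float = 0.8) -> float:
    """Smallest fraction removed at which loss first reaches ``level``.

    Returns 1.0 if the level is never reached before exhaustion.
    """
    hit = np.flatnonzero(curve.connectivity_loss >= level - 1e-12)
    if len(hit) == 0:
        return 1.0
    return float(curve.fraction_removed[hit[0]])


# ---------------------------------------------------------------------------
# Node addition
# ---------------------------------------------------------------------------

@dataclass
class AdditionCurve:
    """LCC size and APL (within LCC) after each random node addition."""

    replicate: int
    n_added: np.ndarray
    lcc: np.ndarray
    apl: np.ndarray
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": self.replicate,
            "n_added": self.n_added,
            "lcc": self.lcc,
            "apl": self.apl,
        })


def _lcc_apl(edges: list[tuple[int, int]], n_vertices: int
             ) -> tuple[int, float]:
    g = ig.Graph(n=n_vertices, edges=edges, directed=False)
    comps = g.connected_components()
    sizes = comps.sizes()
    big = int(np.argmax(sizes))
    lcc = sizes[big]
    if lcc < 2:
        return lcc, float("nan")
    sub = comps.subgraph(big)
    return lcc, float(sub.average_path_length(directed=False, unconn=True))


def add_nodes(net: nx.Graph, n_add: int, reps: int = 3, seed=None,
              record_every: int = 1) -> list[AdditionCurve]:
    """Grow the network by attaching random nodes; record LCC and APL.

    Each new node is connected by one edge to an existing node chosen
    uniformly at random (added nodes become eligible targets).  Metrics are
    recorded every ``record_every`` additions (and always at the last one).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot add nodes to an empty network")
    if n_add < 0:
        raise ValueError("n_add must be >= 0")
    base_nodes = sorted(net.nodes)
    index = {v: k for k, v in enumerate(base_nodes)}
    base_edges = [(index[u], index[v]) for u, v in net.edges]
    rng = np.random.default_rng(seed)
    curves = []
    for rep in range(reps):
        edges = list(base_edges)
        n_vertices = len(base_nodes)
        steps, lccs, apls = [], [], []
        if n_add == 0:
            lcc, apl = _lcc_apl(edges, n_vertices)
            steps, lccs, apls = [0], [lcc], [apl]
        for k in range(1, n_add + 1):
            target = int(rng.integers(0, n_vertices))
            edges.append((n_vertices, target))
            n_vertices += 1
            if k % record_every == 0 or k == n_add:
                lcc, apl = _lcc_apl(edges, n_vertices)
                steps.append(k)
                lccs.append(lcc)
                apls.append(apl)
        curves.append(AdditionCurve(replicate=rep,
                                    n_added=np.array(steps),
                                    lcc=np.array(lccs, dtype=float),
                                    apl=np.array(apls, dtype=float),
                                    seed=seed))
    return curves


def addition_grid(net: nx.Graph, grid=(100, 300, 500, 700, 1000),
                  reps: int = 3, seed=None, record_every: int = 10
                  ) -> pd.DataFrame:
    """Run :func:`add_nodes` for each grid size; long-format results."""
    frames = []
    for i, n_add in enumerate(grid):
        sub_seed = None if seed is None else int(seed) + 1000 * (i + 1)
        for curve in add_nodes(net, n_add, reps=reps, seed=sub_seed,
                               record_every=record_every):
            f = curve.as_frame()
            f.insert(0, "grid", n_add)
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Paired comparison of addition curves
# ---------------------------------------------------------------------------

def compare_addition(curves_a, curves_b, seed=None,
                     n_boot: int = 2000) -> pd.DataFrame:
    """Wilcoxon signed-rank comparison of paired LCC/APL step series.

    Replicate curves are averaged per step, series are paired by addition
    step, zero differences are dropped (exact null distribution for <= 25
    informative pairs, normal approximation beyond), p-values are
    Benjamini-Hochberg adjusted across the tested metrics, and a percentile
    bootstrap (2.5/97.5) of the mean difference is attached.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for metric in ("lcc", "apl"):
        xa = np.nanmean(np.vstack([getattr(c, metric) for c in curves_a]),
                        axis=0)
        xb = np.nanmean(np.vstack([getattr(c, metric) for c in curves_b]),
                        axis=0)
        if xa.shape != xb.shape:
            raise ValueError("paired series must have equal length")
        ok = ~(np.isnan(xa) | np.isnan(xb))
        xa, xb = xa[ok], xb[ok]
        diff = xa - xb
        nz = diff[diff != 0]
        if len(nz) == 0:
            p = 1.0
        else:
            method = "exact" if len(nz) <= 25 else "approx"
            p = float(stats.wilcoxon(nz, zero_method="wilcox",
                                     method=method).pvalue)
        boots = np.array([
            float(np.mean(rng.choice(diff, size=len(diff), replace=True)))
            for _ in range(n_boot)]) if len(diff) else np.array([np.nan])
        rows.append((metric, float(np.mean(diff)) if len(diff) else np.nan,
                     p, float(np.percentile(boots, 2.5)),
                     float(np.percentile(boots, 97.5))))
    out = pd.DataFrame(rows, columns=["metric", "mean_diff", "p",
                                      "ci_low", "ci_high"])
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)
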
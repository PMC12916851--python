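"""Naive, independent reference implementations used to cross-check the
package's graph and clustering code on small instances."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on an unweighted adjacency matrix."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def shortest_path_counts(adj: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Number of shortest paths between every pair (dynamic programming)."""
    n = adj.shape[0]
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    order = np.argsort(d, axis=None)  # fill in increasing distance
    for flat in order:
        i, j = divmod(int(flat), n)
        if i == j or not np.isfinite(d[i, j]):
            continue
        if d[i, j] == 1:
            sigma[i, j] = 1.0
            continue
        total = 0.0
        for k in range(n):
            if adj[k, j] and d[i, k] + 1 == d[i, j]:
                total += sigma[i, k]
        sigma[i, j] = total
    return sigma


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness centrality from first principles."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    sigma = shortest_path_counts(adj, d)
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2
    return bc / norm if norm > 0 else bc


def closeness_per_component(adj: np.ndarray) -> np.ndarray:
    """(reachable - 1) / sum of distances, within each component."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(d[v]) & (np.arange(n) != v)
        tot = d[v, reach].sum()
        out[v] = reach.sum() / tot if tot > 0 else 0.0
    return out


def clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[i, j] > 0
                    for i, j in itertools.combinations(nbrs, 2))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def components(adj: np.ndarray) -> list[list[int]]:
    d = floyd_warshall(adj)
    seen, comps = set(), []
    for v in range(adj.shape[0]):
        if v in seen:
            continue
        comp = sorted(np.flatnonzero(np.isfinite(d[v])))
        seen |= set(comp)
        comps.append(comp)
    return comps


def lcc_diameter(adj: np.ndarray) -> int:
    d = floyd_warshall(adj)
    comp = max(components(adj), key=len)
    if len(comp) < 2:
        return 0
    sub = d[np.ix_(comp, comp)]
    return int(sub[np.isfinite(sub)].max())


def connected_pairs(adj: np.ndarray) -> int:
    return sum(len(c) * (len(c) - 1) // 2 for c in components(adj))


def eigenvector(adj_w: np.ndarray) -> np.ndarray:
    """Principal eigenvector of a weighted adjacency, L2-normalized."""
    vals, vecs = np.linalg.eigh(adj_w)
    v = vecs[:, np.argmax(vals)]
    if v.sum() < 0:
        v = -v
    return np.abs(v) / np.linalg.norm(v)


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def max_modularity(adj_w: np.ndarray) -> float:
    """Exhaustive maximum of Newman modularity over all node partitions."""
    n = adj_w.shape[0]
    m2 = adj_w.sum()  # 2m for symmetric matrix with zero diagonal
    deg = adj_w.sum(axis=0)
    best = -np.inf
    for part in set_partitions(range(n)):
        q = 0.0
        for block in part:
            idx = np.array(block)
            q += adj_w[np.ix_(idx, idx)].sum() / m2
            q -= (deg[idx].sum() / m2) ** 2
        best = max(best, q)
    return best


def upgma(dist: np.ndarray):
    """Naive O(n^3) UPGMA; returns merge heights in order of occurrence."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): dist[i, j]
         for i, j in itertools.combinations(range(n), 2)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        pair = min(d, key=lambda k: (d[k], sorted(k)))
        i, j = sorted(pair)
        heights.append(d[pair])
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        for k in list(d):
            if i in k or j in k:
                del d[k]
        for other, members in clusters.items():
            val = np.mean([dist[a, b] for a in merged for b in members])
            d[frozenset((next_id, other))] = val
        clusters[next_id] = merged
        next_id += 1
    return np.array(heights)


def jaccard_null_pmf(n_universe: int, size_a: int, size_b: int):
    """Exact distribution of J for two uniform random subsets (by overlap).

    Returns (j_values, probabilities) computed by direct combinatorial
    counting, independent of any hypergeometric library routine.
    """
    lo = max(0, size_a + size_b - n_universe)
    hi = min(size_a, size_b)
    total = comb(n_universe, size_b)
    js, ps = [], []
    for k in range(lo, hi + 1):
        ways = (comb(size_a, k) * comb(n_universe - size_a, size_b - k))
        union = size_a + size_b - k
        js.append(k / union if union else 1.0)
        ps.append(ways / total)
    return np.array(js), np.array(ps)


def wilcoxon_exact_two_sided(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign vectors."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    # handle ties by average ranks
    absd = np.abs(diffs)
    for val in np.unique(absd):
        idx = absd == val
        ranks[idx] = ranks[idx].mean()
    w_obs = ranks[diffs > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append((ranks * np.array(signs)).sum())
    stats = np.array(stats)
    mean = ranks.sum() / 2
    p = np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12)
    return float(p)
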
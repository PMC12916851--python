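"""Alpha and beta diversity statistics for taxa count tables.

Alpha diversity: observed features, Shannon entropy (base 2, the QIIME2
convention) and Pielou's evenness, with Kruskal-Wallis group comparisons.
Beta diversity: Bray-Curtis on counts and Jaccard distance on
presence/absence, principal coordinates analysis, PERMANOVA with an
exhaustive-enumeration small-sample mode, beta dispersion (distance to group
centroid in PCoA space with the negative-eigenvalue imaginary-axis
convention) and UPGMA clustering.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .tables_io import TaxaTable


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

@dataclass
class AlphaResult:
    """Per-sample alpha metrics plus per-metric Kruskal-Wallis group tests."""

    per_sample: pd.DataFrame      # observed_features, shannon, pielou
    tests: pd.DataFrame           # index metric, columns H, p


def alpha_diversity(table: TaxaTable, base: float = 2.0) -> AlphaResult:
    """Observed richness, Shannon entropy and Pielou evenness per sample.

    Shannon is -sum p_i log_b p_i over non-zero proportions (default bits);
    Pielou = shannon / log_b(observed), reported missing when observed == 1.
    Groups are compared per metric with the tie-corrected Kruskal-Wallis test
    over biological samples.
    """
    counts = table.counts
    totals = counts.sum(axis=1)
    empty = totals.index[totals == 0]
    if len(empty):
        raise ValueError(f"samples with zero reads: {sorted(map(str, empty))}")
    rows = {}
    for sid, row in counts.iterrows():
        x = row.to_numpy(float)
        x = x[x > 0]
        p = x / x.sum()
        observed = int(len(x))
        shannon = float(-(p * np.log(p) / np.log(base)).sum())
        pielou = (shannon / (np.log(observed) / np.log(base))
                  if observed > 1 else np.nan)
        rows[sid] = (observed, shannon, pielou)
    per_sample = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["observed_features", "shannon", "pielou"])
    per_sample.index.name = "sample_id"

    bio = ~table.is_control
    labels = table.group[bio]
    groups = sorted(labels.unique())
    tests = {}
    for metric in per_sample.columns:
        vals = [per_sample.loc[labels.index[labels == g], metric].dropna()
                for g in groups]
        if len(groups) >= 2 and all(len(v) for v in vals):
            if pd.concat(vals).nunique() <= 1:
                h, p = 0.0, 1.0  # all values tied: no evidence by convention
            else:
                h, p = stats.kruskal(*vals)
        else:
            h, p = np.nan, np.nan
        tests[metric] = (float(h), float(p))
    tests = pd.DataFrame.from_dict(tests, orient="index", columns=["H", "p"])
    return AlphaResult(per_sample=per_sample, tests=tests)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with a sample ordering."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data.to_numpy(float)
        if d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def condensed(self) -> np.ndarray:
        return squareform(self.values(), checks=False)


def beta_distance(table: TaxaTable, metric: str = "bray_curtis"
                  ) -> DistanceMatrix:
    """Pairwise Bray-Curtis (on counts) or Jaccard (on presence) distances.

    Bray-Curtis: sum|x_i - y_i| / sum(x_i + y_i).  Jaccard distance:
    1 - |shared present| / |union present|.  A pair of all-zero samples gets
    distance 0 with a warning.
    """
    x = table.counts.to_numpy(float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if metric == "bray_curtis":
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                warnings.warn("two all-zero samples; distance set to 0")
                val = 0.0
            else:
                val = np.abs(x[i] - x[j]).sum() / denom
        elif metric == "jaccard":
            a, b = x[i] > 0, x[j] > 0
            union = int((a | b).sum())
            if union == 0:
                warnings.warn("two all-zero samples; distance set to 0")
                val = 0.0
            else:
                val = 1.0 - int((a & b).sum()) / union
        else:
            raise ValueError(f"unknown metric {metric!r}")
        d[i, j] = d[j, i] = val
    ids = table.sample_ids
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame   # samples x axes (real axes only)
    eigenvalues: np.ndarray     # all eigenvalues, descending (may be < 0)
    axes_signs: np.ndarray      # +1 for positive-eigenvalue axes, -1 otherwise


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and scales eigenvectors by
    sqrt(|eigenvalue|).  Negative eigenvalues are reported (their axes carry
    sign -1 and correspond to imaginary coordinates); coordinates of
    positive axes reproduce the distances exactly for Euclidean input.
    """
    d = dm.values()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs * np.sqrt(np.abs(evals))[None, :]
    cols = [f"PC{k + 1}" for k in range(n)]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=cols),
        eigenvalues=evals,
        axes_signs=np.where(evals >= 0, 1, -1),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    f: float
    p: float
    n_perm: int
    exhaustive: bool


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None
              ) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between / (k-1)) / (SS_within / (n-k)) with the standard
    squared-distance partition.  p is estimated over label permutations with
    the (1 + #{F_perm >= F_obs}) / (1 + n_perm) estimator; when the number of
    distinct assignments (up to relabelling, for two equal groups) is <=
    n_perm the null is enumerated exhaustively and p is an exact proportion.
    """
    labels = np.asarray(list(groups), dtype=object)
    if len(labels) != len(dm.ids):
        raise ValueError("groups length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    d2 = dm.values() ** 2
    n, k = len(labels), len(uniq)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_stat(lab):
        ssw = _ss_within(d2, lab)
        ssb = ss_total - ssw
        return (ssb / (k - 1)) / (ssw / (n - k)) if ssw > 0 else np.inf

    f_obs = f_stat(labels)

    distinct = _n_distinct_assignments(counts)
    if distinct <= n_perm:
        perms = _enumerate_assignments(labels, uniq, counts)
        fs = np.array([f_stat(lab) for lab in perms])
        p = float((fs >= f_obs - 1e-12).sum()) / len(fs)
        return PermanovaResult(float(f_obs), p, len(fs), True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(labels)) >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(float(f_obs), (1 + hits) / (1 + n_perm),
                           n_perm, False)


def _n_distinct_assignments(counts) -> int:
    from math import comb
    n = int(np.sum(counts))
    total = 1
    rem = n
    for c in counts:
        total *= comb(rem, int(c))
        rem -= int(c)
    # equal-size groups: assignments identical up to relabelling give equal F
    sizes = sorted(counts)
    if len(set(sizes)) == 1:
        from math import factorial
        total //= factorial(len(sizes))
    return total


def _enumerate_assignments(labels, uniq, counts):
    """All distinct label assignments (up to relabelling when sizes equal)."""
    n = len(labels)
    if len(uniq) == 2 and counts[0] == counts[1]:
        seen, out = set(), []
        for idx in itertools.combinations(range(n), int(counts[0])):
            key = frozenset(idx)
            comp = frozenset(set(range(n)) - set(idx))
            if frozenset({key, comp}) in seen:
                continue
            seen.add(frozenset({key, comp}))
            lab = np.full(n, uniq[1], dtype=object)
            lab[list(idx)] = uniq[0]
            out.append(lab)
        return out
    out = []
    for perm in set(itertools.permutations(labels)):
        out.append(np.array(perm, dtype=object))
    return out


# ---------------------------------------------------------------------------
# Beta dispersion
# ---------------------------------------------------------------------------

@dataclass
class BetadisperResult:
    distances: pd.Series   # per-sample distance to group centroid
    f: float
    p: float


def betadisper(dm: DistanceMatrix, groups) -> BetadisperResult:
    """Multivariate homogeneity of group dispersions.

    Samples are embedded by PCoA keeping all axes; distances to the group
    centroid are computed with the vegan convention that negative-eigenvalue
    axes contribute negatively to the squared distance (imaginary parts).
    The group effect on those distances is tested by one-way ANOVA.
    """
    labels = pd.Series(list(groups), index=dm.ids)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if labels.value_counts().min() < 2:
        raise ValueError("every group needs >= 2 samples")
    res = pcoa(dm)
    coords = res.coordinates.to_numpy()
    signs = res.axes_signs.astype(float)
    dist = pd.Series(index=dm.ids, dtype=float)
    for g in uniq:
        idx = labels.index[labels == g]
        pos = [dm.ids.index(i) for i in idx]
        centroid = coords[pos].mean(axis=0)
        diff2 = (coords[pos] - centroid) ** 2
        d2 = (diff2 * signs[None, :]).sum(axis=1)
        dist.loc[idx] = np.sqrt(np.maximum(d2, 0.0))
    vals = [dist.loc[labels.index[labels == g]].to_numpy() for g in uniq]
    allv = np.concatenate(vals)
    if np.allclose(allv, allv[0]):
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*vals)
    return BetadisperResult(distances=dist, f=float(f), p=float(p))


# ---------------------------------------------------------------------------
# Hierarchical clustering / Venn
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    linkage: np.ndarray
    ids: list[str]

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hclust_tree(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """UPGMA (average-linkage) clustering of samples; heights non-decreasing."""
    if linkage != "average":
        raise ValueError("only average linkage (UPGMA) is supported")
    z = hierarchy.linkage(dm.condensed(), method="average")
    return Dendrogram(linkage=z, ids=dm.ids)


def venn_partition(taxa_a, taxa_b) -> dict:
    """Exact unique/shared/unique partition of two taxon sets."""
    a, b = set(taxa_a), set(taxa_b)
    return {
        "unique_a": sorted(a - b),
        "shared": sorted(a & b),
        "unique_b": sorted(b - a),
        "counts": (len(a - b), len(a & b), len(b - a)),
    }
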
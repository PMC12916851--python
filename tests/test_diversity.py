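import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import oracles
from mosqnet import TaxaTable, alpha_diversity, beta_distance, betadisper, \
    hclust_tree, pcoa, permanova, venn_partition
from mosqnet.diversity import DistanceMatrix


def make_table(rows, groups=None):
    counts = pd.DataFrame(rows)
    counts.index = [f"s{i}" for i in range(len(rows))]
    counts.columns = [f"t{j}" for j in range(counts.shape[1])]
    groups = groups or ["g"] * len(rows)
    return TaxaTable(counts, pd.Series(groups, index=counts.index),
                     pd.Series([False] * len(rows), index=counts.index))


def dm_from_array(a, ids=None):
    a = np.asarray(a, float)
    ids = ids or [f"s{i}" for i in range(a.shape[0])]
    return DistanceMatrix(pd.DataFrame(a, index=ids, columns=ids))


class TestAlpha:
    def test_uniform_sample(self):
        res = alpha_diversity(make_table([[10, 10, 10, 10]] * 2))
        row = res.per_sample.iloc[0]
        assert row["observed_features"] == 4
        assert row["shannon"] == pytest.approx(2.0)
        assert row["pielou"] == pytest.approx(1.0)

    def test_single_taxon_sample(self):
        res = alpha_diversity(make_table([[100, 0, 0, 0]] * 2))
        row = res.per_sample.iloc[0]
        assert row["observed_features"] == 1
        assert row["shannon"] == 0.0
        assert np.isnan(row["pielou"])

    def test_zero_count_taxon_changes_nothing(self):
        a = alpha_diversity(make_table([[5, 3, 2]] * 2)).per_sample
        b = alpha_diversity(make_table([[5, 3, 2, 0]] * 2)).per_sample
        np.testing.assert_allclose(a.to_numpy(float), b.to_numpy(float))

    def test_identical_groups_give_p_one(self):
        res = alpha_diversity(make_table(
            [[10, 5], [10, 5], [10, 5], [10, 5]], ["A", "A", "B", "B"]))
        assert res.tests.loc["observed_features", "p"] == pytest.approx(1.0)
        assert res.tests.loc["shannon", "p"] == pytest.approx(1.0)

    def test_empty_sample_is_named(self):
        with pytest.raises(ValueError, match="s1"):
            alpha_diversity(make_table([[3, 1], [0, 0]]))


@given(st.lists(st.integers(0, 40), min_size=2, max_size=8)
       .filter(lambda x: sum(x) > 0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_shannon_bounded_and_maximal_iff_uniform(counts):
    res = alpha_diversity(make_table([counts, counts]))
    row = res.per_sample.iloc[0]
    observed = row["observed_features"]
    assert row["shannon"] <= np.log2(observed) + 1e-9
    nonzero = [c for c in counts if c > 0]
    if len(set(nonzero)) == 1 and observed > 1:
        assert row["shannon"] == pytest.approx(np.log2(observed))
        assert row["pielou"] == pytest.approx(1.0)


@given(st.integers(0, 2 ** 31 - 1), st.integers(3, 7), st.integers(2, 6))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_distances_are_symmetric_bounded_metrics(seed, n_samples, n_taxa):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 30, size=(n_samples, n_taxa))
    counts[:, 0] += 1  # no all-zero samples
    t = make_table(counts)
    for metric in ("bray_curtis", "jaccard"):
        d = beta_distance(t, metric).values()
        assert np.allclose(d, d.T)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(np.diag(d), 0.0)


class TestBetaDistance:
    def test_identical_and_disjoint(self):
        t = make_table([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]])
        for metric in ("bray_curtis", "jaccard"):
            d = beta_distance(t, metric).values()
            assert d[0, 1] == pytest.approx(0.0)
            assert d[0, 2] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        d = beta_distance(make_table([[1, 2, 3], [3, 2, 1]]),
                          "bray_curtis").values()
        assert d[0, 1] == pytest.approx(4 / 12)

    def test_matches_scipy_and_taxa_permutation_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(6, 9))
        t = make_table(counts)
        d = beta_distance(t, "bray_curtis").values()
        ref = squareform(pdist(counts, metric="braycurtis"))
        np.testing.assert_allclose(d, ref, atol=1e-12)
        perm = rng.permutation(9)
        d2 = beta_distance(make_table(counts[:, perm]), "bray_curtis").values()
        np.testing.assert_allclose(d, d2, atol=1e-12)


class TestPCoA:
    def test_identical_samples_collapse(self):
        res = pcoa(dm_from_array(np.zeros((3, 3))))
        np.testing.assert_allclose(res.coordinates.to_numpy(), 0, atol=1e-9)

    def test_equilateral_triangle_spectrum(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(dm_from_array(d))
        np.testing.assert_allclose(sorted(res.eigenvalues)[::-1],
                                   [0.5, 0.5, 0.0], atol=1e-10)

    def test_euclidean_isometry(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        res = pcoa(dm_from_array(d))
        keep = res.eigenvalues > 1e-9
        coords = res.coordinates.to_numpy()[:, keep]
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-8)


class TestPermanova:
    def test_two_vs_two_exhaustive(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(4, 2))
        d = squareform(pdist(pts))
        res = permanova(dm_from_array(d), ["A", "A", "B", "B"])
        assert res.exhaustive
        assert res.n_perm == 3  # distinct splits up to relabelling
        assert res.p in (pytest.approx(1 / 3), pytest.approx(2 / 3),
                         pytest.approx(1.0))
        # brute force over all 3 distinct splits
        d2 = d ** 2
        n = 4

        def f_for(lab):
            lab = np.array(lab)
            ss_tot = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in set(lab):
                idx = np.flatnonzero(lab == g)
                ssw += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)
                                            ].sum() / len(idx)
            return (ss_tot - ssw) / (ssw / 2)

        fs = [f_for(l) for l in (["A", "A", "B", "B"], ["A", "B", "A", "B"],
                                 ["A", "B", "B", "A"])]
        expected_p = np.mean(np.array(fs) >= fs[0] - 1e-12)
        assert res.p == pytest.approx(expected_p)

    def test_identical_clouds_give_p_one(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [0, 0], [1, 0], [0, 1]],
                       float)
        d = squareform(pdist(pts))
        res = permanova(dm_from_array(d),
                        ["A", "A", "A", "B", "B", "B"], n_perm=99, seed=0)
        assert res.f == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_matches_skbio_f(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        pts[5:] += 1.0
        d = squareform(pdist(pts))
        labels = ["A"] * 5 + ["B"] * 5
        res = permanova(dm_from_array(d), labels, n_perm=99, seed=0)
        sk = sk_permanova(skbio.DistanceMatrix(d), grouping=labels,
                          permutations=99)
        assert res.f == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_group_of_one_rejected(self):
        d = squareform(pdist(np.eye(3)))
        with pytest.raises(ValueError):
            permanova(dm_from_array(d), ["A", "B", "B"])


class TestBetadisper:
    def test_mirror_groups_equal_dispersion(self):
        pts = np.array([[1, 0], [-1, 0], [0, 2], [-0 - 1, 1], [1, -1],
                        [0, -2]], float)
        pts = np.vstack([pts, -pts])
        d = squareform(pdist(pts))
        res = betadisper(dm_from_array(d), ["A"] * 6 + ["B"] * 6)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_tight_vs_spread_groups(self):
        rng = np.random.default_rng(4)
        tight = rng.normal(scale=0.01, size=(6, 2))
        spread = rng.normal(scale=5.0, size=(6, 2))
        d = squareform(pdist(np.vstack([tight, spread])))
        res = betadisper(dm_from_array(d), ["A"] * 6 + ["B"] * 6)
        assert res.p < 0.01

    def test_single_axis_hand_distances(self):
        # colinear points: PCoA reduces to the line; distances to centroid
        # are plain absolute deviations
        x = np.array([0.0, 2.0, 10.0, 14.0])
        d = np.abs(x[:, None] - x[None, :])
        res = betadisper(dm_from_array(d), ["A", "A", "B", "B"])
        np.testing.assert_allclose(sorted(res.distances[:2]), [1, 1],
                                   atol=1e-9)
        np.testing.assert_allclose(sorted(res.distances[2:]), [2, 2],
                                   atol=1e-9)


class TestClusteringVenn:
    def test_two_samples_single_merge(self):
        d = np.array([[0, 0.4], [0.4, 0]])
        tree = hclust_tree(dm_from_array(d))
        assert tree.linkage[0, 2] == pytest.approx(0.4)
        assert tree.newick().count(",") == 1

    def test_closest_pair_merges_first(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        tree = hclust_tree(dm_from_array(d))
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}
        assert tree.linkage[0, 2] == pytest.approx(0.1)

    def test_merge_heights_match_naive_upgma(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            pts = rng.normal(size=(n, 2))
            d = squareform(pdist(pts))
            tree = hclust_tree(dm_from_array(d))
            np.testing.assert_allclose(tree.linkage[:, 2],
                                       oracles.upgma(d), atol=1e-9)
            assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()

    @pytest.mark.parametrize("a,b,expected", [
        ({"a", "b", "c"}, {"b", "c", "d"}, (1, 2, 1)),
        ({"a", "b"}, {"a", "b"}, (0, 2, 0)),
        ({"a", "b"}, {"c"}, (2, 0, 1)),
    ])
    def test_venn_partition(self, a, b, expected):
        assert venn_partition(a, b)["counts"] == expected
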
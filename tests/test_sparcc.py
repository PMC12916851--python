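import itertools

import numpy as np
import pandas as pd
import pytest

from mosqnet import SparCC, basis_correlations, sparcc_infer, \
    threshold_edges, variation_matrix


class TestVariationMatrix:
    def test_proportional_columns_have_zero_entry(self):
        counts = np.array([[10, 20, 5], [20, 40, 30], [5, 10, 2]])
        t = variation_matrix(counts, pseudocount=0)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert t[0, 2] > 0

    def test_matches_naive_per_pair_variance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, size=(8, 5))
        t = variation_matrix(counts, pseudocount=1)
        f = (counts + 1) / (counts + 1).sum(axis=1, keepdims=True)
        for i, j in itertools.combinations(range(5), 2):
            direct = np.var(np.log(f[:, i] / f[:, j]), ddof=1)
            assert t[i, j] == pytest.approx(direct, rel=1e-10)
        assert np.allclose(t, t.T) and np.allclose(np.diag(t), 0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 100, size=(6, 4))
        t1 = variation_matrix(counts)
        t2 = variation_matrix(counts[::-1])
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            variation_matrix(np.ones((4, 2)))


class TestBasisCorrelations:
    def test_independent_unit_variances(self):
        # independent log-abundances with variances (1,1,1): t off-diag = 2
        t = 2.0 * (np.ones((3, 3)) - np.eye(3))
        w, r = basis_correlations(t)
        np.testing.assert_allclose(w, [1, 1, 1], atol=1e-12)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-12)

    def test_d3_closed_form(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            # random valid variation matrix from random basis variances/corr
            w_true = rng.uniform(0.2, 3.0, size=3)
            t = np.zeros((3, 3))
            for i, j in itertools.combinations(range(3), 2):
                rho = rng.uniform(-0.5, 0.5)
                t[i, j] = t[j, i] = (w_true[i] + w_true[j]
                                    - 2 * rho * np.sqrt(w_true[i] * w_true[j]))
            w, _ = basis_correlations(t)
            w1 = (t[0, 1] + t[0, 2] - t[1, 2]) / 2
            if w1 > 1e-6:
                assert w[0] == pytest.approx(w1, abs=1e-10)
            else:  # non-positive solutions are floored
                assert w[0] == pytest.approx(1e-6)

    def test_structure_on_random_input(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0.5, 2.0, size=(6, 6))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0)
        _, r = basis_correlations(t)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0 + 1e-12).all()


class TestInference:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 500, size=(10, 6))
        r1 = sparcc_infer(counts, n_resamples=3, seed=42).correlations
        r2 = sparcc_infer(counts, n_resamples=3, seed=42).correlations
        pd.testing.assert_frame_equal(r1, r2)

    def test_scale_invariance_of_variation_input(self):
        # multiplying a sample's counts by a constant leaves fractions, and
        # hence t and r, unchanged (pseudocount-free fractions)
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 200, size=(8, 5)).astype(float)
        t1 = variation_matrix(counts, pseudocount=0)
        scaled = counts.copy()
        scaled[2] *= 7.5
        scaled[5] *= 0.3
        t2 = variation_matrix(scaled, pseudocount=0)
        np.testing.assert_allclose(t1, t2, atol=1e-12)
        _, r1 = basis_correlations(t1)
        _, r2 = basis_correlations(t2)
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_taxa_reordering_equivariance(self):
        # the deterministic core (variation matrix + basis solve) commutes
        # exactly with a permutation of the taxa
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 500, size=(10, 5))
        perm = np.array([2, 0, 4, 1, 3])
        t1 = variation_matrix(counts)
        t2 = variation_matrix(counts[:, perm])
        np.testing.assert_allclose(t1[np.ix_(perm, perm)], t2, atol=1e-12)
        _, r1 = basis_correlations(t1)
        _, r2 = basis_correlations(t2)
        np.testing.assert_allclose(r1[np.ix_(perm, perm)], r2, atol=1e-10)

    def test_zero_and_constant_columns_dropped(self):
        counts = pd.DataFrame({
            "a": [10, 50, 20, 80, 30, 60],
            "b": [5, 25, 40, 10, 70, 15],
            "c": [40, 8, 12, 55, 9, 33],
            "d": [22, 61, 17, 43, 70, 12],
            "zero": [0] * 6,
            "const": [7] * 6,
        })
        model = SparCC(counts, variance_filter=False)
        assert set(model.dropped_taxa) == {"zero", "const"}

    def test_variance_filter_drops_pinned_taxon(self):
        rng = np.random.default_rng(7)
        n = 12
        logab = rng.normal(0, 1.0, size=(n, 4))
        dominant = np.full((n, 1), 6.0)  # constant relative abundance
        ab = np.exp(np.hstack([dominant, logab]))
        props = ab / ab.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(50_000, p) for p in props])
        model = SparCC(pd.DataFrame(
            counts, columns=["dom", "a", "b", "c", "d"]))
        assert "dom" in model.dropped_taxa
        assert set(model.counts.columns) == {"a", "b", "c", "d"}


class TestThresholdEdges:
    def test_boundary_is_inclusive(self):
        r = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        r.loc["a", "b"] = r.loc["b", "a"] = 0.5
        r.loc["a", "c"] = r.loc["c", "a"] = 0.49
        r.loc["b", "c"] = r.loc["c", "b"] = -0.5
        edges = threshold_edges(r, 0.5)
        got = {(row.taxon_a, row.taxon_b): row.sign
               for row in edges.itertuples()}
        assert got == {("a", "b"): 1, ("b", "c"): -1}

    def test_no_edges_below_cutoff(self):
        r = pd.DataFrame(np.eye(4))
        assert threshold_edges(r, 0.5).empty

    def test_cutoff_validated(self):
        with pytest.raises(ValueError):
            threshold_edges(pd.DataFrame(np.eye(3)), 1.5)
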
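"""Gower centering, eigenvector extraction/selection, variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from phylopartition import (PhyloEigenvectorRegression, extract_eigenvectors,
                            gower_center, partition_variance,
                            select_eigenvectors, simulate_yule_tree)
from phylopartition.pvr import inverse_distance_weights


class TestGowerCenter:
    def test_star_tree_closed_form(self, star4):
        # constant off-diagonal d: G = (d^2/2) * C -> eigenvalues {2,2,2,0}
        G = gower_center(star4.patristic_distances())
        vals = np.sort(np.linalg.eigvalsh(G))[::-1]
        assert np.allclose(vals, [2.0, 2.0, 2.0, 0.0], atol=1e-10)

    def test_two_taxa(self):
        from phylopartition import Phylogeny
        tree = Phylogeny.from_newick_string("(A:1,B:1);")
        G = gower_center(tree.patristic_distances())
        assert np.allclose(np.sort(np.linalg.eigvalsh(G)), [0.0, 2.0],
                           atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_rows_and_columns_sum_to_zero(self, seed):
        tree = simulate_yule_tree(12, seed=300 + seed)
        G = gower_center(tree.patristic_distances())
        assert np.allclose(G.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(G.sum(axis=1), 0.0, atol=1e-10)
        assert np.allclose(G, G.T)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gower_center(np.array([[0.0, 1], [2, 0]]))


class TestExtractEigenvectors:
    def test_star_tree_equal_eigenvalues(self, star4):
        basis = extract_eigenvectors(gower_center(star4.patristic_distances()))
        assert basis.k == 3
        assert np.allclose(basis.eigenvalues, 2.0)

    def test_orthonormal_columns(self, yule20):
        basis = extract_eigenvectors(
            gower_center(yule20.patristic_distances()), tuple(yule20.tips))
        V = basis.vectors
        assert np.allclose(V.T @ V, np.eye(basis.k), atol=1e-10)
        assert (np.diff(basis.eigenvalues) <= 1e-12).all()  # descending

    def test_leading_vector_separates_cherries(self, balanced4):
        basis = extract_eigenvectors(
            gower_center(balanced4.patristic_distances()))
        v1 = basis.vectors[:, 0]
        # oracle check: full eigendecomposition, pick leading eigenvector
        G = gower_center(balanced4.patristic_distances())
        vals, vecs = np.linalg.eigh(G)
        lead = vecs[:, np.argmax(vals)]
        assert abs(abs(v1 @ lead) - 1.0) < 1e-10
        assert np.sign(v1[0]) == np.sign(v1[1]) != np.sign(v1[2])

    def test_sign_convention_first_loading_positive(self, yule20):
        basis = extract_eigenvectors(
            gower_center(yule20.patristic_distances()))
        for j in range(basis.k):
            col = basis.vectors[:, j]
            assert col[np.flatnonzero(np.abs(col) > 1e-12)[0]] > 0


class TestSelectEigenvectors:
    def _setup(self, tree):
        d = tree.patristic_distances()
        basis = extract_eigenvectors(gower_center(d), tuple(tree.tips))
        return basis, inverse_distance_weights(d)

    def test_perfect_eigenvector_response(self, yule20):
        basis, w = self._setup(yule20)
        y = basis.vectors[:, 0]
        sel = select_eigenvectors(y, basis, w, B=199, seed=0)
        assert sel == [0]

    def test_iid_noise_rarely_selects(self):
        small = 0
        for r in range(50):
            tree = simulate_yule_tree(20, seed=400 + r)
            basis, w = self._setup(tree)
            y = np.random.default_rng(500 + r).standard_normal(20)
            sel = select_eigenvectors(y, basis, w, B=199, seed=600 + r)
            small += len(sel) <= 1
        assert small / 50 >= 0.8

    def test_deterministic_under_fixed_seed(self, yule20):
        basis, w = self._setup(yule20)
        y = yule20.tip_depths().to_numpy() + basis.vectors[:, 1]
        a = select_eigenvectors(y, basis, w, B=199, seed=3)
        b = select_eigenvectors(y, basis, w, B=199, seed=3)
        assert a == b

    def test_alpha_one_stops_immediately(self, yule20):
        basis, w = self._setup(yule20)
        y = basis.vectors[:, 0] + basis.vectors[:, 2]
        sel = select_eigenvectors(y, basis, w, alpha=1.0, B=199, seed=4)
        assert sel == []


class TestPartitionVariance:
    def test_fully_shared(self, yule20):
        basis = extract_eigenvectors(
            gower_center(yule20.patristic_distances()))
        v1 = basis.vectors[:, 0]
        part = partition_variance(v1, v1[:, None], v1[:, None])
        assert part.traits_alone == pytest.approx(0.0, abs=1e-9)
        assert part.shared == pytest.approx(1.0, abs=1e-9)
        assert part.phylo_alone == pytest.approx(0.0, abs=1e-9)
        assert part.unexplained == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_components_split_evenly(self, yule20):
        basis = extract_eigenvectors(
            gower_center(yule20.patristic_distances()))
        v = basis.vectors[:, 0]
        rng = np.random.default_rng(12)
        t = rng.standard_normal(20)
        t -= t.mean()
        t -= (t @ v) * v  # orthogonalize against v (and the intercept)
        t /= np.linalg.norm(t)
        y = t + v
        part = partition_variance(y, t[:, None], v[:, None])
        assert part.traits_alone == pytest.approx(0.5, abs=1e-9)
        assert part.phylo_alone == pytest.approx(0.5, abs=1e-9)
        assert part.shared == pytest.approx(0.0, abs=1e-9)
        assert part.unexplained == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_r2_oracle(self, yule20):
        import statsmodels.api as sm
        rng = np.random.default_rng(13)
        basis = extract_eigenvectors(
            gower_center(yule20.patristic_distances()))
        X = rng.standard_normal((20, 3))
        E = basis.vectors[:, :2]
        y = X @ np.array([1.0, -1, 0.5]) + E @ np.array([2.0, 1]) \
            + rng.standard_normal(20)
        part = partition_variance(y, X, E)

        def r2(Z):
            return sm.OLS(y, sm.add_constant(Z)).fit().rsquared

        r2_t, r2_p, r2_tp = r2(X), r2(E), r2(np.column_stack([X, E]))
        assert part.traits_alone == pytest.approx(r2_tp - r2_p, abs=1e-9)
        assert part.phylo_alone == pytest.approx(r2_tp - r2_t, abs=1e-9)
        assert part.shared == pytest.approx(r2_t + r2_p - r2_tp, abs=1e-9)
        assert part.unexplained == pytest.approx(1 - r2_tp, abs=1e-9)

    def test_fractions_sum_to_one(self, paperlike):
        from phylopartition import apply_floors, build_design_matrix
        design = build_design_matrix(
            apply_floors(paperlike["traits"], "tannin_pct_tae"))
        results = PhyloEigenvectorRegression(
            paperlike["behaviors"], design, paperlike["tree"], B=199,
            seed=0).fit()
        table = results.summary()
        sums = table[["traits_alone", "shared", "phylo_alone",
                      "unexplained"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert list(table.index) == list(paperlike["behaviors"].columns)

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(14)
        y = rng.standard_normal(5)
        with pytest.raises(ValueError, match="saturated"):
            partition_variance(y, rng.standard_normal((5, 3)),
                               rng.standard_normal((5, 2)))

    def test_phylogeny_free_traits_have_no_shared_fraction(self):
        shared = []
        for r in range(50):
            tree = simulate_yule_tree(50, seed=700 + r)
            rng = np.random.default_rng(800 + r)
            X = rng.standard_normal((50, 3))
            y = X @ np.array([1.0, 0.5, -1]) + rng.standard_normal(50)
            d = tree.patristic_distances()
            basis = extract_eigenvectors(gower_center(d), tuple(tree.tips))
            sel = select_eigenvectors(y, basis,
                                      inverse_distance_weights(d), B=99,
                                      seed=900 + r)
            shared.append(
                partition_variance(y, X, basis.vectors[:, sel]).shared)
        assert abs(np.mean(shared)) < 0.05
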
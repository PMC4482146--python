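"""Tree parsing, patristic distances, Abouheif proximities, normalization."""

import itertools

import numpy as np
import pytest

from phylopartition import (NewickParseError, Phylogeny, WeightMatrix,
                            abouheif_proximity, normalize_weights,
                            patristic_distances, simulate_yule_tree)

from conftest import random_trees


class TestNewickReading:
    def test_balanced_tree_read_back(self, balanced4):
        assert balanced4.tips == ["A", "B", "C", "D"]
        assert balanced4.n_tips == 4
        assert balanced4.is_ultrametric()
        assert np.allclose(balanced4.tip_depths(), 2.0)

    def test_star_polytomy(self):
        tree = Phylogeny.from_newick_string("(A:1,B:1,C:1);")
        assert tree.tips == ["A", "B", "C"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises((NewickParseError, Exception)) as exc:
            Phylogeny.from_newick_string("((A:1,A:1):1,B:2);")
        assert "dup" in str(exc.value).lower() or "A" in str(exc.value)

    def test_malformed_string_rejected(self):
        with pytest.raises(NewickParseError):
            Phylogeny.from_newick_string("((A:1,B:1;")

    def test_missing_branch_lengths_default_to_unit(self):
        with pytest.warns(UserWarning, match="branch length"):
            tree = Phylogeny.from_newick_string("((A,B),(C,D));")
        D = patristic_distances(tree).to_dataframe()
        assert D.loc["A", "B"] == 2.0
        assert D.loc["A", "C"] == 4.0

    def test_newick_round_trip(self, balanced4):
        again = Phylogeny.from_newick_string(balanced4.to_newick())
        assert again.tips == balanced4.tips
        assert np.allclose(patristic_distances(again).values,
                           patristic_distances(balanced4).values)


class TestPatristicDistances:
    def test_balanced_tree_hand_values(self, balanced4):
        D = patristic_distances(balanced4).to_dataframe()
        assert D.loc["A", "B"] == pytest.approx(2.0)
        assert D.loc["A", "C"] == pytest.approx(4.0)
        assert D.loc["C", "D"] == pytest.approx(2.0)

    def test_star_tree_constant(self, star4):
        D = patristic_distances(star4).values
        off = D[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_properties_on_random_trees(self, seed):
        tree = simulate_yule_tree(12, seed=seed)
        D = patristic_distances(tree).values
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all()
        # ultrametric trees satisfy the triangle inequality
        n = D.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


def _all_binary_topologies(labels):
    """All rooted binary topologies on the given labeled tips, as newick."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for size in range(0, len(rest)):
        for group in itertools.combinations(rest, size):
            left = (first,) + group
            right = tuple(l for l in rest if l not in group)
            if not right:
                continue
            for lt in _all_binary_topologies(left):
                for rt in _all_binary_topologies(right):
                    yield f"({lt},{rt})"


def _abouheif_oracle(tree):
    """Path enumeration through an undirected graph of the tree (networkx)."""
    import networkx as nx

    g = nx.Graph()
    node_children = {}
    leaf_of = {}
    for node in tree._tree.preorder_node_iter():
        node_children[id(node)] = len(node.child_nodes())
        for child in node.child_nodes():
            g.add_edge(id(node), id(child))
        if node.is_leaf():
            leaf_of[node.taxon.label if node.taxon else node.label] = id(node)
    tips = tree.tips
    n = len(tips)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = nx.shortest_path(g, leaf_of[tips[i]], leaf_of[tips[j]])
            prod = 1.0
            for node_id in path[1:-1]:
                prod *= node_children[node_id]
            A[i, j] = A[j, i] = 1.0 / prod
    return A


class TestAbouheifProximity:
    def test_balanced_tree_hand_values(self, balanced4):
        A = abouheif_proximity(balanced4).to_dataframe()
        assert A.loc["A", "B"] == pytest.approx(1 / 2)
        assert A.loc["A", "C"] == pytest.approx(1 / 8)
        assert A.loc["C", "D"] == pytest.approx(1 / 2)

    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_star_tree(self, n):
        labels = ",".join(f"t{i}:1" for i in range(n))
        tree = Phylogeny.from_newick_string(f"({labels});")
        A = abouheif_proximity(tree).values
        off = A[~np.eye(n, dtype=bool)]
        assert np.allclose(off, 1 / n)

    def test_branch_length_invariance(self):
        a = Phylogeny.from_newick_string("((A:1,B:2):3,(C:4,D:5):6);")
        b = Phylogeny.from_newick_string("((A:10,B:20):30,(C:40,D:50):60);")
        assert np.allclose(abouheif_proximity(a).values,
                           abouheif_proximity(b).values)

    @pytest.mark.parametrize("n_tips", [3, 4, 5])
    def test_matches_path_oracle_on_all_topologies(self, n_tips):
        labels = tuple(f"t{i}" for i in range(n_tips))
        for newick in _all_binary_topologies(labels):
            tree = Phylogeny.from_newick_string(_with_unit_lengths(newick))
            got = abouheif_proximity(tree).values
            want = _abouheif_oracle(tree)
            assert np.allclose(got, want, atol=1e-12), newick

    def test_matches_path_oracle_with_polytomies(self):
        for newick in ["((A:1,B:1,C:1):1,(D:1,E:1):1);",
                       "(A:1,(B:1,C:1):1,D:1,E:1);"]:
            tree = Phylogeny.from_newick_string(newick)
            assert np.allclose(abouheif_proximity(tree).values,
                               _abouheif_oracle(tree), atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_path_oracle_on_random_trees(self, seed):
        tree = simulate_yule_tree(10, seed=100 + seed)
        assert np.allclose(abouheif_proximity(tree).values,
                           _abouheif_oracle(tree), atol=1e-12)


def _with_unit_lengths(newick_topology: str) -> str:
    import re
    return re.sub(r"(t\d+|\))", r"\1:1", newick_topology) + ";"


class TestNormalizeWeights:
    def test_row_normalized_balanced_example(self, balanced4):
        R = normalize_weights(abouheif_proximity(balanced4), "row_normalized")
        df = R.to_dataframe()
        assert df.loc["A", "B"] == pytest.approx(2 / 3)
        assert df.loc["A", "C"] == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", range(4))
    def test_rows_sum_to_one(self, seed):
        tree = simulate_yule_tree(15, seed=200 + seed)
        R = normalize_weights(abouheif_proximity(tree), "row_normalized")
        assert np.allclose(R.values.sum(axis=1), 1.0, atol=1e-12)

    def test_idempotent_on_normalized_input(self, balanced4):
        R = normalize_weights(abouheif_proximity(balanced4), "row_normalized")
        R2 = normalize_weights(R, "row_normalized")
        assert np.allclose(R.values, R2.values, atol=1e-15)

    def test_symmetrized_differs_when_row_sums_unequal(self):
        # 3-taxon caterpillar: unequal proximity row sums
        tree = Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")
        R = normalize_weights(abouheif_proximity(tree), "row_normalized")
        S = normalize_weights(abouheif_proximity(tree),
                              "symmetrized_row_normalized")
        assert not np.allclose(R.values, S.values)
        assert np.allclose(S.values, S.values.T)

    def test_zero_row_sum_names_species(self):
        w = WeightMatrix(("A", "B", "C"),
                         np.array([[0, 1, 1], [1, 0, 1], [0, 0, 0.]]),
                         kind="custom")
        with pytest.raises(ValueError, match="C"):
            normalize_weights(w, "row_normalized")


class TestWeightMatrix:
    def test_csv_round_trip(self, tmp_path, balanced4):
        w = patristic_distances(balanced4)
        path = tmp_path / "d.csv"
        w.to_csv(path)
        again = WeightMatrix.from_csv(path, kind=w.kind)
        assert again.labels == w.labels
        assert np.allclose(again.values, w.values)

    def test_align_reorders(self, balanced4):
        w = patristic_distances(balanced4)
        v = w.align(["D", "C", "B", "A"])
        assert v.to_dataframe().loc["D", "A"] == w.to_dataframe().loc["A", "D"]

    def test_collapse_clades_polytomizes(self, paperlike):
        tree = paperlike["tree"]
        clade = [t for t in tree.tips if t.startswith("fagA_")]
        collapsed = tree.collapse_clades({"fagA": clade})
        assert sorted(collapsed.tips) == sorted(tree.tips)
        A = abouheif_proximity(collapsed).to_dataframe()
        # within the collapsed clade every pair passes one polytomy only
        vals = [A.loc[a, b] for a in clade for b in clade if a != b]
        assert len(set(np.round(vals, 12))) == 1
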
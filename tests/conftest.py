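import numpy as np
import pytest

from phylopartition import (Phylogeny, normalize_weights, paperlike_dataset,
                            simulate_yule_tree)


@pytest.fixture(scope="session")
def balanced4():
    """((A,B),(C,D)) with unit branches; ultrametric depth 2."""
    return Phylogeny.from_newick_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def star4():
    return Phylogeny.from_newick_string("(A:1,B:1,C:1,D:1);")


@pytest.fixture(scope="session")
def balanced4_weights(balanced4):
    return normalize_weights(balanced4.abouheif_proximity(), "row_normalized")


@pytest.fixture(scope="session")
def yule20():
    return simulate_yule_tree(20, seed=424242)


@pytest.fixture(scope="session")
def paperlike():
    return paperlike_dataset(seed=20110101, noise_sd=1.0)


def random_trees(n_trees: int, n_tips: int, base_seed: int):
    return [simulate_yule_tree(n_tips, seed=base_seed + i)
            for i in range(n_trees)]


def morans_i_double_loop(x, W):
    """Naive O(n^2) oracle for Moran's I."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    n = x.size
    z = x - x.mean()
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            S0 += W[i, j]
    return (n / S0) * num / float((z * z).sum())
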
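"""Phylogenetic autocorrelation statistics and their permutation nulls.

Moran's I measures whether a trait is more similar among closely related
species than expected under random tip labeling:

    I = (n / S0) * (z' W z) / (z' z),   z = x - mean(x),  S0 = sum_ij w_ij

with expectation -1/(n-1) under the permutation null.  The Abouheif test is
Moran's I computed on the row-normalized Abouheif proximity matrix, with
significance from tip-label permutations.  Kendall's W concordance over a set
of distance matrices (the CADM test) checks whether independently derived
distance matrices rank species pairs congruently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .trees import Phylogeny, WeightMatrix, abouheif_proximity, normalize_weights

__all__ = [
    "PermutationTestResult",
    "morans_i",
    "signal_test",
    "abouheif_test",
    "cadm_concordance",
]


@dataclass
class PermutationTestResult:
    """A statistic, its permutation null, and the add-one p-value.

    ``p = (1 + #{null >= statistic}) / (B + 1)`` for the upper tail (mirrored
    for the lower; doubled-min capped at 1 for two-sided), so p is never 0.
    """

    statistic: float
    null_values: np.ndarray
    p_value: float
    tail: str
    B: int
    seed: int
    matrix_kind: str = "custom"

    def to_json(self) -> str:
        return json.dumps({
            "statistic": self.statistic, "p": self.p_value, "B": self.B,
            "seed": self.seed, "tail": self.tail,
            "matrix_kind": self.matrix_kind,
        })


def _permutation_pvalue(stat: float, null: np.ndarray, tail: str) -> float:
    B = null.size
    upper = (1 + int(np.sum(null >= stat))) / (B + 1)
    lower = (1 + int(np.sum(null <= stat))) / (B + 1)
    if tail == "upper":
        return upper
    if tail == "lower":
        return lower
    if tail == "two_sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown tail {tail!r}")


def _as_weights(w: WeightMatrix | np.ndarray) -> np.ndarray:
    return w.values if isinstance(w, WeightMatrix) else np.asarray(w, dtype=float)


def morans_i(x: np.ndarray, w: WeightMatrix | np.ndarray) -> float:
    """Moran's I of a trait vector against a weight matrix.

    Raises on constant input: the statistic is undefined, not zero.
    """
    x = np.asarray(x, dtype=float)
    W = _as_weights(w)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if W.shape != (n, n):
        raise ValueError(f"weight matrix {W.shape} does not match n={n}")
    z = x - x.mean()
    zz = float(z @ z)
    if zz <= 0:
        raise ValueError("Moran's I is undefined for a constant trait")
    S0 = float(W.sum())
    return (n / S0) * float(z @ W @ z) / zz


def _null_morans(z: np.ndarray, W: np.ndarray, B: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized Moran's I over B random tip-label permutations of z."""
    n = z.size
    zz = float(z @ z)  # invariant under permutation
    S0 = float(W.sum())
    idx = np.argsort(rng.random((B, n)), axis=1)
    Zp = z[idx]
    quad = np.einsum("bi,bi->b", Zp @ W, Zp)
    return (n / S0) * quad / zz


def signal_test(x: np.ndarray, w: WeightMatrix | np.ndarray, B: int = 999,
                seed: int = 0, tail: str = "upper") -> PermutationTestResult:
    """Permutation test of phylogenetic signal via Moran's I.

    The trait values are shuffled across tips ``B`` times to build the null;
    the default upper tail asks for positive autocorrelation (relatives more
    alike than chance).
    """
    if B < 99:
        raise ValueError(f"B must be at least 99, got {B}")
    x = np.asarray(x, dtype=float)
    W = _as_weights(w)
    stat = morans_i(x, W)
    rng = np.random.default_rng(seed)
    null = _null_morans(x - x.mean(), W, B, rng)
    p = _permutation_pvalue(stat, null, tail)
    kind = w.kind if isinstance(w, WeightMatrix) else "custom"
    return PermutationTestResult(stat, null, p, tail, B, seed, kind)


def abouheif_test(x: np.ndarray, tree: Phylogeny, B: int = 999, seed: int = 0,
                  tail: str = "upper") -> PermutationTestResult:
    """Abouheif's test: Moran's I on row-normalized Abouheif proximities."""
    w = normalize_weights(abouheif_proximity(tree), "row_normalized")
    return signal_test(x, w, B=B, seed=seed, tail=tail)


def _kendalls_w(ranks: np.ndarray) -> float:
    """Kendall's W of an m x K midrank array (m judges, K objects), with the
    standard tie correction."""
    m, K = ranks.shape
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    T = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        T += float((counts**3 - counts).sum())
    denom = m**2 * (K**3 - K) - m * T
    if denom <= 0:
        raise ValueError("degenerate ranks: all values tied in every matrix")
    return 12.0 * S / denom


def cadm_concordance(matrices: list[WeightMatrix], B: int = 999,
                     seed: int = 0) -> PermutationTestResult:
    """Congruence among distance matrices via Kendall's W of concordance.

    The m matrices' upper triangles are midranked and treated as m judges
    ranking the same n(n-1)/2 species pairs.  The null permutes the species
    labels of all matrices but the first, independently, upper-tailed on W.
    W = 1 means perfect rank agreement; under independence E[W] ~ 1/m.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    labels = matrices[0].labels
    n = len(labels)
    if n < 4:
        raise ValueError(f"need at least 4 species, got {n}")
    for w in matrices[1:]:
        if w.labels != labels:
            raise ValueError("matrices must share the same labels and order")
    iu = np.triu_indices(n, k=1)

    def ranks_of(mats: list[np.ndarray]) -> np.ndarray:
        return np.vstack([rankdata(M[iu]) for M in mats])

    values = [w.values for w in matrices]
    stat = _kendalls_w(ranks_of(values))
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        permuted = [values[0]]
        for M in values[1:]:
            idx = rng.permutation(n)
            permuted.append(M[np.ix_(idx, idx)])
        null[b] = _kendalls_w(ranks_of(permuted))
    p = _permutation_pvalue(stat, null, "upper")
    return PermutationTestResult(stat, null, p, "upper", B, seed,
                                 matrices[0].kind)
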
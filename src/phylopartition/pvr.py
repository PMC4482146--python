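"""Phylogenetic eigenvector regression (PVR) and variance partitioning.

The patristic distance matrix is Gower double-centered
(``G = -1/2 C D^(2) C``) and eigendecomposed; the leading eigenvectors
describe contrasts between deep clades, later ones structure near the tips.
A greedy forward search selects eigenvectors that minimize the absolute
residual Moran's I of a response, stopping once a permutation test finds no
significant residual autocorrelation.  A partial-regression decomposition
then splits each response's variance into four fractions:

    traits alone   = R2(traits + phylo) - R2(phylo)
    phylogeny alone = R2(traits + phylo) - R2(traits)
    shared          = R2(traits) + R2(phylo) - R2(traits + phylo)
    unexplained     = 1 - R2(traits + phylo)

which sum to one by construction.  The ``shared`` fraction can be slightly
negative (a suppression pattern); anything below -1e-6 is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import morans_i, signal_test
from .trees import Phylogeny, WeightMatrix, normalize_weights, patristic_distances

__all__ = [
    "EigenBasis",
    "VariancePartition",
    "gower_center",
    "extract_eigenvectors",
    "select_eigenvectors",
    "partition_variance",
    "inverse_distance_weights",
    "PhyloEigenvectorRegression",
    "PVRResults",
]


@dataclass(frozen=True)
class EigenBasis:
    """Eigenvectors of the double-centered phylogenetic distance matrix."""

    labels: tuple[str, ...]
    eigenvalues: np.ndarray  # descending, only values > tol * max kept
    vectors: np.ndarray      # n x k, orthonormal columns

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


@dataclass
class VariancePartition:
    """Four-way split of one response's variance (a Table-1-style row)."""

    response: str
    traits_alone: float
    shared: float
    phylo_alone: float
    unexplained: float
    selected_eigenvectors: list[int]

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "traits_alone": self.traits_alone,
            "shared": self.shared,
            "phylo_alone": self.phylo_alone,
            "unexplained": self.unexplained,
            "selected_eigenvectors": ";".join(map(str, self.selected_eigenvectors)),
        }


def gower_center(d: WeightMatrix, squared: bool = True) -> np.ndarray:
    """Gower double centering of a distance matrix.

    ``G = -1/2 C A C`` with ``C = I - 11'/n`` and ``A`` the elementwise
    squared distances (``squared=False`` centers the raw distances, an
    alternative convention).  Rows and columns of G sum to zero.
    """
    D = d.values if isinstance(d, WeightMatrix) else np.asarray(d, dtype=float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    A = D**2 if squared else D.copy()
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * (C @ A @ C)


def extract_eigenvectors(g: np.ndarray,
                         labels: tuple[str, ...] | None = None,
                         tol: float = 1e-8) -> EigenBasis:
    """Eigendecompose a (symmetric) Gower matrix into an ordered basis.

    Eigenpairs are sorted by descending eigenvalue and only those above
    ``tol * max`` are kept (the centering always produces at least one zero).
    Sign convention: the first nonzero loading of each vector is positive.
    """
    g = np.asarray(g, dtype=float)
    if not np.allclose(g, g.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(vals.max(), 0.0)
    vals, vecs = vals[keep], vecs[:, keep]
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        lead = col[np.flatnonzero(np.abs(col) > 1e-12)[0]]
        if lead < 0:
            vecs[:, j] = -col
    if labels is None:
        labels = tuple(str(i) for i in range(g.shape[0]))
    return EigenBasis(tuple(labels), vals, vecs)


def inverse_distance_weights(d: WeightMatrix) -> WeightMatrix:
    """Row-normalized 1/d_ij proximity (zero diagonal) from distances.

    The default weight matrix for judging residual autocorrelation during
    eigenvector selection.
    """
    D = d.values
    with np.errstate(divide="ignore"):
        P = np.where(D > 0, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(P, 0.0)
    w = WeightMatrix(d.labels, P, kind="inverse_distance")
    return normalize_weights(w, "row_normalized")


def _ols_residuals(y: np.ndarray, X: np.ndarray,
                   allow_rank_deficient: bool = False) -> np.ndarray:
    """Residuals of y on [1, X].

    Eigenvector selections must be full rank (collinearity there is a bug);
    trait blocks may be aliased by design — e.g. a log interaction column is
    exactly the sum of the two log main effects — in which case the
    projection (and hence R^2) is still well-defined.
    """
    n = y.size
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1] and not allow_rank_deficient:
        raise ValueError("collinear predictors in eigenvector regression")
    return y - Z @ beta


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Ordinary R^2 of y on [1, X]; 0 for an empty predictor set."""
    y = np.asarray(y, dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("constant response")
    if X.size == 0:
        return 0.0
    resid = _ols_residuals(y, X, allow_rank_deficient=True)
    return 1.0 - float((resid**2).sum()) / tss


def select_eigenvectors(y: np.ndarray, basis: EigenBasis, w: WeightMatrix,
                        alpha: float = 0.05, B: int = 999,
                        seed: int = 0) -> list[int]:
    """Greedy forward selection minimizing absolute residual Moran's I.

    Start from the empty set; at each step add the candidate eigenvector
    whose inclusion most reduces |I| of the regression residuals against
    ``w``.  Stop when the residual-signal permutation test is nonsignificant
    at ``alpha``, when no candidate reduces |I|, or at ``n - 3`` vectors.
    Ties go to the lower index (coarser phylogenetic scale first).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    V = basis.vectors
    if V.shape[1] == 0:
        raise ValueError("empty eigenvector basis")
    selected: list[int] = []
    step = 0
    while True:
        resid = _ols_residuals(y, V[:, selected])
        if resid.std() <= 1e-12 * max(1.0, y.std()):
            break  # perfect fit; nothing left to explain
        if alpha >= 1.0:  # nothing can be significant; keep no vectors
            break
        test = signal_test(resid, w, B=B, seed=seed + step, tail="two_sided")
        if test.p_value > alpha:
            break
        if len(selected) >= n - 3:
            break
        current = abs(morans_i(resid, w))
        best_j, best_abs = None, current
        for j in range(V.shape[1]):
            if j in selected:
                continue
            try:
                r = _ols_residuals(y, V[:, selected + [j]])
            except ValueError:
                continue
            if r.std() <= 1e-12 * max(1.0, y.std()):
                cand = 0.0
            else:
                cand = abs(morans_i(r, w))
            if cand < best_abs - 1e-12:
                best_j, best_abs = j, cand
        if best_j is None:
            break
        selected.append(best_j)
        step += 1
    return selected


def partition_variance(y: np.ndarray, X_traits: np.ndarray,
                       basis_selected: np.ndarray,
                       response: str = "response") -> VariancePartition:
    """Partial-regression variance partition of one response.

    ``basis_selected`` holds the selected eigenvectors as columns (possibly
    zero columns).  The four fractions sum to one.
    """
    y = np.asarray(y, dtype=float)
    X_traits = np.atleast_2d(np.asarray(X_traits, dtype=float))
    if X_traits.shape[0] != y.size:
        X_traits = X_traits.T
    E = np.asarray(basis_selected, dtype=float)
    if E.ndim == 1:
        E = E[:, None]
    if E.size == 0:
        E = np.empty((y.size, 0))
    p_combined = X_traits.shape[1] + E.shape[1]
    if p_combined >= y.size:
        raise ValueError(
            f"saturated model: {p_combined} predictors for n={y.size}"
        )
    r2_t = _r2(y, X_traits)
    r2_p = _r2(y, E)
    r2_tp = _r2(y, np.column_stack([X_traits, E]) if E.shape[1] else X_traits)
    part = VariancePartition(
        response=response,
        traits_alone=r2_tp - r2_p,
        shared=r2_t + r2_p - r2_tp,
        phylo_alone=r2_tp - r2_t,
        unexplained=1.0 - r2_tp,
        selected_eigenvectors=[],
    )
    if part.shared < -1e-6:
        import warnings
        warnings.warn(
            f"negative shared fraction ({part.shared:.4g}) for {response}: "
            "suppression between traits and phylogeny", stacklevel=2)
    return part


class PhyloEigenvectorRegression:
    """PVR variance partitioning of responses between traits and phylogeny.

    Parameters
    ----------
    responses : DataFrame
        Species x response table (e.g. the four foraging investments).
    traits : DataFrame
        Species x trait design matrix.
    tree : Phylogeny
        Source of the patristic distance matrix.
    squared_distances : bool
        Square distances inside the Gower centering (the principal-
        coordinates convention; default) or center raw distances.
    residual_weights : {"inverse_distance", "abouheif"}
        Weight matrix for the residual Moran's I used in selection.
    """

    def __init__(self, responses: pd.DataFrame, traits: pd.DataFrame,
                 tree: Phylogeny, *, squared_distances: bool = True,
                 residual_weights: str = "inverse_distance",
                 alpha: float = 0.05, B: int = 999, seed: int = 0):
        order = tree.tips
        missing = (set(order) ^ set(responses.index)) | (set(order) ^ set(traits.index))
        if missing:
            raise ValueError(f"species mismatch: {sorted(missing)}")
        self.responses = responses.loc[order]
        self.traits = traits.loc[order]
        self.tree = tree
        self.alpha, self.B, self.seed = alpha, B, seed
        self.distances = patristic_distances(tree)
        self.gower = gower_center(self.distances, squared=squared_distances)
        self.basis = extract_eigenvectors(self.gower, tuple(order))
        if residual_weights == "abouheif":
            from .trees import abouheif_proximity
            self.residual_w = normalize_weights(abouheif_proximity(tree),
                                                "row_normalized")
        elif residual_weights == "inverse_distance":
            self.residual_w = inverse_distance_weights(self.distances)
        else:
            raise ValueError(f"unknown residual_weights {residual_weights!r}")

    def fit(self) -> "PVRResults":
        X = self.traits.to_numpy(dtype=float)
        parts = []
        for name in self.responses.columns:
            y = self.responses[name].to_numpy(dtype=float)
            sel = select_eigenvectors(y, self.basis, self.residual_w,
                                      alpha=self.alpha, B=self.B,
                                      seed=self.seed)
            part = partition_variance(y, X, self.basis.vectors[:, sel],
                                      response=name)
            part.selected_eigenvectors = sorted(sel)
            parts.append(part)
        return PVRResults(self, parts)


class PVRResults:
    """Fitted variance partitions, one per response."""

    def __init__(self, model: PhyloEigenvectorRegression,
                 partitions: list[VariancePartition]):
        self.model = model
        self.partitions = partitions

    def summary(self) -> pd.DataFrame:
        """Table-1-shaped frame: response x four fractions + selection."""
        return pd.DataFrame([p.as_dict() for p in self.partitions]
                            ).set_index("response")

    def to_csv(self, path) -> None:
        self.summary().to_csv(path)
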
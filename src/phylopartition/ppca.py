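"""Phylogenetic principal component analysis with global and local axes.

Ordinary PCA maximizes score variance; phylogenetic PCA maximizes the
product of score variance and phylogenetic autocorrelation.  With X the
species x trait matrix (columns standardized to mean 0, variance 1 with
divisor n) and W_s a symmetrized row-normalized phylogenetic proximity
matrix, the decomposition is of

    H = (1/n) X' W_s X.

Because W_s has total weight n, every axis satisfies the defining identity

    eigenvalue = var_n(score) * MoranI(score)

so large positive eigenvalues are "global" axes — high-variance trait
combinations that are positively autocorrelated across deep clades — and
negative eigenvalues are "local" axes, trait combinations that differ
between close relatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import PermutationTestResult, abouheif_test, morans_i
from .trees import Phylogeny, WeightMatrix, abouheif_proximity, normalize_weights

__all__ = ["PhyloPCA", "PhyloPCAResults", "fit_ppca", "default_ppca_weights"]


def default_ppca_weights(tree: Phylogeny) -> WeightMatrix:
    """Symmetrized row-normalized Abouheif proximity (the analysis default)."""
    return normalize_weights(abouheif_proximity(tree),
                             "symmetrized_row_normalized")


class PhyloPCA:
    """Phylogenetic PCA model over a standardized trait matrix.

    Parameters
    ----------
    traits_std : DataFrame
        Species x trait matrix, each column mean 0 and variance 1
        (divisor n); see :func:`phylopartition.traits.standardize`.
    weights : WeightMatrix
        Phylogenetic proximity aligned to the species; pass an identity
        matrix to recover ordinary PCA of the correlation matrix.
    """

    def __init__(self, traits_std: pd.DataFrame, weights: WeightMatrix):
        if list(traits_std.index) != list(weights.labels):
            if set(traits_std.index) != set(weights.labels):
                raise ValueError("species labels of traits and weights differ")
            traits_std = traits_std.loc[list(weights.labels)]
        X = traits_std.to_numpy(dtype=float)
        n = X.shape[0]
        if not np.allclose(X.mean(axis=0), 0.0, atol=1e-8):
            raise ValueError("traits must be centered (column means 0)")
        var_n = (X**2).mean(axis=0)
        if not np.allclose(var_n, 1.0, atol=1e-6):
            raise ValueError(
                "traits must be standardized to variance 1 (divisor n)"
            )
        self.traits = traits_std
        self.weights = weights
        self._X = X
        self._n = n

    def fit(self) -> "PhyloPCAResults":
        X, n = self._X, self._n
        Ws = 0.5 * (self.weights.values + self.weights.values.T)
        H = X.T @ Ws @ X / n
        vals, vecs = np.linalg.eigh(H)
        tol = 1e-10 * max(np.abs(vals).max(), 1.0)
        neg = vals < -tol
        pos_idx = np.flatnonzero(~neg)
        neg_idx = np.flatnonzero(neg)
        pos_order = pos_idx[np.argsort(vals[pos_idx])[::-1]]   # descending
        neg_order = neg_idx[np.argsort(vals[neg_idx])]         # most negative first
        order = np.concatenate([pos_order, neg_order]).astype(int)
        vals, vecs = vals[order], vecs[:, order]
        # deterministic orientation: largest-|loading| trait positive per axis
        for j in range(vecs.shape[1]):
            lead = np.argmax(np.abs(vecs[:, j]))
            if vecs[lead, j] < 0:
                vecs[:, j] = -vecs[:, j]
        labels = ([f"global_{i + 1}" for i in range(len(pos_order))]
                  + [f"local_{i + 1}" for i in range(len(neg_order))])
        scores = X @ vecs
        return PhyloPCAResults(self, vals, vecs, scores, labels)


class PhyloPCAResults:
    """Eigenvalues, loadings and tip scores of a fitted phylogenetic PCA."""

    def __init__(self, model: PhyloPCA, eigenvalues: np.ndarray,
                 loadings: np.ndarray, scores: np.ndarray,
                 axis_labels: list[str]):
        self.model = model
        self.eigenvalues = eigenvalues
        self.axis_labels = list(axis_labels)
        self.loadings = pd.DataFrame(loadings, index=model.traits.columns,
                                     columns=self.axis_labels)
        self.scores = pd.DataFrame(scores, index=model.traits.index,
                                   columns=self.axis_labels)

    # -- variance accounting ------------------------------------------------

    @property
    def variance_share(self) -> pd.Series:
        """Per-axis |eigenvalue| / sum of |eigenvalues|."""
        a = np.abs(self.eigenvalues)
        return pd.Series(a / a.sum(), index=self.axis_labels)

    @property
    def variance_share_of_total(self) -> pd.Series:
        """Per-axis |eigenvalue| / total trait variance (= number of traits).

        The companion convention; both are reported because variance shares
        of a signed spectrum are quoted inconsistently in the literature.
        """
        p = self.loadings.shape[0]
        return pd.Series(np.abs(self.eigenvalues) / p, index=self.axis_labels)

    def axis_identity_residuals(self) -> pd.Series:
        """Per-axis |eigenvalue - var_n(score) * I(score)| (should be ~0)."""
        Ws = 0.5 * (self.model.weights.values + self.model.weights.values.T)
        out = {}
        for lam, axis in zip(self.eigenvalues, self.axis_labels):
            s = self.scores[axis].to_numpy()
            if s.std() <= 1e-12:
                out[axis] = abs(lam)
                continue
            out[axis] = abs(lam - (s**2).mean() * morans_i(s, Ws))
        return pd.Series(out)

    # -- retention and signal -----------------------------------------------

    def retain(self, k_global: int, k_local: int) -> "PhyloPCAResults":
        """Keep the k_global largest-positive and k_local most-negative axes."""
        n_global = sum(l.startswith("global") for l in self.axis_labels)
        n_local = len(self.axis_labels) - n_global
        if k_global > n_global or k_local > n_local:
            raise ValueError(
                f"requested {k_global} global / {k_local} local axes but only "
                f"{n_global} global / {n_local} local exist"
            )
        keep = ([f"global_{i + 1}" for i in range(k_global)]
                + [f"local_{i + 1}" for i in range(k_local)])
        idx = [self.axis_labels.index(a) for a in keep]
        out = PhyloPCAResults(self.model, self.eigenvalues[idx],
                              self.loadings.iloc[:, idx].to_numpy(),
                              self.scores.iloc[:, idx].to_numpy(), keep)
        out._parent_abs_sum = float(np.abs(self.eigenvalues).sum())
        return out

    @property
    def retained_variance_share(self) -> float:
        """Sum |retained eigenvalues| / sum |all eigenvalues| of the parent fit."""
        total = getattr(self, "_parent_abs_sum",
                        float(np.abs(self.eigenvalues).sum()))
        return float(np.abs(self.eigenvalues).sum() / total)

    def score_signal(self, tree: Phylogeny, B: int = 999,
                     seed: int = 0) -> dict[str, PermutationTestResult]:
        """Abouheif's test per axis: upper-tailed for global, lower for local."""
        out = {}
        for i, axis in enumerate(self.axis_labels):
            tail = "upper" if axis.startswith("global") else "lower"
            out[axis] = abouheif_test(self.scores[axis].to_numpy(), tree,
                                      B=B, seed=seed + i, tail=tail)
        return out

    def dominant_loadings(self, q: float = 0.75) -> dict[str, list[str]]:
        """Traits whose |loading| exceeds the q-quantile cutoff, per axis."""
        out = {}
        for axis in self.axis_labels:
            a = self.loadings[axis].abs()
            cutoff = a.quantile(q)
            out[axis] = list(a.index[a > cutoff])
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues,
            "variance_share": self.variance_share.to_numpy(),
            "variance_share_of_total": self.variance_share_of_total.to_numpy(),
        }, index=self.axis_labels)


def fit_ppca(traits_std: pd.DataFrame, w: WeightMatrix) -> PhyloPCAResults:
    """Functional wrapper: ``PhyloPCA(traits_std, w).fit()``."""
    return PhyloPCA(traits_std, w).fit()
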
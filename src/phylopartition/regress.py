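"""Regression inference for the foraging-behavior analyses.

Residual diagnostics in this design (n = 23 species means) rarely support
normal-theory p-values, so the multiple regressions of behaviors on pPCA
axes use permutation inference: the response is shuffled B times and each
coefficient's two-sided p-value is the add-one tail fraction of |t*| >= |t|.
A log-link Poisson regression (IRLS) covers the conspecific-interference
counts, and a classical paired t-test compares handling times with and
without interference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OLSFit",
    "fit_ols",
    "PermutationOLS",
    "PermutationOLSResults",
    "permutation_inference",
    "fit_poisson",
    "PairedTResult",
    "paired_t",
]


@dataclass
class OLSFit:
    """Least-squares fit with classical t statistics and ordinary R^2."""

    coefficients: pd.Series
    t_statistics: pd.Series
    R2: float
    residuals: np.ndarray
    fitted: np.ndarray


def _design(X, add_intercept: bool):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = [f"x{j + 1}" for j in range(X.shape[1])]
    if isinstance(X, np.ndarray):
        pass
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    return X, names


def fit_ols(y, X, add_intercept: bool = True,
            names: list[str] | None = None) -> OLSFit:
    """OLS with intercept; errors on rank deficiency or saturated designs."""
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = ["intercept"] + list(X.columns) if add_intercept else list(X.columns)
        Xv = X.to_numpy(dtype=float)
        Z, _ = _design(Xv, add_intercept)
    else:
        Z, default = _design(X, add_intercept)
        if names is None:
            names = default
        elif add_intercept:
            names = ["intercept"] + list(names)
    n, k = Z.shape
    if n <= k:
        raise ValueError(f"need n > p + 1; got n={n}, {k} coefficients")
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < k:
        raise ValueError("rank-deficient design matrix")
    fitted = Z @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    sigma2 = rss / (n - k)
    XtX_inv = np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("constant response")
    r2 = 1.0 - rss / tss
    return OLSFit(pd.Series(beta, index=names), pd.Series(t, index=names),
                  r2, resid, fitted)


@dataclass
class PermutationOLSResults:
    """Coefficients, classical t, permutation p-values and R^2."""

    response: str
    coefficients: pd.Series
    t_statistics: pd.Series
    perm_p: pd.Series
    R2: float
    B: int
    seed: int

    def summary(self) -> pd.DataFrame:
        """Table with one row per predictor: slope, t, permutation p."""
        return pd.DataFrame({
            "slope": self.coefficients,
            "t_statistic": self.t_statistics,
            "p_value": self.perm_p,
        })


class PermutationOLS:
    """Multiple regression with permutation inference on the coefficients.

    The observed fit is the ordinary least-squares fit; only the p-values
    come from permutations of the response vector (the raw-data scheme; a
    residual-permutation Freedman-Lane variant is available via
    ``scheme="freedman_lane"``).
    """

    def __init__(self, y, X, response: str = "response",
                 add_intercept: bool = True, scheme: str = "response"):
        self.y = np.asarray(y, dtype=float)
        if isinstance(X, pd.DataFrame):
            self._names = ["intercept"] + list(X.columns) if add_intercept \
                else list(X.columns)
            Z, _ = _design(X.to_numpy(dtype=float), add_intercept)
        else:
            Z, self._names = _design(X, add_intercept)
        self.Z = Z
        self.response = response
        if scheme not in ("response", "freedman_lane"):
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        self.scheme = scheme

    def fit(self, B: int = 999, seed: int = 0) -> PermutationOLSResults:
        if B < 99:
            raise ValueError(f"B must be at least 99, got {B}")
        y, Z = self.y, self.Z
        n, k = Z.shape
        obs = fit_ols(y, Z, add_intercept=False, names=self._names)
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((B, n)), axis=1)
        if self.scheme == "response":
            Yp = y[idx]  # B x n permuted responses
        else:  # Freedman-Lane under the full null: permute residuals of y ~ 1
            mu = y.mean()
            Yp = mu + (y - mu)[idx]
        pinv = np.linalg.pinv(Z)  # k x n
        Beta = Yp @ pinv.T  # B x k
        fitted = Beta @ Z.T  # B x n
        rss = ((Yp - fitted) ** 2).sum(axis=1)
        sigma2 = rss / (n - k)
        diag = np.diag(np.linalg.inv(Z.T @ Z))
        se = np.sqrt(np.maximum(sigma2[:, None] * diag[None, :], 1e-300))
        T = Beta / se
        t_obs = obs.t_statistics.to_numpy()
        count = (np.abs(T) >= np.abs(t_obs)[None, :]).sum(axis=0)
        p = (1 + count) / (B + 1)
        return PermutationOLSResults(
            self.response, obs.coefficients, obs.t_statistics,
            pd.Series(p, index=self._names), obs.R2, B, seed,
        )


def permutation_inference(y, X, B: int = 999, seed: int = 0,
                          response: str = "response") -> PermutationOLSResults:
    """Functional wrapper: ``PermutationOLS(y, X, response).fit(B, seed)``."""
    return PermutationOLS(y, X, response=response).fit(B=B, seed=seed)


def fit_poisson(counts, X=None, add_intercept: bool = True, tol: float = 1e-8,
                max_iter: int = 100, return_deviance_path: bool = False):
    """Log-link Poisson regression by iteratively reweighted least squares.

    ``X=None`` fits the intercept-only model (MLE = log mean).  Convergence
    is declared when ``max |delta beta| < tol``; failure to converge in
    ``max_iter`` iterations raises with the iteration trace.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        counts = np.round(counts).astype(int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative integers")
    y = counts.astype(float)
    n = y.size
    if X is None:
        Z, names = np.ones((n, 1)), ["intercept"]
    elif isinstance(X, pd.DataFrame):
        names = ["intercept"] + list(X.columns) if add_intercept else list(X.columns)
        Z, _ = _design(X.to_numpy(dtype=float), add_intercept)
    else:
        Z, names = _design(X, add_intercept)
    if n <= Z.shape[1]:
        raise ValueError("need n > p + 1 for Poisson regression")
    if y.sum() == 0:
        raise ValueError("all counts are zero: Poisson MLE diverges to -inf")
    beta = np.zeros(Z.shape[1])
    beta[0] = np.log(y.mean()) if add_intercept or X is None else 0.0
    trace = []
    deviances = []
    for _ in range(max_iter):
        eta = Z @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu
        z = eta + (y - mu) / mu
        WZ = Z * W[:, None]
        try:
            new = np.linalg.solve(Z.T @ WZ, WZ.T @ z)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular IRLS system: {exc}") from exc
        delta = float(np.max(np.abs(new - beta)))
        trace.append(delta)
        beta = new
        deviances.append(_poisson_deviance_at(y, Z, beta))
        if delta < tol:
            coefs = pd.Series(beta, index=names)
            return (coefs, deviances) if return_deviance_path else coefs
    raise ValueError(
        f"Poisson IRLS did not converge in {max_iter} iterations; "
        f"|delta beta| trace tail: {trace[-5:]}"
    )


def _poisson_deviance_at(y: np.ndarray, Z: np.ndarray,
                         beta: np.ndarray) -> float:
    mu = np.exp(np.clip(Z @ beta, -30, 30))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float((term - (y - mu)).sum())


def poisson_deviance(counts, X, beta, add_intercept: bool = True) -> float:
    """Poisson deviance at given coefficients (diagnostic helper)."""
    y = np.asarray(counts, dtype=float)
    if X is None:
        Z = np.ones((y.size, 1))
    elif isinstance(X, pd.DataFrame):
        Z, _ = _design(X.to_numpy(dtype=float), add_intercept)
    else:
        Z, _ = _design(X, add_intercept)
    mu = np.exp(Z @ np.asarray(beta, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float((term - (y - mu)).sum())


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float


def paired_t(a, b) -> PairedTResult:
    """Classical paired t-test on the differences a - b (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero-variance differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedTResult(float(t), n - 1, p)
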
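"""Synthetic trees, traits and behaviors with known statistical structure.

The generator mirrors the study design it is meant to exercise: an
ultrametric phylogeny of ~23 hardwood-like species with nested clades,
traits evolved with a tunable amount of phylogenetic signal, and four
behavioral responses that are linear functions of latent trait axes plus
noise, with per-species Poisson interference counts.

Trees come from a pure-birth (Yule) process.  Traits are multivariate
normal with covariance ``sigma2 * V(lambda)``, where ``V`` holds shared
root-to-MRCA path lengths; the off-diagonal attenuation by ``lambda``
(diagonal untouched) is the standard Pagel construction — ``lambda = 1`` is
pure Brownian motion, ``lambda = 0`` independent tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "simulate_traits",
    "simulate_behaviors",
    "paperlike_dataset",
    "BEHAVIOR_COLUMNS",
]

BEHAVIOR_COLUMNS = [
    "time_to_consume_min",
    "distance_to_consume_m",
    "time_to_cache_min",
    "distance_to_cache_m",
]


@dataclass
class SimConfig:
    """Knobs of the synthetic study; the defaults are the study conditions.

    ``n_tips=23`` species, 11 traits, 4 behaviors, B-type effect sizes on
    the first/second global and first local trait axes, trial-scale noise,
    and an interference rate matching roughly 14 interference trials over
    23 species.
    """

    n_tips: int = 23
    birth_rate: float = 1.0
    sigma2: float = 1.0
    lam: float = 1.0
    n_traits: int = 11
    beta: np.ndarray = field(
        default_factory=lambda: np.array([-3.0, 0.0, 3.0]))
    noise_sd: float = 1.0
    interference_rate: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.sigma2 <= 0 or self.birth_rate <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd < 0 or self.interference_rate < 0:
            raise ValueError("noise_sd and interference_rate must be >= 0")


class _Lineage:
    __slots__ = ("name", "birth", "children", "length")

    def __init__(self, birth: float):
        self.name = None
        self.birth = birth
        self.children = []
        self.length = 0.0

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       label_prefix: str = "t") -> Phylogeny:
    """Simulate an ultrametric pure-birth tree with exactly ``n_tips`` tips.

    Waiting times between splits are exponential with rate
    ``k * birth_rate`` for ``k`` extant lineages; a final waiting interval
    is appended after the last split so tips never sit at a node.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if rng is None:
        rng = np.random.default_rng(seed)
    root = _Lineage(0.0)
    active = [_Lineage(0.0), _Lineage(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        parent = active.pop(i)
        parent.length = t - parent.birth
        kids = [_Lineage(t), _Lineage(t)]
        parent.children = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    width = len(str(n_tips))
    counter = 0
    # name tips in tree traversal order for stable labels
    stack = [root]
    while stack:
        node = stack.pop()
        if node.children:
            stack.extend(reversed(node.children))
        else:
            counter += 1
            node.name = f"{label_prefix}{counter:0{width}d}"
            node.length = t - node.birth
    return Phylogeny.from_newick_string(root.newick().rsplit(":", 1)[0] + ";")


def simulate_traits(tree: Phylogeny, sigma2: float = 1.0,
                    lam: float | np.ndarray = 1.0, p: int = 1,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    names: list[str] | None = None) -> pd.DataFrame:
    """Evolve ``p`` independent traits on the tree with signal ``lam``.

    Each column is drawn from ``N(0, sigma2 * V(lam))`` with ``V(lam)``
    the shared-path-length matrix whose off-diagonals are scaled by the
    column's lambda.  A scalar ``lam`` applies to all columns; a vector
    gives per-trait signal strengths.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    V = tree.shared_path_lengths().values
    n = V.shape[0]
    lams = np.broadcast_to(np.asarray(lam, dtype=float), (p,))
    if ((lams < 0) | (lams > 1)).any():
        raise ValueError("lambda must be in [0, 1]")
    cols = np.empty((n, p))
    chol_cache: dict[float, np.ndarray] = {}
    for j, l in enumerate(lams):
        key = float(l)
        if key not in chol_cache:
            Vl = l * V
            np.fill_diagonal(Vl, np.diag(V))
            Vl = sigma2 * Vl
            try:
                L = np.linalg.cholesky(Vl)
            except np.linalg.LinAlgError:
                import warnings
                warnings.warn("trait covariance not positive definite; "
                              "jittering diagonal by 1e-10", stacklevel=2)
                L = np.linalg.cholesky(Vl + 1e-10 * np.eye(n))
            chol_cache[key] = L
        cols[:, j] = chol_cache[key] @ rng.standard_normal(n)
    if names is None:
        names = [f"trait_{j + 1}" for j in range(p)]
    return pd.DataFrame(cols, index=tree.tips, columns=names)


def simulate_behaviors(axis_scores: pd.DataFrame,
                       beta: np.ndarray,
                       noise_sd: float = 1.0,
                       interference_rate: float = 0.6,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       names: list[str] | None = None,
                       intercepts: np.ndarray | None = None,
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Linear behaviors from latent axis scores, plus interference counts.

    ``beta`` is either a vector (one behavior) or a behaviors x axes matrix;
    each behavior is ``intercept + scores @ beta_row + N(0, noise_sd)``.
    Interference counts are Poisson(``interference_rate``) per species,
    independent of the axes (the null the post-hoc analysis probes).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    S = axis_scores.to_numpy(dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("axis scores must be finite")
    B = np.atleast_2d(np.asarray(beta, dtype=float))
    if B.shape[1] != S.shape[1]:
        raise ValueError(
            f"beta has {B.shape[1]} columns for {S.shape[1]} axes")
    n, m = S.shape[0], B.shape[0]
    if names is None:
        names = (BEHAVIOR_COLUMNS[:m] if m <= len(BEHAVIOR_COLUMNS)
                 else [f"behavior_{i + 1}" for i in range(m)])
    if intercepts is None:
        intercepts = np.zeros(m)
    Y = (intercepts[None, :] + S @ B.T
         + noise_sd * rng.standard_normal((n, m)))
    behaviors = pd.DataFrame(Y, index=axis_scores.index, columns=names)
    counts = pd.Series(rng.poisson(interference_rate, size=n),
                       index=axis_scores.index, name="interference_trials")
    return behaviors, counts


def _nested_clade_tree(rng: np.random.Generator, sizes=(8, 10, 5),
                       birth_rate: float = 1.0) -> Phylogeny:
    """23-tip ultrametric tree with three nested clades (family-like),
    shaped ((A, B), C) with clade depth 0.6 and total depth 1.0."""
    prefixes = ["fagA_", "juglB_", "betuC_"][: len(sizes)]
    subtrees = []
    for size, prefix in zip(sizes, prefixes):
        sub = simulate_yule_tree(size, birth_rate, rng=rng,
                                 label_prefix=prefix)
        depth = sub.tip_depths().iloc[0]
        subtrees.append(_rescale_newick(sub.to_newick(), 0.6 / depth))
    a, b, c = subtrees
    newick = f"(({a}:0.1,{b}:0.1):0.3,{c}:0.4);"
    return Phylogeny.from_newick_string(newick)


def _rescale_newick(newick: str, factor: float) -> str:
    """Multiply every branch length in a newick fragment by ``factor``;
    returns the fragment without the trailing semicolon or root length."""
    import re

    body = newick.strip().rstrip(";")

    def sub(match):
        return f":{float(match.group(1)) * factor:.10g}"

    return re.sub(r":([0-9.eE+-]+)", sub, body)


_PAPERLIKE_LAMBDA = {
    # strong family/genus-level signal in nutrition and shell traits,
    # signal-free kernel mass and tannins (the study's observed pattern)
    "lipid_pct": 1.0, "carbohydrate_pct": 1.0, "protein_pct": 1.0,
    "caloric_cal_per_g": 1.0, "dormancy_days": 1.0, "hardness_kg": 1.0,
    "thickness_um": 1.0, "shell_mass_g": 1.0,
    "kernel_mass_g": 0.0, "tannin_pct_tae": 0.0, "moisture_pct": 0.0,
}

#: behaviors x (global_1, global_2, local_1) effect sizes: the first and
#: third axes drive everything, the second axis only consumption time
_PAPERLIKE_BETA = np.array([
    [-3.0, 2.0, 3.0],    # time to consume
    [-1.0, 0.0, 2.5],    # distance to consume
    [-0.5, 0.0, 1.0],    # time to cache
    [-5.0, 0.0, 8.0],    # distance to cache
])
_PAPERLIKE_INTERCEPTS = np.array([9.0, 6.0, 2.0, 26.0])


def paperlike_dataset(seed: int, noise_sd: float = 1.0,
                      interference_rate: float = 0.6,
                      n_zero_tannin: int = 3) -> dict:
    """The full synthetic study: tree, raw trait table, behaviors, counts.

    23 species in three nested clades (8/10/5), 11 raw traits on natural
    scales (percentages, masses, etc.) with mixed phylogenetic signal,
    behaviors driven by the first/second global and first local axes of a
    phylogenetic PCA of the prepared traits, and Poisson interference
    counts.  Returns a dict with keys ``tree``, ``traits``, ``behaviors``,
    ``interference``, ``scores``, ``beta``, ``config``.
    """
    from .ppca import PhyloPCA, default_ppca_weights
    from .traits import apply_floors, build_design_matrix, standardize

    rng = np.random.default_rng(seed)
    tree = _nested_clade_tree(rng)
    cols = list(_PAPERLIKE_LAMBDA)
    lams = np.array([_PAPERLIKE_LAMBDA[c] for c in cols])
    g = simulate_traits(tree, sigma2=1.0, lam=lams, p=len(cols), rng=rng,
                        names=cols)
    traits = pd.DataFrame(index=tree.tips)
    traits["lipid_pct"] = 100.0 / (1.0 + np.exp(-g["lipid_pct"] / 2.0))
    traits["carbohydrate_pct"] = 100.0 / (1.0 + np.exp(-g["carbohydrate_pct"] / 2.0))
    traits["protein_pct"] = 100.0 / (1.0 + np.exp(-(g["protein_pct"] / 2.0 + 1.0)))
    traits["caloric_cal_per_g"] = 4500.0 + 600.0 * g["caloric_cal_per_g"]
    traits["dormancy_days"] = 60.0 * np.exp(0.5 * g["dormancy_days"])
    traits["hardness_kg"] = 20.0 * np.exp(0.6 * g["hardness_kg"])
    traits["thickness_um"] = 400.0 * np.exp(0.5 * g["thickness_um"])
    traits["kernel_mass_g"] = 1.5 * np.exp(0.8 * g["kernel_mass_g"])
    traits["shell_mass_g"] = 2.0 * np.exp(0.8 * g["shell_mass_g"])
    tannin = 1.2 * np.exp(0.8 * g["tannin_pct_tae"])
    # emulate tannin-free species: zero out the lowest assays
    floor_idx = tannin.nsmallest(n_zero_tannin).index
    tannin.loc[floor_idx] = 0.0
    traits["tannin_pct_tae"] = tannin
    traits["moisture_pct"] = 100.0 / (1.0 + np.exp(-(g["moisture_pct"] / 2.0 - 1.0)))

    design = build_design_matrix(apply_floors(traits, "tannin_pct_tae"))
    result = PhyloPCA(standardize(design), default_ppca_weights(tree)).fit()
    retained = result.retain(2, 1)
    behaviors, counts = simulate_behaviors(
        retained.scores, _PAPERLIKE_BETA, noise_sd=noise_sd,
        interference_rate=interference_rate, rng=rng,
        intercepts=_PAPERLIKE_INTERCEPTS,
    )
    return {
        "tree": tree,
        "traits": traits,
        "behaviors": behaviors,
        "interference": counts,
        "scores": retained.scores,
        "beta": _PAPERLIKE_BETA.copy(),
        "config": {"seed": seed, "noise_sd": noise_sd,
                   "interference_rate": interference_rate,
                   "lambda": _PAPERLIKE_LAMBDA,
                   "intercepts": _PAPERLIKE_INTERCEPTS.tolist()},
    }
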
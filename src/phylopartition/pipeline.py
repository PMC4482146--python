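"""End-to-end orchestration: signal -> prep -> PVR -> pPCA -> regressions.

All randomness flows from the single configured seed: each stage draws from
a substream derived by hashing the stage name into the seed (CRC32, reduced
mod 2^31), so adding a stage never perturbs another stage's draws and reruns
with the same config are byte-identical apart from the manifest timestamp.
Species order in every output follows the tree's tip order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ppca import PhyloPCA, default_ppca_weights
from .pvr import PhyloEigenvectorRegression
from .regress import PermutationOLS, fit_poisson
from .signal import abouheif_test
from .traits import (apply_floors, build_design_matrix, read_trait_table,
                     spearman_matrix, standardize)
from .trees import read_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed: ``crc32("stage:seed") mod 2^31``."""
    return zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)


@dataclass
class RunConfig:
    """Inputs, output directory and analysis settings for one full run."""

    tree_path: str
    traits_path: str
    behaviors_path: str
    out_dir: str
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    k_global: int = 2
    k_local: int = 1
    weight_kind: str = "inverse_distance"  # residual weights for PVR selection
    squared_distances: bool = True         # Gower centering convention
    standardize_traits: bool = True

    def __post_init__(self) -> None:
        if self.B < 99:
            raise ValueError("B must be at least 99")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    tree = read_newick(config.tree_path)
    traits = read_trait_table(config.traits_path)
    behaviors = pd.read_csv(config.behaviors_path, index_col=0)
    behaviors.index = behaviors.index.astype(str)
    tree_set = set(tree.tips)
    for name, table in (("traits", traits), ("behaviors", behaviors)):
        diff = tree_set ^ set(table.index)
        if diff:
            raise ValueError(
                f"species mismatch between tree and {name} table; "
                f"symmetric difference: {sorted(diff)}"
            )
    order = tree.tips
    return tree, traits.loc[order], behaviors.loc[order]


def run_all(config: RunConfig) -> dict:
    """Run the whole analysis and write all tables; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, traits, behaviors = _load_inputs(config)
    interference = None
    if "interference_trials" in behaviors.columns:
        interference = behaviors["interference_trials"]
        behaviors = behaviors.drop(columns=["interference_trials"])

    # -- trait prep ---------------------------------------------------------
    design = build_design_matrix(apply_floors(traits, "tannin_pct_tae"))
    design.to_csv(out / "design_matrix.csv", index_label="species")

    # -- per-trait phylogenetic signal (S5-shaped) --------------------------
    sig_seed = stage_seed(config.seed, "signal")
    rows = []
    for i, col in enumerate(design.columns):
        res = abouheif_test(design[col].to_numpy(), tree, B=config.B,
                            seed=sig_seed + i, tail="upper")
        rows.append({"trait": col, "morans_i": res.statistic,
                     "p_value": res.p_value})
    pd.DataFrame(rows).to_csv(out / "signal_table.csv", index=False)

    # -- Spearman screen over behaviors + traits (S3-shaped) ----------------
    screen = spearman_matrix(pd.concat([behaviors, design], axis=1))
    screen.to_csv(out / "spearman_rho.csv", out / "spearman_p.csv")

    # -- PVR variance partitioning (Table-1-shaped) -------------------------
    pvr = PhyloEigenvectorRegression(
        behaviors, design, tree,
        squared_distances=config.squared_distances,
        residual_weights=("abouheif" if config.weight_kind == "abouheif"
                          else "inverse_distance"),
        alpha=config.alpha, B=config.B,
        seed=stage_seed(config.seed, "pvr"),
    ).fit()
    pvr.to_csv(out / "variance_partition.csv")

    # -- phylogenetic PCA ---------------------------------------------------
    traits_for_ppca = standardize(design) if config.standardize_traits else design
    fit = PhyloPCA(traits_for_ppca, default_ppca_weights(tree)).fit()
    retained = fit.retain(config.k_global, config.k_local)
    retained.loadings.to_csv(out / "ppca_loadings.csv", index_label="trait")
    retained.scores.to_csv(out / "ppca_scores.csv", index_label="species")
    axis_tests = retained.score_signal(tree, B=config.B,
                                       seed=stage_seed(config.seed, "ppca"))
    eigen_info = {
        "eigenvalues": fit.eigenvalues.tolist(),
        "axis_labels": fit.axis_labels,
        "variance_share": fit.variance_share.to_dict(),
        "variance_share_of_total": fit.variance_share_of_total.to_dict(),
        "retained": retained.axis_labels,
        "retained_variance_share": retained.retained_variance_share,
        "dominant_loadings": retained.dominant_loadings(),
        "score_signal": {a: {"statistic": r.statistic, "p": r.p_value,
                             "tail": r.tail}
                         for a, r in axis_tests.items()},
    }
    (out / "ppca_eigen.json").write_text(json.dumps(eigen_info, indent=2))

    # -- permutation regressions (Table-2-shaped) ---------------------------
    reg_seed = stage_seed(config.seed, "regress")
    frames = []
    for i, name in enumerate(behaviors.columns):
        res = PermutationOLS(behaviors[name].to_numpy(), retained.scores,
                             response=name).fit(B=config.B, seed=reg_seed + i)
        frame = res.summary()
        frame.insert(0, "response", name)
        frame.insert(4, "R2", res.R2)
        frames.append(frame)
    pd.concat(frames).to_csv(out / "regressions.csv", index_label="predictor")

    # -- post-hoc Poisson interference model --------------------------------
    if interference is not None and interference.sum() > 0:
        coefs = fit_poisson(interference.to_numpy(), retained.scores)
        coefs.rename("coefficient").to_csv(out / "poisson_interference.csv",
                                           index_label="predictor")

    manifest = {
        "package": "phylopartition",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_species": tree.n_tips,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", out)
    return manifest
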
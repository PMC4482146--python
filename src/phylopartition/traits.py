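"""Building the analysis-ready seed-trait design matrix.

The study design measures, per species: kernel nutrient content (% lipid,
% carbohydrate, % protein), caloric concentration (cal/g), dormancy (days of
cold stratification), physical defenses (hardness in kg, shell thickness in
um, shell mass in g), kernel mass (g), kernel tannin (% tannic acid
equivalents) and moisture (%).  The analysis matrix holds 11 columns in a
fixed order — the five untransformed nutrition/dormancy traits, then natural
logs of hardness, thickness, the hardness x thickness interaction, kernel
mass, shell mass and tannin.  Moisture is measured but excluded.  A small
positive floor replaces exact zeros (tannins) before log transformation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RAW_TRAIT_COLUMNS",
    "DESIGN_COLUMNS",
    "TANNIN_FLOOR",
    "read_trait_table",
    "apply_floors",
    "build_design_matrix",
    "spearman_matrix",
    "standardize",
    "SpearmanResult",
]

#: raw per-species trait columns expected in input CSVs (moisture optional)
RAW_TRAIT_COLUMNS = [
    "lipid_pct",
    "carbohydrate_pct",
    "protein_pct",
    "caloric_cal_per_g",
    "dormancy_days",
    "hardness_kg",
    "thickness_um",
    "kernel_mass_g",
    "shell_mass_g",
    "tannin_pct_tae",
]

#: the 11 analysis columns, in their fixed order
DESIGN_COLUMNS = [
    "lipid_pct",
    "carbohydrate_pct",
    "protein_pct",
    "caloric_cal_per_g",
    "dormancy_days",
    "log_hardness",
    "log_thickness",
    "log_hardness_x_thickness",
    "log_kernel_mass",
    "log_shell_mass",
    "log_tannin",
]

#: floor (% TAE) assigned to tannin-free species before log transformation
TANNIN_FLOOR = 0.35

_PERCENT_COLUMNS = ("lipid_pct", "carbohydrate_pct", "protein_pct",
                    "moisture_pct")


def read_trait_table(path) -> pd.DataFrame:
    """Read a species x trait CSV (species in the first column) and validate."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    missing = [c for c in RAW_TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if df.index.duplicated().any():
        raise ValueError("duplicate species in trait table")
    sub = df[RAW_TRAIT_COLUMNS]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing cells in analysis columns: {bad}")
    for col in _PERCENT_COLUMNS:
        if col in df.columns and ((df[col] < 0) | (df[col] > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    nonneg = [c for c in RAW_TRAIT_COLUMNS if c not in _PERCENT_COLUMNS]
    if (sub[nonneg] < 0).any().any():
        raise ValueError("negative values in mass/hardness/thickness/days column")
    return df


def apply_floors(table: pd.DataFrame, column: str,
                 floor: float = TANNIN_FLOOR) -> pd.DataFrame:
    """Replace exact zeros in ``column`` by ``floor`` (log-transform guard)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if column not in table.columns:
        raise ValueError(f"no column {column!r} in trait table")
    if (table[column] < 0).any():
        raise ValueError(f"negative values in {column!r}")
    out = table.copy()
    zeros = out[column] == 0
    out.loc[zeros, column] = floor
    if int(zeros.sum()):
        logger.info("apply_floors: %d zero(s) in %s floored to %g",
                    int(zeros.sum()), column, floor)
    return out


def build_design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 11-column analysis matrix from raw traits.

    Logs are natural logs; the interaction column is
    ``ln(hardness_kg * thickness_um)``.  Zeros must already be floored.
    """
    log_sources = {
        "log_hardness": table["hardness_kg"],
        "log_thickness": table["thickness_um"],
        "log_hardness_x_thickness": table["hardness_kg"] * table["thickness_um"],
        "log_kernel_mass": table["kernel_mass_g"],
        "log_shell_mass": table["shell_mass_g"],
        "log_tannin": table["tannin_pct_tae"],
    }
    for name, col in log_sources.items():
        bad = col[col <= 0]
        if len(bad):
            raise ValueError(
                f"nonpositive value for {name} at species "
                f"{bad.index[0]!r} ({bad.iloc[0]}); apply a floor first"
            )
    design = pd.DataFrame(index=table.index)
    design["lipid_pct"] = table["lipid_pct"]
    design["carbohydrate_pct"] = table["carbohydrate_pct"]
    design["protein_pct"] = table["protein_pct"]
    design["caloric_cal_per_g"] = table["caloric_cal_per_g"]
    design["dormancy_days"] = table["dormancy_days"]
    for name, col in log_sources.items():
        design[name] = np.log(col)
    return design[DESIGN_COLUMNS]


class SpearmanResult:
    """Spearman rank-correlation screen: rho matrix, p matrix, flagged pairs."""

    def __init__(self, rho: pd.DataFrame, p: pd.DataFrame,
                 flagged: list[str]):
        self.rho = rho
        self.p = p
        self.flagged = flagged  # constant columns with undefined rho

    def to_csv(self, rho_path, p_path) -> None:
        self.rho.to_csv(rho_path, index_label="variable")
        self.p.to_csv(p_path, index_label="variable")


def spearman_matrix(columns: pd.DataFrame) -> SpearmanResult:
    """All-pairs Spearman rank correlations with large-sample p-values.

    Constant columns make rho undefined for their pairs; those are flagged
    and reported as NaN rather than silently set to 0.
    """
    if columns.shape[0] < 4:
        raise ValueError("need at least 4 rows for a correlation screen")
    X = columns.to_numpy(dtype=float)
    names = list(columns.columns)
    flagged = [c for c, v in zip(names, X.var(axis=0)) if v == 0]
    if X.shape[1] == 2:
        r, p = stats.spearmanr(X[:, 0], X[:, 1])
        rho = np.array([[1.0, r], [r, 1.0]])
        pmat = np.array([[0.0, p], [p, 0.0]])
    else:
        rho, pmat = stats.spearmanr(X)
        rho = np.asarray(rho)
        pmat = np.asarray(pmat)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pmat, 0.0)
    return SpearmanResult(pd.DataFrame(rho, index=names, columns=names),
                          pd.DataFrame(pmat, index=names, columns=names),
                          flagged)


def standardize(columns: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, variance 1 with divisor n.

    The n-divisor keeps the phylogenetic PCA eigenvalues decomposing the
    exact trait variance used in the score identities.
    """
    X = columns.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # divisor n
    bad = [c for c, s in zip(columns.columns, sd) if s == 0]
    if bad:
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    return pd.DataFrame((X - mean) / sd, index=columns.index,
                        columns=columns.columns)
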
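"""Per-gene age x radiation interaction models and preranked-list export.

Each gene is fit by ordinary least squares::

    y = b0 + b1 * age_term + b2 * rad + b3 * age_term * rad + e

where ``rad`` is the ordinal radiation-bin code (0 control, 1 low, 2 medium,
3 high; a continuous-Gy option exists) and ``age_term`` is either centred age
in years (continuous mode) or the young-class indicator (categorical mode).
A gene passes the screen when the two-sided t-test on the interaction
coefficient b3 gives p < alpha (raw p-values; the screen is deliberately not
FDR-adjusted, unlike the contrast battery).  The union of the continuous-mode
and categorical-mode gene lists feeds downstream disease evaluation, and a
signed -log10(p) metric orders genes for preranked enrichment export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ValidationError

__all__ = [
    "InteractionResult",
    "fit_gene_interaction",
    "run_interaction_screen",
    "union_interaction_genes",
    "build_preranked",
    "write_rnk",
    "read_rnk",
]

MAX_NEGLOG10_P = 308.0  # float64 underflow guard for -log10(p)


@dataclass(frozen=True)
class InteractionResult:
    """OLS fit of one gene's age x radiation model."""

    coef: tuple[float, float, float, float]  # b0, b1 age, b2 rad, b3 age*rad
    se: tuple[float, float, float, float]
    p_interaction: float
    age_mode: str
    log2FC_radiation: float
    log2FC_age: float


def _interaction_design(
    age: np.ndarray, rad: np.ndarray, age_mode: str, cutoff: float
) -> np.ndarray:
    if age_mode == "continuous":
        age_term = age - age.mean()
    elif age_mode == "categorical":
        age_term = (age <= cutoff).astype(float)
    else:
        raise ValidationError(f"age_mode must be continuous or categorical, got {age_mode!r}")
    return np.column_stack([np.ones(age.size), age_term, rad, age_term * rad])


def _check_design(X: np.ndarray) -> None:
    if X.shape[0] < 8:
        raise ValidationError("interaction model needs at least 8 samples")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        culprits = []
        if np.ptp(X[:, 1]) == 0:
            culprits.append("age term is constant")
        if np.ptp(X[:, 2]) == 0:
            culprits.append("radiation is constant (all samples in one bin)")
        if not culprits:
            culprits.append("age term and radiation are collinear")
        raise ValidationError("rank-deficient design: " + "; ".join(culprits))


def _ols_multi(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each row of Y on X; returns (coef, se, p) each genes x 4."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # genes x k
    resid = Y - beta @ X.T
    df = n - k
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    p = 2.0 * stats.t.sf(np.abs(tvals), df)
    return beta, se, p


def _fold_changes(
    y: np.ndarray, age: np.ndarray, rad: np.ndarray, cutoff: float
) -> tuple[float, float]:
    irradiated = rad > 0
    young = age <= cutoff
    fc_rad = (
        float(y[irradiated].mean() - y[~irradiated].mean())
        if irradiated.any() and (~irradiated).any()
        else np.nan
    )
    fc_age = (
        float(y[young].mean() - y[~young].mean())
        if young.any() and (~young).any()
        else np.nan
    )
    return fc_rad, fc_age


def fit_gene_interaction(
    y: np.ndarray | pd.Series,
    age: np.ndarray | pd.Series,
    radiation: np.ndarray | pd.Series,
    age_mode: str = "continuous",
    cutoff: float = 29.0,
) -> InteractionResult:
    """Fit the age x radiation OLS model for one gene.

    ``radiation`` is the ordinal bin code (or continuous Gy if the caller
    prefers); ``cutoff`` defines the young indicator in categorical mode and
    the young/old fold change reported in both modes.  The interaction
    p-value is the two-sided t-test on b3 with n - 4 residual degrees of
    freedom.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    rad = np.asarray(radiation, dtype=float)
    if not (y.size == age.size == rad.size):
        raise ValidationError("y, age and radiation must align")
    X = _interaction_design(age, rad, age_mode, cutoff)
    _check_design(X)
    beta, se, p = _ols_multi(X, y[np.newaxis, :])
    fc_rad, fc_age = _fold_changes(y, age, rad, cutoff)
    return InteractionResult(
        coef=tuple(beta[0]),
        se=tuple(se[0]),
        p_interaction=float(p[0, 3]),
        age_mode=age_mode,
        log2FC_radiation=fc_rad,
        log2FC_age=fc_age,
    )


def run_interaction_screen(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    age_mode: str = "continuous",
    alpha: float = 0.05,
    cutoff: float = 29.0,
    rad_column: str = "rad_code",
) -> tuple[list[str], pd.DataFrame]:
    """Screen every gene for an age x radiation interaction at raw p < alpha.

    Returns the significant gene list (matrix row order) and the complete
    per-gene table of coefficients, standard errors, p-values and the
    reporting fold changes (irradiated - control; young - old at ``cutoff``).
    """
    annot = annot.loc[expr.columns]
    if "age" not in annot.columns or rad_column not in annot.columns:
        raise ValidationError(f"annotations need 'age' and {rad_column!r} columns")
    age = annot["age"].to_numpy(dtype=float)
    rad = annot[rad_column].to_numpy(dtype=float)
    X = _interaction_design(age, rad, age_mode, cutoff)
    _check_design(X)
    Y = expr.to_numpy(dtype=float)
    beta, se, p = _ols_multi(X, Y)

    irradiated = rad > 0
    young = age <= cutoff
    fc_rad = Y[:, irradiated].mean(axis=1) - Y[:, ~irradiated].mean(axis=1)
    fc_age = Y[:, young].mean(axis=1) - Y[:, ~young].mean(axis=1)
    table = pd.DataFrame(
        {
            "b0": beta[:, 0],
            "b_age": beta[:, 1],
            "b_rad": beta[:, 2],
            "b_interaction": beta[:, 3],
            "se_interaction": se[:, 3],
            "p_interaction": p[:, 3],
            "log2FC_radiation": fc_rad,
            "log2FC_age": fc_age,
            "age_mode": age_mode,
        },
        index=expr.index.copy(),
    )
    significant = table.index[table["p_interaction"] < alpha].tolist()
    return significant, table


def union_interaction_genes(
    list_continuous: Sequence[str], list_categorical: Sequence[str]
) -> list[str]:
    """Deterministic alphabetical union of the two screens' gene lists."""
    return sorted(set(list_continuous) | set(list_categorical))


def build_preranked(
    results: pd.DataFrame, metric: str = "signed_logp"
) -> pd.DataFrame:
    """Order genes for preranked enrichment from an interaction-screen table.

    Metrics: ``signed_logp`` (default) = sign(log2FC_radiation) *
    -log10(p_interaction); ``log2FC_radiation``; ``log2FC_age``.  The list is
    sorted by score descending with alphabetical tie order; p = 0 scores are
    capped at +/-308.
    """
    needed = {"p_interaction", "log2FC_radiation", "log2FC_age"}
    missing_cols = needed - set(results.columns)
    if missing_cols:
        raise ValidationError(f"results table lacks columns: {sorted(missing_cols)}")
    if metric == "signed_logp":
        cols = ["p_interaction", "log2FC_radiation"]
    elif metric in ("log2FC_radiation", "log2FC_age"):
        cols = [metric]
    else:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    sub = results[cols]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing ranking values for gene(s): {bad[:10]}")
    if metric == "signed_logp":
        p = results["p_interaction"].to_numpy(dtype=float)
        zero = p == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} gene(s) with p = 0; score capped at "
                f"+/-{MAX_NEGLOG10_P:.0f}",
                stacklevel=2,
            )
        with np.errstate(divide="ignore"):
            logp = np.minimum(-np.log10(p), MAX_NEGLOG10_P)
        score = np.sign(results["log2FC_radiation"].to_numpy(dtype=float)) * logp
    else:
        score = results[metric].to_numpy(dtype=float)
    ranked = pd.DataFrame({"gene": results.index, "score": score})
    if ranked["gene"].duplicated().any():
        raise ValidationError("ranked list requires unique gene ids")
    ranked = ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ranked


def write_rnk(ranked: pd.DataFrame, path: str | Path) -> Path:
    """Write a two-column gene/score .rnk file (no header, tab-delimited)."""
    path = Path(path)
    ranked[["gene", "score"]].to_csv(path, sep="\t", header=False, index=False)
    return path


def read_rnk(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
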
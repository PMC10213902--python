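"""Reading, validation and harmonisation of expression matrices and annotations.

Expression is a log2-scale genes x samples DataFrame; annotations are a
per-sample covariate sheet (age, absorbed dose D_T in Gy, sex, batch, and the
optional disease-cohort columns).  This module also owns the dose-binning
convention, the young/old dichotomy, robust outlier screening, per-gene
regression batch removal, and probe-to-gene collapse.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "RadiationBin",
    "RADIATION_BINS",
    "read_expression_table",
    "read_series_matrix",
    "assign_radiation_bin",
    "annotate_bins_and_age",
    "dichotomize_age",
    "detect_outlier_samples",
    "remove_batch_effect",
    "collapse_probes",
    "maybe_log2",
]


class ValidationError(ValueError):
    """Input tables violate the pipeline's contracts."""


class RadiationBin(NamedTuple):
    """CDC-aligned absorbed-dose category with its ordinal code."""

    label: str
    code: int


RADIATION_BINS = {
    "control": RadiationBin("control", 0),
    "low": RadiationBin("low", 1),
    "medium": RadiationBin("medium", 2),
    "high": RadiationBin("high", 3),
}


def assign_radiation_bin(dose_Gy: float) -> RadiationBin:
    """Map an absorbed dose D_T (Gy) to its category.

    control: D_T = 0; low: 0 < D_T < 0.5; medium: 0.5 <= D_T < 1;
    high: D_T >= 1.  Boundaries at 0.5 and 1 Gy are left-closed.
    """
    if dose_Gy < 0:
        raise ValidationError(f"dose must be >= 0 Gy, got {dose_Gy}")
    if dose_Gy == 0:
        return RADIATION_BINS["control"]
    if dose_Gy < 0.5:
        return RADIATION_BINS["low"]
    if dose_Gy < 1.0:
        return RADIATION_BINS["medium"]
    return RADIATION_BINS["high"]


def dichotomize_age(age: float, cutoff: float) -> str:
    """Return "young" iff ``age <= cutoff`` else "old" (boundary inclusive)."""
    if age <= 0:
        raise ValidationError(f"age must be positive, got {age}")
    return "young" if age <= cutoff else "old"


def annotate_bins_and_age(annot: pd.DataFrame, cutoff: float | None = None) -> pd.DataFrame:
    """Return a copy of ``annot`` with radiation_bin/rad_code (and age_class) columns."""
    out = annot.copy()
    if "dose_Gy" in out.columns:
        bins = [assign_radiation_bin(d) for d in out["dose_Gy"].astype(float)]
        out["radiation_bin"] = [b.label for b in bins]
        out["rad_code"] = [b.code for b in bins]
    if cutoff is not None and "age" in out.columns:
        out["age_class"] = [dichotomize_age(a, cutoff) for a in out["age"].astype(float)]
    return out


def read_expression_table(
    path: str | Path, annotation_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read tab-delimited expression (first column gene id) and annotation sheets.

    Sample ids must match exactly between the two files; annotation rows are
    reordered to the expression column order.  Missing optional covariates are
    left absent (callers treat them as unknown).
    """
    path, annotation_path = Path(path), Path(annotation_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)
    expr = pd.read_csv(path, sep="\t", index_col=0)
    annot = pd.read_csv(annotation_path, sep="\t", index_col=0)
    _validate_pair(expr, annot)
    return expr, annot.loc[expr.columns]


def _validate_pair(expr: pd.DataFrame, annot: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    non_numeric = [c for c in expr.columns if not pd.api.types.is_numeric_dtype(expr[c])]
    if non_numeric:
        col = non_numeric[0]
        bad = expr[col][pd.to_numeric(expr[col], errors="coerce").isna()]
        loc = f"column {col!r}" + (f", row {bad.index[0]!r}" if len(bad) else "")
        raise ValidationError(f"non-numeric expression value at {loc}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValidationError("expression matrix contains non-finite values")
    missing = sorted(set(expr.columns) - set(annot.index))
    extra = sorted(set(annot.index) - set(expr.columns))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"samples missing from annotations: {missing[:10]}")
        if extra:
            parts.append(f"annotated samples absent from matrix: {extra[:10]}")
        raise ValidationError("; ".join(parts))


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read the expression block of a GEO series-matrix text file.

    Metadata lines starting with "!" are skipped; the table between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` (or, if
    those sentinels are absent, all non-"!" lines) is parsed as tab-delimited
    with the first column as probe/gene id.
    """
    lines = Path(path).read_text().splitlines()
    body = [ln for ln in lines if ln and not ln.startswith("!")]
    if not body:
        raise ValidationError(f"no expression table found in {path}")
    from io import StringIO

    expr = pd.read_csv(StringIO("\n".join(body)), sep="\t", index_col=0)
    expr.index.name = "gene_id"
    expr.columns = [c.strip('"') for c in expr.columns]
    expr.index = [str(i).strip('"') for i in expr.index]
    return expr


def detect_outlier_samples(
    expr: pd.DataFrame, threshold_k: float = 6.0
) -> list[str]:
    """Flag samples far from the cohort centroid in PC1/PC2 space.

    A sample is an outlier when its Euclidean distance from the centroid in
    the first two principal components exceeds ``median + k * scaled-MAD`` of
    the distance distribution (MAD scaled by 1.4826 for normal consistency).
    """
    if threshold_k <= 0:
        raise ValidationError(f"threshold_k must be > 0, got {threshold_k}")
    if expr.shape[1] < 4:
        raise ValidationError("outlier detection needs at least 4 samples")
    if math.isinf(threshold_k):
        return []
    scores = PCA(n_components=2, svd_solver="full").fit_transform(expr.to_numpy().T)
    dist = np.linalg.norm(scores - scores.mean(axis=0), axis=1)
    med = float(np.median(dist))
    mad = 1.4826 * float(np.median(np.abs(dist - med)))
    if mad == 0.0:
        return []
    flagged = dist > med + threshold_k * mad
    return [s for s, f in zip(expr.columns, flagged) if f]


def _design_matrix(
    batches: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build [intercept | covariates | sum-to-zero batch contrasts]."""
    n = len(batches)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.nunique() < 2:
                continue  # constant covariate carries no batch-protectable signal
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
            else:
                levels = sorted(col.astype(str).unique())
                for lev in levels[1:]:
                    cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                    names.append(f"{name}[{lev}]")
    levels = sorted(batches.astype(str).unique())
    contrast = np.zeros((n, len(levels) - 1))
    codes = batches.astype(str).map({lev: i for i, lev in enumerate(levels)}).to_numpy()
    for j in range(len(levels) - 1):
        contrast[codes == j, j] = 1.0
        contrast[codes == len(levels) - 1, j] = -1.0
    X = np.column_stack(cols)
    return X, contrast, names


def remove_batch_effect(
    expr: pd.DataFrame,
    batches: pd.Series | Mapping[str, str],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regress out additive per-batch shifts, protecting biological covariates.

    Per gene, an ordinary least-squares model with intercept, the protected
    covariates and sum-to-zero batch contrasts is fit (via the normal
    equations, all genes at once) and the fitted batch component subtracted.
    Protected-covariate effect estimates are unchanged by construction, and
    the operation is idempotent.  A single batch is returned unchanged.
    """
    batches = pd.Series(batches).loc[expr.columns]
    if covariates is not None:
        covariates = covariates.loc[expr.columns]
    if batches.nunique() < 2:
        return expr.copy()
    X, contrast, names = _design_matrix(batches, covariates)
    full = np.column_stack([X, contrast])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        # identify which protected column is confounded with batch
        base_rank = np.linalg.matrix_rank(X)
        offender = "covariates"
        for j, name in enumerate(names[1:], start=1):  # never blame the intercept
            trial = np.column_stack([np.delete(X, j, axis=1), contrast])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                offender = name
                break
        raise ValidationError(
            f"batch is confounded with protected covariate {offender!r} "
            f"(design rank {rank} < {full.shape[1]}, covariate-only rank {base_rank})"
        )
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(full, Y, rcond=None)
    batch_coef = beta[X.shape[1]:, :]
    batch_component = contrast @ batch_coef  # samples x genes
    cleaned = (Y - batch_component).T
    return pd.DataFrame(cleaned, index=expr.index, columns=expr.columns)


def collapse_probes(
    expr: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    rule: str = "max_variance",
) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene.

    ``max_variance`` (default) keeps the probe with the largest variance
    across samples; ``mean`` averages the probes of each gene.
    """
    unmapped = sorted(set(expr.index) - set(probe_to_gene))
    if unmapped:
        raise ValidationError(f"unmapped probe(s): {unmapped[:10]}")
    if rule not in ("max_variance", "mean"):
        raise ValidationError(f"unknown collapse rule {rule!r}")
    genes = pd.Series({p: probe_to_gene[p] for p in expr.index}, name="gene")
    if rule == "mean":
        out = expr.groupby(genes, sort=True).mean()
    else:
        variances = expr.var(axis=1, ddof=1)
        keep = (
            pd.DataFrame({"gene": genes, "var": variances})
            .sort_values(["gene", "var"], ascending=[True, False], kind="stable")
            .drop_duplicates("gene")
            .index
        )
        out = expr.loc[keep].copy()
        out.index = [probe_to_gene[p] for p in out.index]
        out = out.sort_index()
    out.index.name = "gene_id"
    return out


def maybe_log2(expr: pd.DataFrame, apply: bool = False, ceiling: float = 30.0) -> pd.DataFrame:
    """Guard against linear-scale input: warn when max exceeds ``ceiling``.

    The pipeline assumes log2-scale values throughout.  When ``apply`` is
    true and the matrix looks linear-scale, ``log2(x + 1)`` is applied.
    """
    if float(expr.to_numpy().max()) > ceiling:
        if apply:
            return np.log2(expr + 1.0)
        warnings.warn(
            f"expression maximum exceeds {ceiling}; values may be on a linear "
            "scale (pass apply=True to log2-transform)",
            stacklevel=2,
        )
    return expr.copy()
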
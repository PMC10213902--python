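"""Two-group differential expression across dose bins, age classes and sex.

Each contrast is a per-gene Welch t-test with Benjamini-Hochberg FDR control
within the contrast, and log2 fold change defined as mean(A) - mean(B) on the
log2 scale.  Also provides UpSet-style intersection counts over the
significant sets of several contrasts, and qualitative dose-trend profiles
across the ordered radiation bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ValidationError

__all__ = [
    "two_group_de",
    "bh_adjust",
    "ContrastSet",
    "default_contrasts",
    "run_contrasts",
    "intersect_significant",
    "dose_trend",
]


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def two_group_de(
    expr: pd.DataFrame,
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    label: str = "",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group t-test table for groups A and B of samples.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``, ``fdr``
    (BH within this table), ``log2FC`` (mean_A - mean_B), ``n_A``, ``n_B``
    and the contrast ``label``.  Welch (unequal-variance) by default; pass
    ``equal_var=True`` for the pooled-variance variant.
    """
    ids_a, ids_b = list(ids_a), list(ids_b)
    overlap = sorted(set(ids_a) & set(ids_b))
    if overlap:
        raise ValidationError(f"groups overlap: {overlap[:5]}")
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    A = expr[ids_a].to_numpy(dtype=float)
    B = expr[ids_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) constant in both groups; "
            "reporting t=0, p=1",
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
            "log2FC": log2fc,
            "n_A": len(ids_a),
            "n_B": len(ids_b),
            "contrast": label,
        },
        index=expr.index.copy(),
    )
    return table


@dataclass(frozen=True)
class ContrastSet:
    """Named two-group contrasts defined over annotation columns.

    Each contrast maps a name to a pair of boolean selector expressions
    evaluated against the annotation sheet via :meth:`resolve`.
    """

    contrasts: tuple[tuple[str, str, str], ...]  # (name, query_A, query_B)

    def resolve(
        self, annot: pd.DataFrame
    ) -> dict[str, tuple[list[str], list[str]]]:
        out = {}
        for name, qa, qb in self.contrasts:
            ids_a = annot.query(qa).index.tolist()
            ids_b = annot.query(qb).index.tolist()
            out[name] = (ids_a, ids_b)
        return out


def default_contrasts() -> ContrastSet:
    """The six-contrast battery: four radiation contrasts, age, and sex."""
    return ContrastSet(
        contrasts=(
            ("control_vs_any_radiation", "rad_code == 0", "rad_code > 0"),
            ("control_vs_low", "rad_code == 0", "rad_code == 1"),
            ("low_vs_medium", "rad_code == 1", "rad_code == 2"),
            ("medium_vs_high", "rad_code == 2", "rad_code == 3"),
            ("young_vs_old", "age_class == 'young'", "age_class == 'old'"),
            ("male_vs_female", "sex == 'male'", "sex == 'female'"),
        )
    )


def run_contrasts(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    contrasts: ContrastSet | None = None,
) -> dict[str, pd.DataFrame]:
    """Run a battery of contrasts; empty-sided contrasts are skipped with a warning."""
    contrasts = contrasts if contrasts is not None else default_contrasts()
    resolved = contrasts.resolve(annot.loc[expr.columns])
    tables: dict[str, pd.DataFrame] = {}
    for name, (ids_a, ids_b) in resolved.items():
        if len(ids_a) < 2 or len(ids_b) < 2:
            warnings.warn(f"contrast {name!r} skipped: a side has < 2 samples", stacklevel=2)
            continue
        tables[name] = two_group_de(expr, ids_a, ids_b, label=name)
    return tables


def intersect_significant(
    tables: Mapping[str, pd.DataFrame], alpha_on_q: float = 0.05
) -> pd.DataFrame:
    """UpSet-style exact-subset counts of significant genes across contrasts.

    For every non-empty subset of tables, counts genes significant
    (``fdr < alpha_on_q``) in exactly that subset.  Returns a DataFrame with
    one indicator column per table, a ``count`` column, and the member genes.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValidationError("need at least 2 tables to intersect")
    sig_sets = {
        name: set(tab.index[tab["fdr"] < alpha_on_q]) for name, tab in tables.items()
    }
    union = sorted(set().union(*sig_sets.values()))
    membership: dict[tuple[bool, ...], list[str]] = {}
    for gene in union:
        key = tuple(gene in sig_sets[name] for name in names)
        membership.setdefault(key, []).append(gene)
    rows = []
    for key, genes in sorted(membership.items(), key=lambda kv: (-sum(kv[0]), kv[0])):
        row = {name: inc for name, inc in zip(names, key)}
        row["count"] = len(genes)
        row["genes"] = ",".join(sorted(genes))
        rows.append(row)
    return pd.DataFrame(rows, columns=names + ["count", "genes"])


def dose_trend(
    expr: pd.DataFrame, annot: pd.DataFrame, genes: Sequence[str]
) -> pd.DataFrame:
    """Sign profile of successive bin-mean differences over the four dose bins.

    For each gene, the sign of (low - control, medium - low, high - medium)
    of the per-bin means on the log2 scale, e.g. ``(+,+,+)`` for a monotone
    dose response.  All four bins must be populated.
    """
    annot = annot.loc[expr.columns]
    if "rad_code" not in annot.columns:
        raise ValidationError("annotations lack rad_code; run annotate_bins_and_age first")
    bin_ids = {c: annot.index[annot["rad_code"] == c].tolist() for c in range(4)}
    empty = [
        {0: "control", 1: "low", 2: "medium", 3: "high"}[c]
        for c, ids in bin_ids.items()
        if not ids
    ]
    if empty:
        raise ValidationError(f"empty radiation bin(s): {', '.join(empty)}")
    missing = sorted(set(genes) - set(expr.index))
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:10]}")
    means = np.column_stack(
        [expr.loc[list(genes), bin_ids[c]].mean(axis=1).to_numpy() for c in range(4)]
    )
    diffs = np.diff(means, axis=1)
    symbols = np.where(diffs > 0, "+", np.where(diffs < 0, "-", "0"))
    profile = ["(" + ",".join(row) + ")" for row in symbols]
    return pd.DataFrame(
        {
            "d_control_to_low": diffs[:, 0],
            "d_low_to_medium": diffs[:, 1],
            "d_medium_to_high": diffs[:, 2],
            "profile": profile,
        },
        index=pd.Index(genes, name="gene_id"),
    )
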
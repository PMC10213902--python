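"""Evaluation of the rad-age gene list on a lung-disease cohort.

Three stages: (1) one-vs-rest two-group tests for every disease, ethnicity
and sex level within each of the train/test/validation splits; (2) a
cross-split candidate filter keeping genes that are significant with a large
fold change in at least ``min_test_cases`` of those one-vs-rest test cases in
every split; (3) a per-gene factorial OLS model
``gene ~ disease * ethnicity * sex`` whose three-way interaction block is
tested with a partial F-test, with genes tiered by the deepest significant
interaction (three-way > any two-way > any main effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import two_group_de
from .preprocess import ValidationError

__all__ = [
    "CandidateFilterConfig",
    "ThreeWayResult",
    "merge_rare_levels",
    "one_vs_rest_tables",
    "all_one_vs_rest",
    "filter_candidates",
    "fit_three_way",
    "rank_clinical_genes",
]

FACTORS = ("disease", "ethnicity", "sex")
SPLITS = ("train", "test", "validation")


@dataclass(frozen=True)
class CandidateFilterConfig:
    """Cross-split gene filter: p < alpha with |log2FC| > fc_threshold in at
    least ``min_test_cases`` one-vs-rest cases in every required split."""

    alpha: float = 0.05
    min_test_cases: int = 2
    fc_threshold: float = 2.0
    required_splits: tuple[str, ...] = SPLITS
    abs_fc: bool = True  # gate on |log2FC|; False gates on signed log2FC

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_test_cases < 1:
            raise ValidationError("min_test_cases must be >= 1")
        if self.fc_threshold < 0:
            raise ValidationError("fc_threshold must be >= 0")


def merge_rare_levels(
    annot: pd.DataFrame,
    factor: str,
    min_count: int = 4,
    split_column: str | None = "split",
    other_label: str = "other",
) -> pd.DataFrame:
    """Merge factor levels with < ``min_count`` samples in any split into "other".

    Singleton demographic levels cannot support one-vs-rest tests or factorial
    cells; merging them keeps every retained level testable in every split.
    """
    out = annot.copy()
    if split_column is not None and split_column in out.columns:
        counts = out.groupby([split_column, factor], observed=True).size().unstack(fill_value=0)
        rare = [lev for lev in counts.columns if (counts[lev] < min_count).any()]
    else:
        vc = out[factor].value_counts()
        rare = [lev for lev in vc.index if vc[lev] < min_count]
    if rare:
        out[factor] = out[factor].where(~out[factor].isin(rare), other_label)
    return out


def one_vs_rest_tables(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    factor: str,
    split: str,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest tables per level of ``factor`` within one split.

    Levels with fewer than 2 samples on either side are skipped with a
    warning.  For two-level factors only the alphabetically first level is
    tested (the other is its mirror).
    """
    if factor not in annot.columns:
        raise ValidationError(f"factor {factor!r} absent from annotations")
    annot = annot.loc[expr.columns]
    sub = annot[annot["split"] == split]
    if sub.empty:
        raise ValidationError(f"split {split!r} has no samples")
    levels = sorted(sub[factor].dropna().unique())
    if len(levels) == 2:
        levels = levels[:1]
    tables: dict[str, pd.DataFrame] = {}
    for level in levels:
        ids_level = sub.index[sub[factor] == level].tolist()
        ids_rest = sub.index[sub[factor] != level].tolist()
        if len(ids_level) < 2 or len(ids_rest) < 2:
            warnings.warn(
                f"{factor}={level!r} skipped in split {split!r}: "
                "< 2 samples on one side",
                stacklevel=2,
            )
            continue
        tables[level] = two_group_de(
            expr[sub.index.tolist()], ids_level, ids_rest,
            label=f"{factor}:{level}_vs_rest[{split}]",
        )
    return tables


def all_one_vs_rest(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    split: str,
    factors: Sequence[str] = FACTORS,
) -> dict[str, pd.DataFrame]:
    """All one-vs-rest test cases of a split, keyed "factor:level"."""
    cases: dict[str, pd.DataFrame] = {}
    for factor in factors:
        for level, table in one_vs_rest_tables(expr, annot, factor, split).items():
            cases[f"{factor}:{level}"] = table
    return cases


def filter_candidates(
    gene_list: Sequence[str],
    tables_by_split: Mapping[str, Mapping[str, pd.DataFrame]],
    config: CandidateFilterConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the cross-split candidate rule to ``gene_list``.

    A gene survives iff in every required split it is significant
    (p < alpha) with a passing fold change in at least ``min_test_cases``
    distinct one-vs-rest test cases (pooled across factors).  Genes absent
    from the disease matrix are dropped with a warning.  Returns the
    surviving genes and a per-gene x split table of passing-case counts.
    """
    config = config or CandidateFilterConfig()
    missing_splits = [s for s in config.required_splits if s not in tables_by_split]
    if missing_splits:
        raise ValidationError(f"missing tables for split(s): {missing_splits}")
    genes = list(dict.fromkeys(gene_list))
    available: set[str] = set()
    for split in config.required_splits:
        for table in tables_by_split[split].values():
            available.update(table.index)
    dropped = [g for g in genes if g not in available]
    if dropped:
        warnings.warn(
            f"{len(dropped)} candidate gene(s) absent from the disease matrix "
            f"and dropped: {dropped[:10]}",
            stacklevel=2,
        )
    genes = [g for g in genes if g in available]
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                          columns=list(config.required_splits))
    for split in config.required_splits:
        for table in tables_by_split[split].values():
            sub = table.loc[table.index.intersection(genes)]
            fc = sub["log2FC"].abs() if config.abs_fc else sub["log2FC"]
            passing = sub.index[(sub["p"] < config.alpha) & (fc > config.fc_threshold)]
            counts.loc[passing, split] += 1
    survivors = counts.index[(counts >= config.min_test_cases).all(axis=1)].tolist()
    return survivors, counts


# ---------------------------------------------------------------------------
# Three-way factorial model.

@dataclass(frozen=True)
class ThreeWayResult:
    """Partial-F decomposition of one gene's disease x ethnicity x sex model."""

    p_three_way: float
    p_two_way: Mapping[tuple[str, str], float]
    p_main: Mapping[str, float]
    residual_df: int
    coef: Mapping[str, float] = field(default_factory=dict)
    dropped_terms: tuple[str, ...] = ()


def _dummies(labels: np.ndarray, name: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(labels))
    cols = [(labels == lev).astype(float) for lev in levels[1:]]
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    if not cols:
        return np.empty((labels.size, 0)), []
    return np.column_stack(cols), names


def _interact(
    a: np.ndarray, a_names: list[str], b: np.ndarray, b_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for i, ni in enumerate(a_names):
        for j, nj in enumerate(b_names):
            cols.append(a[:, i] * b[:, j])
            names.append(f"{ni}:{nj}")
    if not cols:
        return np.empty((a.shape[0], 0)), []
    return np.column_stack(cols), names


def _prune(
    base: np.ndarray, block: np.ndarray, names: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily keep block columns that add rank to the running design."""
    kept_cols, kept_names, dropped = [], [], []
    current = base
    rank = np.linalg.matrix_rank(current) if current.size else 0
    for j, name in enumerate(names):
        col = block[:, j : j + 1]
        if not col.any():
            dropped.append(name)
            continue
        trial = np.hstack([current, col])
        trial_rank = np.linalg.matrix_rank(trial)
        if trial_rank > rank:
            current = trial
            rank = trial_rank
            kept_cols.append(block[:, j])
            kept_names.append(name)
        else:
            dropped.append(name)
    kept = np.column_stack(kept_cols) if kept_cols else np.empty((block.shape[0], 0))
    return kept, kept_names, dropped


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(np.linalg.matrix_rank(X))


def _partial_f(y: np.ndarray, X_red: np.ndarray, X_full: np.ndarray) -> float:
    rss_f, rank_f = _rss(X_full, y)
    rss_r, rank_r = _rss(X_red, y)
    df_diff = rank_f - rank_r
    df_res = y.size - rank_f
    if df_diff == 0:
        return np.nan
    if df_res <= 0:
        raise ValidationError(
            "saturated model with zero residual degrees of freedom; merge factor levels"
        )
    if rss_f <= 0:
        return 0.0
    f = ((rss_r - rss_f) / df_diff) / (rss_f / df_res)
    return float(stats.f.sf(f, df_diff, df_res))


def fit_three_way(
    y: np.ndarray | pd.Series,
    disease: Sequence[str],
    ethnicity: Sequence[str],
    sex: Sequence[str],
) -> ThreeWayResult:
    """Full-factorial OLS of one gene on disease, ethnicity and sex.

    The three-way p-value is the partial F-test of the full model against
    the model with all main effects and two-way interactions; each two-way
    block is tested within the all-two-way model, and each main block within
    the main-effects model.  Interaction columns for empty factorial cells
    (or otherwise collinear columns) are dropped and recorded.
    """
    y = np.asarray(y, dtype=float)
    labels = {
        "disease": np.asarray(disease, dtype=object),
        "ethnicity": np.asarray(ethnicity, dtype=object),
        "sex": np.asarray(sex, dtype=object),
    }
    for name, arr in labels.items():
        if arr.size != y.size:
            raise ValidationError(f"{name} labels must align with y")
        counts = pd.Series(arr).value_counts()
        if len(counts) < 2:
            raise ValidationError(f"factor {name!r} has a single level")
        if (counts < 2).any():
            thin = counts.index[counts < 2].tolist()
            raise ValidationError(
                f"factor {name!r} level(s) {thin} have < 2 samples; merge levels first"
            )

    main: dict[str, tuple[np.ndarray, list[str]]] = {
        name: _dummies(arr, name) for name, arr in labels.items()
    }
    intercept = np.ones((y.size, 1))
    X_main = np.hstack([intercept] + [main[f][0] for f in FACTORS])

    dropped_all: list[str] = []
    two_way: dict[tuple[str, str], tuple[np.ndarray, list[str]]] = {}
    base = X_main
    for fa, fb in combinations(FACTORS, 2):
        block, names = _interact(*main[fa], *main[fb])
        kept, kept_names, dropped = _prune(base, block, names)
        two_way[(fa, fb)] = (kept, kept_names)
        dropped_all.extend(dropped)
        base = np.hstack([base, kept]) if kept.size else base
    X_two = base
    tw_block, tw_names = _interact(
        *_interact(*main["disease"], *main["ethnicity"]), *main["sex"]
    )
    kept3, kept3_names, dropped3 = _prune(X_two, tw_block, tw_names)
    dropped_all.extend(dropped3)
    X_full = np.hstack([X_two, kept3]) if kept3.size else X_two

    rank_full = np.linalg.matrix_rank(X_full)
    residual_df = y.size - rank_full
    if residual_df <= 0:
        raise ValidationError(
            "saturated model with zero residual degrees of freedom; merge factor levels"
        )

    p_three = _partial_f(y, X_two, X_full)
    p_two: dict[tuple[str, str], float] = {}
    for pair in combinations(FACTORS, 2):
        others = [two_way[q][0] for q in combinations(FACTORS, 2) if q != pair]
        X_red = np.hstack([X_main] + [o for o in others if o.size])
        p_two[pair] = _partial_f(y, X_red, X_two)
    p_main: dict[str, float] = {}
    for factor in FACTORS:
        others = [main[f][0] for f in FACTORS if f != factor]
        X_red = np.hstack([intercept] + [o for o in others if o.size])
        p_main[factor] = _partial_f(y, X_red, X_main)

    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    names = (
        ["intercept"]
        + [n for f in FACTORS for n in main[f][1]]
        + [n for pair in combinations(FACTORS, 2) for n in two_way[pair][1]]
        + kept3_names
    )
    coef = dict(zip(names, map(float, beta)))
    return ThreeWayResult(
        p_three_way=p_three,
        p_two_way=p_two,
        p_main=p_main,
        residual_df=int(residual_df),
        coef=coef,
        dropped_terms=tuple(dropped_all),
    )


def rank_clinical_genes(
    results: Mapping[str, ThreeWayResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Tier genes by the deepest significant interaction.

    Tier 1: significant three-way interaction; tier 2: any significant
    two-way block; tier 3: any significant main effect; tier 0: nothing
    significant.  Within a tier genes sort by the tier's defining p-value.
    """
    rows = []
    for gene, res in results.items():
        p2 = min((p for p in res.p_two_way.values() if np.isfinite(p)), default=np.nan)
        pm = min((p for p in res.p_main.values() if np.isfinite(p)), default=np.nan)
        if np.isfinite(res.p_three_way) and res.p_three_way < alpha:
            tier, key = 1, res.p_three_way
        elif np.isfinite(p2) and p2 < alpha:
            tier, key = 2, p2
        elif np.isfinite(pm) and pm < alpha:
            tier, key = 3, pm
        else:
            tier, key = 0, np.inf
        rows.append(
            {
                "gene": gene,
                "tier": tier,
                "p_three_way": res.p_three_way,
                "p_two_way_min": p2,
                "p_main_min": pm,
                "_key": key,
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return pd.DataFrame(
            columns=["gene", "tier", "p_three_way", "p_two_way_min", "p_main_min"]
        )
    report["_tier_order"] = report["tier"].replace(0, 99)
    report = report.sort_values(
        ["_tier_order", "_key", "gene"], kind="stable"
    ).drop(columns=["_key", "_tier_order"]).reset_index(drop=True)
    return report
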
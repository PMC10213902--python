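"""Empirical determination of the young/old chronological-age cutoff.

Every candidate cutoff age in a range (default 21-65 years) is evaluated by
dichotomising the cohort at that age and, for each gene of a small aging
panel, computing (a) a two-sample t-test p-value and log2 fold change
(young minus old) and (b) the average train/test ROC AUC of a univariate
classifier over many balanced subsampling permutations.  The winning cutoff
is the one with the most panel genes significant at alpha, ties broken by
the higher mean test AUC among those significant genes.

Balanced subsampling: at each permutation the majority class is downsampled
without replacement to the minority size, the balanced set is split 60/40
into train/test with age-quartile stratification within each class, the
classifier is oriented on the training half, and ROC AUC is recorded for
both halves.  Because ROC AUC is a rank statistic, any monotone link yields
the same AUC; the only trainable quantity of a univariate logistic-type
score that affects AUC is its orientation, which is estimated as the sign of
the training-set class-mean difference (the sign of the fitted univariate
logistic slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ValidationError

__all__ = [
    "GenePanel",
    "ThresholdScanConfig",
    "ThresholdScanResult",
    "CutoffSelection",
    "balanced_auc",
    "scan_thresholds",
    "select_cutoff",
]


@dataclass(frozen=True)
class GenePanel:
    """Ordered marker-gene panel, resolved against an expression matrix."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene panel is empty")

    def resolve(self, expr: pd.DataFrame) -> tuple[list[str], list[str]]:
        """Return (present, dropped) panel members for this matrix."""
        index = set(expr.index)
        present = [g for g in self.genes if g in index]
        dropped = [g for g in self.genes if g not in index]
        if not present:
            raise ValidationError("no panel gene present in the expression matrix")
        if dropped:
            warnings.warn(
                f"{len(dropped)} panel gene(s) absent and dropped: {dropped}",
                stacklevel=2,
            )
        return present, dropped


@dataclass(frozen=True)
class ThresholdScanConfig:
    cutoff_min: int = 21
    cutoff_max: int = 65
    alpha: float = 0.05
    n_perm: int = 1000
    train_fraction: float = 0.6
    min_class_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cutoff_min < self.cutoff_max:
            raise ValidationError("cutoff_min must be < cutoff_max")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")


def _rank_auc(scores: np.ndarray, is_pos: np.ndarray) -> float:
    """Mann-Whitney ROC AUC of ``scores`` for the positive class, ties averaged.

    Computed as the fraction of (positive, negative) pairs ordered correctly,
    counting ties as half, via a sort of the negatives and two binary
    searches per positive.
    """
    pos = scores[is_pos]
    neg = np.sort(scores[~is_pos])
    if pos.size == 0 or neg.size == 0:
        return np.nan
    less = np.searchsorted(neg, pos, side="left")
    less_or_eq = np.searchsorted(neg, pos, side="right")
    wins = less.sum() + 0.5 * (less_or_eq - less).sum()
    return float(wins / (pos.size * neg.size))


def _stratified_split(
    members: np.ndarray,
    bins: np.ndarray,
    train_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split one class's (randomly ordered) members 60/40 within age bins.

    Randomness comes from the caller-permuted member order; within each age
    bin the first ~60% of that order go to train."""
    b = bins[members]
    order = np.argsort(b, kind="stable")
    s = members[order]
    bs = b[order]
    starts = np.flatnonzero(np.r_[True, bs[1:] != bs[:-1]])
    ends = np.r_[starts[1:], s.size]
    take = np.zeros(s.size, dtype=bool)
    for start, end in zip(starts, ends):
        n_tr = int(round(train_fraction * (end - start)))
        take[start : start + n_tr] = True
    train, test = s[take], s[~take]
    # every class must appear in both halves
    if train.size == 0:
        train, test = test[:1], test[1:]
    if test.size == 0:
        train, test = train[:-1], train[-1:]
    return train, test


def _balanced_split(
    rng: np.random.Generator,
    idx_young: np.ndarray,
    idx_old: np.ndarray,
    m: int,
    bins: np.ndarray,
    train_fraction: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One balanced permutation: subsample each class to ``m``, split 60/40.

    Returns (train_young, test_young, train_old, test_old) sample indices;
    each class contributes exactly ``m`` samples in total.
    """
    sub_y = rng.permutation(idx_young)[:m]
    sub_o = rng.permutation(idx_old)[:m]
    tr_y, te_y = _stratified_split(sub_y, bins, train_fraction)
    tr_o, te_o = _stratified_split(sub_o, bins, train_fraction)
    return tr_y, te_y, tr_o, te_o


def balanced_auc(
    values: np.ndarray | pd.Series,
    is_young: np.ndarray,
    ages: np.ndarray | None = None,
    config: ThresholdScanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean train/test ROC AUC of a single-gene classifier over balanced permutations.

    Per permutation the majority class is subsampled without replacement to
    the minority size, the balanced set is split train/test (default 60/40,
    stratified on age quartiles within each class when ``ages`` is given),
    the score orientation is learned on the training half, and ROC AUC of the
    oriented expression score is computed on both halves.

    Returns ``(auc_train_mean, auc_test_mean)``; young is the positive class.
    """
    config = config or ThresholdScanConfig()
    x = np.asarray(values, dtype=float)
    y = np.asarray(is_young, dtype=bool)
    if x.shape != y.shape:
        raise ValidationError("values and labels must align")
    n_young, n_old = int(y.sum()), int((~y).sum())
    if n_young == 0 or n_old == 0:
        raise ValidationError("both classes must be non-empty")
    if np.ptp(x) == 0:
        warnings.warn("constant expression vector; AUC defined as 0.5", stacklevel=2)
        return 0.5, 0.5
    if min(n_young, n_old) < config.min_class_size:
        warnings.warn(
            f"minority class has {min(n_young, n_old)} < {config.min_class_size} "
            "samples; AUC estimate is unstable",
            stacklevel=2,
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if ages is not None:
        quartiles = np.quantile(np.asarray(ages, dtype=float), [0.25, 0.5, 0.75])
        bins = np.searchsorted(quartiles, np.asarray(ages, dtype=float))
    else:
        bins = np.zeros(x.size, dtype=int)

    idx_young = np.flatnonzero(y)
    idx_old = np.flatnonzero(~y)
    m = min(n_young, n_old)
    tr_sum = te_sum = 0.0
    for _ in range(config.n_perm):
        tr_y, te_y, tr_o, te_o = _balanced_split(
            rng, idx_young, idx_old, m, bins, config.train_fraction
        )
        train = np.concatenate([tr_y, tr_o])
        test = np.concatenate([te_y, te_o])
        direction = np.sign(x[tr_y].mean() - x[tr_o].mean())
        if direction == 0:
            tr_sum += 0.5
            te_sum += 0.5
            continue
        score = direction * x
        tr_sum += _rank_auc(score[train], y[train])
        te_sum += _rank_auc(score[test], y[test])
    return tr_sum / config.n_perm, te_sum / config.n_perm


@dataclass
class ThresholdScanResult:
    """Long-format grid of per-(cutoff, gene) scan statistics."""

    table: pd.DataFrame  # columns: cutoff, gene, p_value, log2FC, auc_train_mean, auc_test_mean, n_young, n_old
    skipped_cutoffs: list[int] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)
    config: ThresholdScanConfig | None = None

    def wide(self, metric: str) -> pd.DataFrame:
        """Heat-map-ready cutoff x gene table of one metric."""
        if metric not in self.table.columns:
            raise ValidationError(f"unknown metric {metric!r}")
        return self.table.pivot(index="cutoff", columns="gene", values=metric)

    def write(self, directory: str | Path, stem: str = "threshold_scan") -> list[Path]:
        """Write the long table plus four wide tables (p, log2FC, train/test AUC)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = [directory / f"{stem}_long.tsv"]
        self.table.to_csv(paths[0], sep="\t", index=False)
        for metric in ("p_value", "log2FC", "auc_train_mean", "auc_test_mean"):
            path = directory / f"{stem}_{metric}.tsv"
            self.wide(metric).to_csv(path, sep="\t")
            paths.append(path)
        return paths

    def plot_heatmaps(self, path: str | Path) -> Path:
        """Optional PNG with the four scan heat maps (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(12, 9), constrained_layout=True)
        metrics = ("auc_train_mean", "auc_test_mean", "log2FC", "p_value")
        for ax, metric in zip(axes.ravel(), metrics):
            wide = self.wide(metric)
            im = ax.imshow(wide.to_numpy(), aspect="auto", origin="lower")
            ax.set_xticks(range(len(wide.columns)), wide.columns, rotation=90, fontsize=6)
            step = max(len(wide.index) // 15, 1)
            ax.set_yticks(range(0, len(wide.index), step), wide.index[::step], fontsize=6)
            ax.set_title(metric)
            ax.set_ylabel("age cutoff (years)")
            fig.colorbar(im, ax=ax)
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def scan_thresholds(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    panel: GenePanel,
    config: ThresholdScanConfig | None = None,
) -> ThresholdScanResult:
    """Evaluate every candidate age cutoff for every panel gene.

    For each cutoff in ``[cutoff_min, cutoff_max]`` with at least
    ``min_class_size`` samples in each class: Welch t-test p, log2FC
    (mean young - mean old), and balanced-subsampling train/test AUC per
    panel gene.  Permutation streams are seeded per (seed, cutoff, gene), so
    individual cells are reproducible in isolation.
    """
    config = config or ThresholdScanConfig()
    present, dropped = panel.resolve(expr)
    annot = annot.loc[expr.columns]
    ages = annot["age"].to_numpy(dtype=float)
    values = expr.loc[present].to_numpy(dtype=float)

    rows = []
    skipped: list[int] = []
    for cutoff in range(config.cutoff_min, config.cutoff_max + 1):
        is_young = ages <= cutoff
        n_young, n_old = int(is_young.sum()), int((~is_young).sum())
        if min(n_young, n_old) < config.min_class_size:
            skipped.append(cutoff)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(
                values[:, is_young], values[:, ~is_young], axis=1, equal_var=False
            )
        p = np.where(np.isnan(p), 1.0, p)
        log2fc = values[:, is_young].mean(axis=1) - values[:, ~is_young].mean(axis=1)
        for gi, gene in enumerate(present):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(config.seed), int(cutoff), gi))
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                auc_tr, auc_te = balanced_auc(
                    values[gi], is_young, ages=ages, config=config, rng=rng
                )
            rows.append(
                (cutoff, gene, float(p[gi]), float(log2fc[gi]), auc_tr, auc_te, n_young, n_old)
            )
    if not rows:
        raise ValidationError("no evaluable cutoff in the configured range")
    table = pd.DataFrame(
        rows,
        columns=[
            "cutoff", "gene", "p_value", "log2FC",
            "auc_train_mean", "auc_test_mean", "n_young", "n_old",
        ],
    )
    return ThresholdScanResult(
        table=table, skipped_cutoffs=skipped, dropped_genes=dropped, config=config
    )


@dataclass(frozen=True)
class CutoffSelection:
    cutoff: int
    n_significant: int
    mean_test_auc_significant: float
    fallback: bool = False  # no cutoff had any significant gene


def select_cutoff(result: ThresholdScanResult, alpha: float = 0.05) -> CutoffSelection:
    """Pick the cutoff with the most significant panel genes.

    Primary criterion: maximum count of panel genes with p < alpha.  Ties go
    to the cutoff with the higher mean test AUC over its significant genes,
    then to the smaller cutoff.  If no cutoff yields any significant gene the
    cutoff maximising the mean test AUC over all genes is returned with the
    ``fallback`` flag set.
    """
    table = result.table
    if table.empty:
        raise ValidationError("empty scan result")
    sig = table[table["p_value"] < alpha]
    if sig.empty:
        warnings.warn(
            "no significant gene at any cutoff; falling back to max mean test AUC",
            stacklevel=2,
        )
        by_auc = table.groupby("cutoff")["auc_test_mean"].mean()
        cutoff = int(by_auc.idxmax())
        return CutoffSelection(
            cutoff=cutoff,
            n_significant=0,
            mean_test_auc_significant=float(by_auc.max()),
            fallback=True,
        )
    counts = sig.groupby("cutoff").size()
    aucs = sig.groupby("cutoff")["auc_test_mean"].mean()
    ranking = pd.DataFrame({"n_sig": counts, "auc": aucs}).reset_index()
    ranking = ranking.sort_values(
        ["n_sig", "auc", "cutoff"], ascending=[False, False, True], kind="stable"
    )
    best = ranking.iloc[0]
    return CutoffSelection(
        cutoff=int(best["cutoff"]),
        n_significant=int(best["n_sig"]),
        mean_test_auc_significant=float(best["auc"]),
    )
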
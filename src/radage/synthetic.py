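"""Synthetic blood-transcriptome cohorts with known age, dose and batch structure.

Every downstream stage of the pipeline (cutoff scan, dose-bin contrasts,
interaction screen, disease filter) is exercised against matrices produced
here, where the true generative effects are known.  The generative model per
gene g and sample s is additive on the log2 scale::

    y[g, s] = baseline + age_term(s) * age_effect[g]
              + dose(s) * dose_effect[g]
              + age_term(s) * dose(s) * interaction_effect[g]
              + batch_shift[batch(s)] + N(0, noise_sd^2)

where ``age_term`` is the centred age in years (``linear`` mode) or the
young-class indicator ``1{age <= true_cutoff}`` (``step`` mode).

Ages are sampled uniformly over the design's age range so that every candidate
cutoff in a threshold scan has support on both sides.  Doses are drawn from a
discrete set of gray (Gy) levels with sampling weights; noise is Gaussian on
the log2 scale, the standard approximation for processed microarray values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortDesign",
    "EffectSpec",
    "DiseaseDesign",
    "MarkerSpec",
    "simulate_cohort",
    "simulate_disease_cohort",
    "add_batch_effect",
    "write_expression",
    "write_annotations",
    "write_cohort",
    "AGING_PANEL",
    "CANDIDATE_PANEL",
    "age_cohort_design",
    "radiation_cohort_design",
    "interaction_cohort_design",
    "lung_disease_design",
]

# 12-gene blood aging panel used by the cutoff scan (a further four candidate
# markers -- GATA6, RIPK1, CDKN1A, RIPK3 -- are routinely absent from blood
# array platforms and are kept in CANDIDATE_PANEL to exercise panel matching).
AGING_PANEL: tuple[str, ...] = (
    "CDKN2A", "FOXO1", "SIRT1", "IL6", "TFAM", "MTOR",
    "TSC1", "TP53", "SIRT6", "MLKL", "ALOX15B", "TNFAIP3",
)
CANDIDATE_PANEL: tuple[str, ...] = AGING_PANEL + ("GATA6", "RIPK1", "CDKN1A", "RIPK3")


class DesignError(ValueError):
    """Raised when a cohort design or effect specification is invalid."""


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design for one simulated cohort.

    Parameters
    ----------
    n_samples, n_genes
        Cohort and matrix dimensions.
    age_range
        (min, max) age in years, uniform sampling; must lie within [18, 90].
    dose_levels
        Mapping of absorbed dose in Gy -> sampling weight; weights must sum
        to 1 and doses must be >= 0.
    sex_ratio
        Fraction of male samples.
    batch_sizes
        Number of samples per batch; must sum to ``n_samples``.  Batches are
        labelled ``batch_labels`` (defaults to B1, B2, ...).
    batch_shifts
        Additive per-batch offsets in log2 units, aligned with batches.
    noise_sd
        Gaussian noise standard deviation, log2 units, > 0.
    baseline_mean
        Grand-mean expression in log2 units.
    gene_ids
        Optional explicit row identifiers (e.g. to place panel genes).
    """

    n_samples: int
    n_genes: int
    age_range: tuple[float, float] = (21.0, 69.0)
    dose_levels: Mapping[float, float] = field(default_factory=lambda: {0.0: 1.0})
    sex_ratio: float = 0.5
    batch_sizes: tuple[int, ...] | None = None
    batch_shifts: tuple[float, ...] | None = None
    batch_labels: tuple[str, ...] | None = None
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    gene_ids: tuple[str, ...] | None = None
    paired_donors: bool = False

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise DesignError("n_samples and n_genes must be positive")
        lo, hi = self.age_range
        if not (lo < hi):
            raise DesignError(f"age_range min must be < max, got {self.age_range}")
        if lo < 18 or hi > 90:
            raise DesignError(f"age_range must lie within [18, 90], got {self.age_range}")
        if any(d < 0 for d in self.dose_levels):
            raise DesignError("dose levels must be >= 0 Gy")
        total = float(sum(self.dose_levels.values()))
        if abs(total - 1.0) > 1e-9:
            raise DesignError(f"dose weights must sum to 1, got {total}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise DesignError("sex_ratio must be in [0, 1]")
        if self.noise_sd <= 0:
            raise DesignError("noise_sd must be > 0")
        if self.batch_sizes is not None and sum(self.batch_sizes) != self.n_samples:
            raise DesignError("batch_sizes must sum to n_samples")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise DesignError("gene_ids length must equal n_genes")

    @property
    def resolved_batches(self) -> tuple[tuple[str, ...], tuple[int, ...], tuple[float, ...]]:
        sizes = self.batch_sizes if self.batch_sizes is not None else (self.n_samples,)
        labels = self.batch_labels if self.batch_labels is not None else tuple(
            f"B{i + 1}" for i in range(len(sizes))
        )
        shifts = self.batch_shifts if self.batch_shifts is not None else (0.0,) * len(sizes)
        if not (len(labels) == len(sizes) == len(shifts)):
            raise DesignError("batch labels, sizes and shifts must have equal length")
        return labels, sizes, shifts

    @property
    def resolved_gene_ids(self) -> tuple[str, ...]:
        if self.gene_ids is not None:
            return self.gene_ids
        return tuple(f"GENE{i + 1:05d}" for i in range(self.n_genes))


@dataclass(frozen=True)
class EffectSpec:
    """Per-gene generative effect: age mode/size, dose slope and interaction."""

    gene_index: int
    age_mode: str = "none"  # none | linear | step
    age_effect: float = 0.0  # log2 per year (linear) or step height (step)
    true_cutoff: float | None = None  # years, required for step mode
    dose_effect: float = 0.0  # log2 per Gy (or per ordinal bin, caller's choice)
    interaction_effect: float = 0.0  # log2 units on the age_term * dose product

    def validate(self, design: CohortDesign) -> None:
        if not 0 <= self.gene_index < design.n_genes:
            raise DesignError(
                f"gene_index {self.gene_index} outside [0, {design.n_genes})"
            )
        if self.age_mode not in ("none", "linear", "step"):
            raise DesignError(f"unknown age_mode {self.age_mode!r}")
        if self.age_mode == "step":
            if self.true_cutoff is None:
                raise DesignError("step mode requires true_cutoff")
            lo, hi = design.age_range
            if not (lo <= self.true_cutoff <= hi):
                raise DesignError(
                    f"true_cutoff {self.true_cutoff} outside age_range {design.age_range}"
                )


def simulate_cohort(
    design: CohortDesign,
    effects: Sequence[EffectSpec] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (expression genes x samples, annotations).

    The expression matrix is a DataFrame indexed by gene id with sample-id
    columns; annotations are indexed by sample id and carry age, dose_Gy,
    sex, batch and (optionally) donor columns.  Fixed seed gives bit-identical
    output.
    """
    for eff in effects:
        eff.validate(design)
    rng = np.random.default_rng(seed)
    n, g = design.n_samples, design.n_genes
    labels, sizes, shifts = design.resolved_batches

    lo, hi = design.age_range
    ages = np.round(rng.uniform(lo, hi, size=n)).astype(int)
    ages = np.clip(ages, int(np.ceil(lo)), int(np.floor(hi)))
    doses = rng.choice(
        np.array(list(design.dose_levels), dtype=float),
        size=n,
        p=np.array(list(design.dose_levels.values()), dtype=float),
    )
    sexes = np.where(rng.random(n) < design.sex_ratio, "male", "female")
    batch = np.repeat(np.array(labels, dtype=object), sizes)
    batch_shift = np.repeat(np.asarray(shifts, dtype=float), sizes)

    values = np.full((g, n), design.baseline_mean, dtype=float)
    mean_age = ages.mean()
    for eff in effects:
        if eff.age_mode == "linear":
            age_term = ages - mean_age
        elif eff.age_mode == "step":
            age_term = (ages <= eff.true_cutoff).astype(float)
        else:
            age_term = np.zeros(n)
        row = (
            eff.age_effect * age_term
            + eff.dose_effect * doses
            + eff.interaction_effect * age_term * doses
        )
        values[eff.gene_index] += row
    values += batch_shift[np.newaxis, :]
    values += rng.normal(0.0, design.noise_sd, size=(g, n))

    sample_ids = [f"{batch[i]}_S{i + 1:04d}" for i in range(n)]
    expr = pd.DataFrame(values, index=list(design.resolved_gene_ids), columns=sample_ids)
    expr.index.name = "gene_id"
    annot = pd.DataFrame(
        {
            "age": ages,
            "dose_Gy": doses,
            "sex": sexes,
            "batch": batch,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if design.paired_donors:
        # Ex-vivo repeated-exposure layout: donors cycle within each batch.
        donor = np.empty(n, dtype=object)
        start = 0
        for lab, size in zip(labels, sizes):
            donor[start : start + size] = [
                f"{lab}_D{(j % max(size // 4, 1)) + 1:03d}" for j in range(size)
            ]
            start += size
        annot["donor"] = donor
    return expr, annot


@dataclass(frozen=True)
class MarkerSpec:
    """Additive shifts for one disease-cohort marker gene.

    Each mapping sends a factor level (or a tuple of levels for interactions)
    to a log2 shift applied to samples carrying those labels.
    """

    gene: str
    disease: Mapping[str, float] = field(default_factory=dict)
    ethnicity: Mapping[str, float] = field(default_factory=dict)
    sex: Mapping[str, float] = field(default_factory=dict)
    disease_x_ethnicity: Mapping[tuple[str, str], float] = field(default_factory=dict)
    disease_x_sex: Mapping[tuple[str, str], float] = field(default_factory=dict)
    ethnicity_x_sex: Mapping[tuple[str, str], float] = field(default_factory=dict)
    three_way: Mapping[tuple[str, str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class DiseaseDesign:
    """Design for the lung-disease evaluation cohort with train/test/validation splits."""

    n_per_split: tuple[int, int, int]
    disease_levels: tuple[str, ...]
    ethnicity_levels: tuple[str, ...]
    sex_levels: tuple[str, ...] = ("male", "female")
    disease_weights: tuple[float, ...] | None = None
    ethnicity_weights: tuple[float, ...] | None = None
    sex_weights: tuple[float, ...] | None = None
    marker_specs: tuple[MarkerSpec, ...] = ()
    n_genes: int = 500
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.n_per_split) != 3 or any(k <= 0 for k in self.n_per_split):
            raise DesignError("n_per_split must be three positive counts (train, test, validation)")
        for name, levels in (
            ("disease", self.disease_levels),
            ("ethnicity", self.ethnicity_levels),
            ("sex", self.sex_levels),
        ):
            if len(levels) == 0:
                raise DesignError(f"{name}_levels must be non-empty")
        for name, levels, weights in (
            ("disease", self.disease_levels, self.disease_weights),
            ("ethnicity", self.ethnicity_levels, self.ethnicity_weights),
            ("sex", self.sex_levels, self.sex_weights),
        ):
            if weights is not None and len(weights) != len(levels):
                raise DesignError(f"{name}_weights length must match {name}_levels")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise DesignError("gene_ids length must equal n_genes")
        known = set(self.resolved_gene_ids)
        for spec in self.marker_specs:
            if spec.gene not in known:
                raise DesignError(f"marker gene {spec.gene!r} not among gene ids")

    @property
    def resolved_gene_ids(self) -> tuple[str, ...]:
        if self.gene_ids is not None:
            return self.gene_ids
        return tuple(f"GENE{i + 1:05d}" for i in range(self.n_genes))


def _draw_labels(
    rng: np.random.Generator,
    n: int,
    levels: Sequence[str],
    weights: Sequence[float] | None,
) -> np.ndarray:
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=p)


def simulate_disease_cohort(
    design: DiseaseDesign, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a disease cohort with disease/ethnicity/sex/split labels.

    Marker genes are shifted additively according to their ``MarkerSpec``;
    all other genes are exchangeable across labels.
    """
    rng = np.random.default_rng(seed)
    splits = ("train", "test", "validation")
    n_total = sum(design.n_per_split)
    split = np.repeat(np.array(splits, dtype=object), design.n_per_split)
    disease = _draw_labels(rng, n_total, design.disease_levels, design.disease_weights)
    ethnicity = _draw_labels(rng, n_total, design.ethnicity_levels, design.ethnicity_weights)
    sex = _draw_labels(rng, n_total, design.sex_levels, design.sex_weights)

    gene_ids = list(design.resolved_gene_ids)
    g = design.n_genes
    values = rng.normal(design.baseline_mean, design.noise_sd, size=(g, n_total))
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for spec in design.marker_specs:
        row = np.zeros(n_total)
        for level, shift in spec.disease.items():
            row += np.where(disease == level, shift, 0.0)
        for level, shift in spec.ethnicity.items():
            row += np.where(ethnicity == level, shift, 0.0)
        for level, shift in spec.sex.items():
            row += np.where(sex == level, shift, 0.0)
        for (d, e), shift in spec.disease_x_ethnicity.items():
            row += np.where((disease == d) & (ethnicity == e), shift, 0.0)
        for (d, s), shift in spec.disease_x_sex.items():
            row += np.where((disease == d) & (sex == s), shift, 0.0)
        for (e, s), shift in spec.ethnicity_x_sex.items():
            row += np.where((ethnicity == e) & (sex == s), shift, 0.0)
        for (d, e, s), shift in spec.three_way.items():
            row += np.where((disease == d) & (ethnicity == e) & (sex == s), shift, 0.0)
        values[gene_pos[spec.gene]] += row

    sample_ids = [f"D_{split[i][:2].upper()}_S{i + 1:04d}" for i in range(n_total)]
    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    expr.index.name = "gene_id"
    annot = pd.DataFrame(
        {
            "disease": disease,
            "ethnicity": ethnicity,
            "sex": sex,
            "split": split,
            "batch": "D1",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return expr, annot


def add_batch_effect(
    expr: pd.DataFrame, annot: pd.DataFrame, shifts: Mapping[str, float]
) -> pd.DataFrame:
    """Return a copy of ``expr`` with per-batch additive log2 offsets applied."""
    batches = annot.loc[expr.columns, "batch"]
    unknown = sorted(set(batches) - set(shifts))
    if unknown:
        raise DesignError(f"no shift provided for batch(es): {', '.join(unknown)}")
    offsets = batches.map(shifts).to_numpy(dtype=float)
    return expr + offsets[np.newaxis, :]


# ---------------------------------------------------------------------------
# Tab-delimited writers (the ingest module's readers accept these layouts).

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def write_annotations(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="sample_id")


def write_cohort(
    expr: pd.DataFrame, annot: pd.DataFrame, directory: str | Path, name: str
) -> tuple[Path, Path]:
    """Write one cohort as <name>_expression.tsv / <name>_annotations.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    epath = directory / f"{name}_expression.tsv"
    apath = directory / f"{name}_annotations.tsv"
    write_expression(expr, epath)
    write_annotations(annot, apath)
    return epath, apath


# ---------------------------------------------------------------------------
# Default study-condition designs.  Cohort sizes, age spans, dose levels and
# the disease-cohort factor structure mirror the multi-study blood-transcriptome
# layout the pipeline targets: two healthy ageing cohorts (76 + 301 samples,
# ages 21-69), three gamma-irradiated cohorts (20 + 48 + 95 samples, doses
# 0/0.1/0.5/2 Gy), and a 236-sample lung-disease cohort pre-split into
# train/test/validation (93/102/41).

def _panel_gene_ids(n_genes: int) -> tuple[str, ...]:
    fillers = tuple(f"GENE{i + 1:05d}" for i in range(n_genes - len(AGING_PANEL)))
    return AGING_PANEL + fillers


def age_cohort_design(
    n_genes: int = 500,
    true_cutoff: float = 29.0,
    noise_sd: float = 1.0,
) -> tuple[CohortDesign, tuple[EffectSpec, ...]]:
    """Two healthy cohorts (76 + 301 samples) with a heterogeneous aging panel.

    Five panel genes carry a step change of varying sign and size at the true
    cutoff, three drift weakly linearly with age, and the remaining four are
    null -- aging markers are not uniformly informative in blood, and a mixed
    panel keeps the cutoff scan's significant-gene count from saturating.
    """
    design = CohortDesign(
        n_samples=377,
        n_genes=n_genes,
        age_range=(21, 69),
        dose_levels={0.0: 1.0},
        batch_sizes=(76, 301),
        batch_labels=("A1", "A2"),
        batch_shifts=(0.0, 0.5),
        noise_sd=noise_sd,
        gene_ids=_panel_gene_ids(n_genes),
    )
    step_sizes = (0.8, -0.8, 0.6, -0.6, 1.0)
    linear_slopes = (0.006, -0.006, 0.009)
    effects = tuple(
        EffectSpec(
            gene_index=i, age_mode="step", age_effect=delta, true_cutoff=true_cutoff
        )
        for i, delta in enumerate(step_sizes)
    ) + tuple(
        EffectSpec(gene_index=len(step_sizes) + j, age_mode="linear", age_effect=slope)
        for j, slope in enumerate(linear_slopes)
    )
    return design, effects


def radiation_cohort_design(
    n_genes: int = 500, n_dose_responsive: int = 40, dose_effect: float = 0.6
) -> tuple[CohortDesign, tuple[EffectSpec, ...]]:
    """Three irradiated cohorts (20 + 48 + 95 = 163 samples), doses 0-2 Gy.

    Dose-level weights follow the pooled bin occupancy of the emulated studies
    (58 control, 24 low, 48 medium, 33 high of 163).
    """
    design = CohortDesign(
        n_samples=163,
        n_genes=n_genes,
        age_range=(21, 64),
        dose_levels={0.0: 58 / 163, 0.1: 24 / 163, 0.5: 48 / 163, 2.0: 33 / 163},
        batch_sizes=(20, 48, 95),
        batch_labels=("R1", "B1", "B2"),
        batch_shifts=(0.0, 0.3, -0.3),
        noise_sd=1.0,
        gene_ids=_panel_gene_ids(n_genes),
    )
    start = len(AGING_PANEL)
    n_dose_responsive = min(n_dose_responsive, max(n_genes - start, 0))
    effects = tuple(
        EffectSpec(gene_index=start + i, dose_effect=dose_effect)
        for i in range(n_dose_responsive)
    )
    return design, effects


def interaction_cohort_design(
    n_genes: int = 500,
    n_interacting: int = 20,
    interaction_effect: float = 0.8,
    true_cutoff: float = 29.0,
) -> tuple[CohortDesign, tuple[EffectSpec, ...]]:
    """Two cohorts with both age and dose recorded (48 + 95 = 143 samples)."""
    design = CohortDesign(
        n_samples=143,
        n_genes=n_genes,
        age_range=(21, 64),
        dose_levels={0.0: 48 / 143, 0.1: 24 / 143, 0.5: 48 / 143, 2.0: 23 / 143},
        batch_sizes=(48, 95),
        batch_labels=("B1", "B2"),
        batch_shifts=(0.2, -0.2),
        noise_sd=1.0,
        gene_ids=_panel_gene_ids(n_genes),
    )
    start = min(len(AGING_PANEL) + 40, max(n_genes - n_interacting, 0))
    n_interacting = min(n_interacting, max(n_genes - start, 0))
    effects = tuple(
        EffectSpec(
            gene_index=start + i,
            age_mode="step",
            age_effect=0.3,
            true_cutoff=true_cutoff,
            interaction_effect=interaction_effect,
        )
        for i in range(n_interacting)
    )
    return design, effects


def default_disease_markers() -> tuple[MarkerSpec, ...]:
    """Markers inside the interaction-responsive gene block (GENE00041-60).

    The disease cohort is only informative about the rad-age gene list if some
    of those genes actually differentiate lung disease; these markers carry
    strong shifts along two demographic axes each (so the cross-split filter's
    two-test-case rule is satisfiable) and one carries a pure three-way
    disease x ethnicity x sex offset.  Two weaker markers are included that
    should fail the fold-change gate.
    """
    return (
        MarkerSpec(
            gene="GENE00041",
            disease={"TB": 3.0},
            sex={"male": 3.0},
            three_way={("TB", "Caucasian", "male"): 2.0},
        ),
        MarkerSpec(gene="GENE00042", disease={"TB": 3.0}, ethnicity={"Caucasian": 3.0}),
        MarkerSpec(
            gene="GENE00043",
            disease={"active sarcoidosis": 3.0},
            ethnicity={"African": 3.0},
        ),
        MarkerSpec(gene="GENE00044", disease={"TB": 3.0}, sex={"male": -3.0}),
        MarkerSpec(gene="GENE00045", disease={"TB": 1.5}),
        MarkerSpec(gene="GENE00046", ethnicity={"African": 1.2}),
        MarkerSpec(gene="GENE00047", disease={"TB": 3.0}, ethnicity={"African": 3.0}),
        MarkerSpec(
            gene="GENE00048",
            disease={"active sarcoidosis": 3.0},
            sex={"male": 3.0},
        ),
    )


def lung_disease_design(
    n_genes: int = 500, marker_specs: tuple[MarkerSpec, ...] | None = None
) -> DiseaseDesign:
    """236-sample lung-disease cohort split 93/102/41 across train/test/validation.

    Factor-level weights follow the cohort's marginal composition: control-heavy
    disease mix, predominantly Caucasian/African/Indian-subcontinent ethnicity,
    and a mild female excess.  Default markers (see
    :func:`default_disease_markers`) are used when ``marker_specs`` is None;
    pass ``()`` for a fully null cohort.
    """
    if marker_specs is None:
        marker_specs = default_disease_markers() if n_genes >= 60 else ()
    return DiseaseDesign(
        n_per_split=(93, 102, 41),
        disease_levels=(
            "control", "pneumonia", "TB", "active sarcoidosis",
            "non-active sarcoidosis", "lung cancer",
        ),
        disease_weights=(121, 6, 35, 37, 21, 16),
        ethnicity_levels=(
            "Central Asia", "SE Asia", "Indian subcontinent",
            "Middle Eastern", "Caucasian", "African",
        ),
        ethnicity_weights=(1, 3, 36, 2, 135, 58),
        sex_levels=("male", "female"),
        sex_weights=(106, 130),
        marker_specs=marker_specs,
        n_genes=n_genes,
        gene_ids=_panel_gene_ids(n_genes),
    )
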
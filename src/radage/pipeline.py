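"""End-to-end orchestration: ingest -> cutoff scan -> contrasts -> interaction
screen -> preranked export -> disease filter -> three-way report.

A single global seed is fanned out to per-stage seeds through named
``numpy.random.SeedSequence`` spawn keys, so any stage can be re-run in
isolation with the same stream.  Every output file is tab-delimited or JSON
and listed in a manifest with SHA-256 checksums; headline numbers (selected
cutoff, per-stage gene counts) go to a machine-readable ``summary.json``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffexp, disease, interaction, preprocess, synthetic, threshold

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage:{stage}] {message}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence((int(global_seed), key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Each cohort slot (age, radiation, interaction, disease) is either the
    string ``"synthetic"`` or a mapping with ``expression`` and
    ``annotations`` paths to tab-delimited tables.
    """

    out_dir: str | Path = "radage_results"
    seed: int = 0
    n_genes: int = 500
    cohorts: Mapping[str, Any] = field(
        default_factory=lambda: {
            "age": "synthetic",
            "radiation": "synthetic",
            "interaction": "synthetic",
            "disease": "synthetic",
        }
    )
    scan: Mapping[str, Any] = field(default_factory=dict)  # ThresholdScanConfig kwargs
    interaction_alpha: float = 0.05
    filter: Mapping[str, Any] = field(default_factory=dict)  # CandidateFilterConfig kwargs
    outlier_k: float = 6.0
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def scan_config(self) -> threshold.ThresholdScanConfig:
        kwargs = dict(self.scan)
        kwargs.setdefault("seed", stage_seed(self.seed, "scan"))
        return threshold.ThresholdScanConfig(**kwargs)

    def filter_config(self) -> disease.CandidateFilterConfig:
        return disease.CandidateFilterConfig(**dict(self.filter))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(
    slot: str, spec: Any, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    seed = stage_seed(config.seed, f"simulate:{slot}")
    if spec == "synthetic":
        if slot == "age":
            design, effects = synthetic.age_cohort_design(n_genes=config.n_genes)
            return synthetic.simulate_cohort(design, effects, seed=seed)
        if slot == "radiation":
            design, effects = synthetic.radiation_cohort_design(n_genes=config.n_genes)
            return synthetic.simulate_cohort(design, effects, seed=seed)
        if slot == "interaction":
            design, effects = synthetic.interaction_cohort_design(n_genes=config.n_genes)
            return synthetic.simulate_cohort(design, effects, seed=seed)
        if slot == "disease":
            design = synthetic.lung_disease_design(n_genes=config.n_genes)
            return synthetic.simulate_disease_cohort(design, seed=seed)
        raise PipelineError("ingest", f"unknown cohort slot {slot!r}")
    if isinstance(spec, Mapping) and {"expression", "annotations"} <= set(spec):
        try:
            return preprocess.read_expression_table(spec["expression"], spec["annotations"])
        except FileNotFoundError as exc:
            raise PipelineError("ingest", f"cohort {slot!r}: missing file {exc}") from exc
        except preprocess.ValidationError as exc:
            raise PipelineError("ingest", f"cohort {slot!r}: {exc}") from exc
    raise PipelineError(
        "ingest",
        f"cohort {slot!r} must be 'synthetic' or a mapping with "
        f"expression/annotations paths, got {spec!r}",
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the run report (also written as JSON).

    The report contains a ``summary`` block of headline numbers and a
    ``manifest`` listing every emitted file with its SHA-256 checksum.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    summary: dict[str, Any] = {"seed": int(config.seed)}

    def emit(path: Path) -> None:
        artifacts.append(path)

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest = [
            {"path": str(p.relative_to(out)), "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in artifacts
        ]
        (out / "partial_manifest.json").write_text(json.dumps(manifest, indent=1))
        return PipelineError(stage, str(exc))

    # --- ingest -----------------------------------------------------------
    try:
        cohorts = {
            slot: _load_cohort(slot, spec, config)
            for slot, spec in config.cohorts.items()
        }
        processed: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
        for slot, (expr, annot) in cohorts.items():
            if slot == "disease":
                processed[slot] = (expr, annot)
                continue
            outliers = preprocess.detect_outlier_samples(expr, config.outlier_k)
            if outliers:
                expr = expr.drop(columns=outliers)
                annot = annot.drop(index=outliers)
            protect_cols = [c for c in ("age", "dose_Gy") if c in annot.columns]
            if annot["batch"].nunique() > 1:
                expr = preprocess.remove_batch_effect(
                    expr, annot["batch"], annot[protect_cols] if protect_cols else None
                )
            annot = preprocess.annotate_bins_and_age(annot)
            processed[slot] = (expr, annot)
            summary[f"n_samples_{slot}"] = int(expr.shape[1])
            summary[f"n_outliers_removed_{slot}"] = len(outliers)
        expr_d, annot_d = processed["disease"]
        summary["n_samples_disease"] = int(expr_d.shape[1])
        for slot, (expr, annot) in processed.items():
            emit(_write_tsv(annot, out / f"cohort_{slot}_annotations.tsv"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage tag
        raise fail("ingest", exc) from exc

    # --- age-threshold scan ----------------------------------------------
    try:
        expr_a, annot_a = processed["age"]
        panel = threshold.GenePanel(synthetic.CANDIDATE_PANEL)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = threshold.scan_thresholds(expr_a, annot_a, panel, config.scan_config())
        selection = threshold.select_cutoff(scan, alpha=config.scan_config().alpha)
        for p in scan.write(out, stem="threshold_scan"):
            emit(p)
        summary["selected_cutoff_years"] = selection.cutoff
        summary["n_significant_at_cutoff"] = selection.n_significant
        summary["mean_test_auc_significant"] = round(selection.mean_test_auc_significant, 6)
        cutoff = float(selection.cutoff)
    except Exception as exc:  # noqa: BLE001
        raise fail("threshold_scan", exc) from exc

    # --- contrast battery -------------------------------------------------
    try:
        expr_r, annot_r = processed["radiation"]
        annot_r = preprocess.annotate_bins_and_age(annot_r, cutoff=cutoff)
        annot_a2 = preprocess.annotate_bins_and_age(annot_a, cutoff=cutoff)
        shared = expr_a.index.intersection(expr_r.index)
        combined_expr = pd.concat([expr_a.loc[shared], expr_r.loc[shared]], axis=1)
        combined_annot = pd.concat([annot_a2, annot_r])
        rad_tables = diffexp.run_contrasts(
            expr_r,
            annot_r,
            diffexp.ContrastSet(tuple(diffexp.default_contrasts().contrasts[:4])),
        )
        demo_tables = diffexp.run_contrasts(
            combined_expr,
            combined_annot,
            diffexp.ContrastSet(tuple(diffexp.default_contrasts().contrasts[4:])),
        )
        tables = {**rad_tables, **demo_tables}
        for name, table in tables.items():
            emit(_write_tsv(table, out / f"contrast_{name}.tsv"))
        summary["n_contrasts_run"] = len(tables)
        summary["n_significant_per_contrast"] = {
            name: int((t["fdr"] < 0.05).sum()) for name, t in tables.items()
        }
        if len(tables) >= 2:
            inter = diffexp.intersect_significant(tables, alpha_on_q=0.05)
            emit(_write_tsv(inter, out / "contrast_intersections.tsv", index=False))
    except Exception as exc:  # noqa: BLE001
        raise fail("contrasts", exc) from exc

    # --- interaction screen ----------------------------------------------
    try:
        expr_i, annot_i = processed["interaction"]
        annot_i = preprocess.annotate_bins_and_age(annot_i, cutoff=cutoff)
        sig_cont, tab_cont = interaction.run_interaction_screen(
            expr_i, annot_i, age_mode="continuous",
            alpha=config.interaction_alpha, cutoff=cutoff,
        )
        sig_cat, tab_cat = interaction.run_interaction_screen(
            expr_i, annot_i, age_mode="categorical",
            alpha=config.interaction_alpha, cutoff=cutoff,
        )
        union = interaction.union_interaction_genes(sig_cont, sig_cat)
        emit(_write_tsv(tab_cont, out / "interaction_continuous.tsv"))
        emit(_write_tsv(tab_cat, out / "interaction_categorical.tsv"))
        (out / "interaction_union_genes.txt").write_text("\n".join(union) + "\n")
        emit(out / "interaction_union_genes.txt")
        for mode, tab in (("continuous", tab_cont), ("categorical", tab_cat)):
            for metric in ("signed_logp", "log2FC_radiation", "log2FC_age"):
                ranked = interaction.build_preranked(tab.loc[union] if union else tab, metric)
                emit(interaction.write_rnk(ranked, out / f"preranked_{mode}_{metric}.rnk"))
        summary["n_interaction_continuous"] = len(sig_cont)
        summary["n_interaction_categorical"] = len(sig_cat)
        summary["n_interaction_union"] = len(union)
    except Exception as exc:  # noqa: BLE001
        raise fail("interaction_screen", exc) from exc

    # --- disease evaluation ----------------------------------------------
    try:
        fcfg = config.filter_config()
        annot_d = disease.merge_rare_levels(annot_d, "ethnicity")
        tables_by_split = {
            split: disease.all_one_vs_rest(expr_d, annot_d, split)
            for split in fcfg.required_splits
        }
        for split, cases in tables_by_split.items():
            for case, table in cases.items():
                safe = case.replace(":", "_").replace(" ", "-").replace("/", "-")
                emit(_write_tsv(table, out / f"disease_{split}_{safe}.tsv"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            survivors, counts = disease.filter_candidates(union, tables_by_split, fcfg)
        emit(_write_tsv(counts, out / "disease_filter_counts.tsv"))
        results = {}
        for gene in survivors:
            results[gene] = disease.fit_three_way(
                expr_d.loc[gene, annot_d.index].to_numpy(),
                annot_d["disease"], annot_d["ethnicity"], annot_d["sex"],
            )
        report = disease.rank_clinical_genes(results)
        emit(_write_tsv(report, out / "disease_clinical_report.tsv", index=False))
        summary["n_candidate_genes"] = len(survivors)
        summary["n_tier1_three_way"] = int((report["tier"] == 1).sum()) if len(report) else 0
    except Exception as exc:  # noqa: BLE001
        raise fail("disease_diff", exc) from exc

    # --- report ------------------------------------------------------------
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    emit(summary_path)
    manifest = [
        {"path": str(p.relative_to(out)), "sha256": _sha256(p), "bytes": p.stat().st_size}
        for p in artifacts
    ]
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"summary": summary, "manifest": manifest, "out_dir": str(out)}
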
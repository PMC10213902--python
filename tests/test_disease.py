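"""Disease-cohort evaluation: one-vs-rest tests, the cross-split filter
against a brute-force rule oracle, and the factorial partial-F model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radage.disease import (
    CandidateFilterConfig,
    all_one_vs_rest,
    filter_candidates,
    fit_three_way,
    merge_rare_levels,
    one_vs_rest_tables,
    rank_clinical_genes,
)
from radage.preprocess import ValidationError
from radage.synthetic import DiseaseDesign, simulate_disease_cohort


class TestOneVsRest:
    def test_two_level_factor_yields_single_table(self, marker_disease_cohort):
        expr, annot = marker_disease_cohort
        tables = one_vs_rest_tables(expr, annot, "sex", "train")
        assert len(tables) == 1
        (table,) = tables.values()
        n_split = (annot["split"] == "train").sum()
        assert table["n_A"].iloc[0] + table["n_B"].iloc[0] == n_split

    def test_marker_gene_significant_with_large_fc_in_every_split(self, marker_disease_cohort):
        expr, annot = marker_disease_cohort
        for split in ("train", "test", "validation"):
            table = one_vs_rest_tables(expr, annot, "disease", split)["lung cancer"]
            row = table.loc["GENE00001"]
            assert row["p"] < 0.05
            assert abs(row["log2FC"]) > 2

    def test_split_restriction_never_leaks_samples(self, marker_disease_cohort):
        expr, annot = marker_disease_cohort
        for split in ("train", "test", "validation"):
            for table in all_one_vs_rest(expr, annot, split).values():
                assert (
                    table["n_A"].iloc[0] + table["n_B"].iloc[0]
                    == (annot["split"] == split).sum()
                )

    def test_null_cohort_significance_near_alpha(self):
        design = DiseaseDesign(
            n_per_split=(120, 120, 120),
            disease_levels=("control", "TB"),
            ethnicity_levels=("Caucasian", "African"),
            n_genes=500,
        )
        expr, annot = simulate_disease_cohort(design, seed=40)
        table = one_vs_rest_tables(expr, annot, "disease", "train")["TB"]
        frac = (table["p"] < 0.05).mean()
        lo, hi = stats.binom.ppf([0.005, 0.995], 500, 0.05) / 500
        assert lo <= frac <= hi

    def test_missing_factor_rejected(self, marker_disease_cohort):
        expr, annot = marker_disease_cohort
        with pytest.raises(ValidationError, match="smoking"):
            one_vs_rest_tables(expr, annot, "smoking", "train")


def _fake_table(genes, p, fc):
    return pd.DataFrame(
        {"p": p, "fdr": p, "log2FC": fc, "t": 0.0, "n_A": 5, "n_B": 5},
        index=pd.Index(genes, name="gene_id"),
    )


class TestFilterCandidates:
    @staticmethod
    def _brute_force(genes, tables_by_split, alpha, min_cases, fc_thresh):
        survivors = []
        for g in genes:
            ok = True
            for split, cases in tables_by_split.items():
                n_pass = 0
                for table in cases.values():
                    if g in table.index:
                        row = table.loc[g]
                        if row["p"] < alpha and abs(row["log2FC"]) > fc_thresh:
                            n_pass += 1
                if n_pass < min_cases:
                    ok = False
            if ok:
                survivors.append(g)
        return survivors

    @pytest.fixture()
    def constructed_tables(self):
        """10 genes with hand-chosen per-split significance/fold-change patterns."""
        genes = [f"G{i}" for i in range(10)]
        rng = np.random.default_rng(41)
        tables = {}
        for si, split in enumerate(("train", "test", "validation")):
            cases = {}
            for ci in range(4):
                p = rng.choice([0.001, 0.2], size=10, p=[0.5, 0.5])
                fc = rng.choice([3.0, 1.0], size=10, p=[0.6, 0.4])
                cases[f"case{ci}"] = _fake_table(genes, p, fc)
            tables[split] = cases
        # force the two canonical exclusion patterns onto G8 / G9
        for split in tables:
            for case in tables[split].values():
                case.loc["G8"] = [0.001, 0.001, 3.0, 0.0, 5, 5]
                case.loc["G9"] = [0.001, 0.001, 1.5, 0.0, 5, 5]
        for ci, case in enumerate(tables["validation"].values()):
            if ci > 0:  # G8 keeps only one passing case in validation
                case.loc["G8", "p"] = 0.9
        return genes, tables

    def test_matches_brute_force_oracle(self, constructed_tables):
        genes, tables = constructed_tables
        config = CandidateFilterConfig(alpha=0.05, min_test_cases=2, fc_threshold=2.0)
        survivors, counts = filter_candidates(genes, tables, config)
        expected = self._brute_force(genes, tables, 0.05, 2, 2.0)
        assert survivors == expected
        assert set(counts.index) == set(genes)

    def test_gene_failing_one_split_excluded(self, constructed_tables):
        genes, tables = constructed_tables
        survivors, counts = filter_candidates(genes, tables)
        assert "G8" not in survivors  # 2 passing cases in train/test, 1 in validation
        assert counts.loc["G8", "validation"] == 1
        assert counts.loc["G8", "train"] == 4

    def test_fold_change_gate(self, constructed_tables):
        genes, tables = constructed_tables
        survivors, _ = filter_candidates(genes, tables)
        assert "G9" not in survivors  # significant everywhere but |log2FC| = 1.5

    def test_relaxing_thresholds_never_shrinks_survivors(self, constructed_tables):
        genes, tables = constructed_tables
        strict, _ = filter_candidates(
            genes, tables, CandidateFilterConfig(alpha=0.01, fc_threshold=2.5)
        )
        loose, _ = filter_candidates(
            genes, tables, CandidateFilterConfig(alpha=0.10, fc_threshold=1.0)
        )
        assert set(strict) <= set(loose)

    def test_unknown_gene_dropped_with_warning(self, constructed_tables):
        genes, tables = constructed_tables
        with pytest.warns(UserWarning, match="NOT_A_GENE"):
            survivors, _ = filter_candidates(genes + ["NOT_A_GENE"], tables)
        assert "NOT_A_GENE" not in survivors

    def test_missing_split_rejected(self, constructed_tables):
        genes, tables = constructed_tables
        with pytest.raises(ValidationError, match="validation"):
            filter_candidates(genes, {k: tables[k] for k in ("train", "test")})


def _balanced_factorial(reps, seed=42, noise=0.0, three_way_offset=0.0):
    rng = np.random.default_rng(seed)
    disease, ethnicity, sex = [], [], []
    for d, e, s in itertools.product(("ctl", "dz"), ("afr", "cau"), ("f", "m")):
        disease += [d] * reps
        ethnicity += [e] * reps
        sex += [s] * reps
    disease, ethnicity, sex = map(np.array, (disease, ethnicity, sex))
    y = (
        1.0
        + 0.5 * (disease == "dz")
        + 0.25 * (ethnicity == "cau")
        - 0.75 * (sex == "m")
        + three_way_offset * ((disease == "dz") & (ethnicity == "cau") & (sex == "m"))
    )
    y = y + rng.normal(0, noise, size=y.size) if noise else y
    return y, disease, ethnicity, sex


class TestThreeWay:
    def test_noiseless_cell_offset_recovered_exactly(self):
        y, d, e, s = _balanced_factorial(reps=3, three_way_offset=2.0)
        res = fit_three_way(y, d, e, s)
        assert res.p_three_way < 1e-12
        assert res.coef["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert res.coef["disease[dz]"] == pytest.approx(0.5, abs=1e-10)
        assert res.coef["ethnicity[cau]"] == pytest.approx(0.25, abs=1e-10)
        assert res.coef["sex[m]"] == pytest.approx(-0.75, abs=1e-10)
        assert res.coef["disease[dz]:ethnicity[cau]:sex[m]"] == pytest.approx(2.0, abs=1e-9)

    def test_f_matches_cell_means_oracle(self):
        y, d, e, s = _balanced_factorial(reps=4, noise=1.0, three_way_offset=1.0, seed=43)
        res = fit_three_way(y, d, e, s)
        # classical balanced-ANOVA contrast: the +/- alternating cell-mean
        # combination divided by its variance under the pooled within-cell MSE
        cells, within_ss, n_cells = [], 0.0, 0
        for dd, ee, ss_ in itertools.product(("ctl", "dz"), ("afr", "cau"), ("f", "m")):
            mask = (d == dd) & (e == ee) & (s == ss_)
            vals = y[mask]
            sign = (
                (1 if dd == "dz" else -1)
                * (1 if ee == "cau" else -1)
                * (1 if ss_ == "m" else -1)
            )
            cells.append((sign, vals.mean(), len(vals)))
            within_ss += ((vals - vals.mean()) ** 2).sum()
            n_cells += 1
        r = cells[0][2]
        mse = within_ss / (len(y) - n_cells)
        contrast = sum(sign * mean for sign, mean, _ in cells)
        f_oracle = contrast**2 / (mse * n_cells / r)
        p_oracle = stats.f.sf(f_oracle, 1, len(y) - n_cells)
        assert res.p_three_way == pytest.approx(p_oracle, abs=1e-8)

    def test_matches_statsmodels_partial_f(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(44)
        n = 240
        d = rng.choice(["ctl", "dz", "pna"], n)
        e = rng.choice(["afr", "cau"], n)
        s = rng.choice(["f", "m"], n)
        y = rng.normal(size=n) + 0.4 * ((d == "dz") & (e == "cau") & (s == "m"))
        res = fit_three_way(y, d, e, s)
        df = pd.DataFrame({"y": y, "d": d, "e": e, "s": s})
        full = smf.ols("y ~ d * e * s", data=df).fit()
        red = smf.ols("y ~ (d + e + s) ** 2", data=df).fit()
        p_sm = anova_lm(red, full).iloc[1]["Pr(>F)"]
        assert res.p_three_way == pytest.approx(p_sm, abs=1e-8)

    def test_null_three_way_p_is_calibrated(self):
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            y, d, e, s = _balanced_factorial(reps=4, noise=1.0, seed=1000 + seed)
            if fit_three_way(y, d, e, s).p_three_way < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.09

    def test_single_level_factor_rejected(self):
        y, d, e, s = _balanced_factorial(reps=3)
        with pytest.raises(ValidationError, match="single level"):
            fit_three_way(y, d, e, np.full_like(s, "f"))

    def test_saturated_design_rejected(self):
        y, d, e, s = _balanced_factorial(reps=1, noise=0.1)
        with pytest.raises(ValidationError, match="saturated|merge"):
            fit_three_way(y, d, e, s)

    def test_thin_level_advises_merging(self):
        y, d, e, s = _balanced_factorial(reps=3)
        e = e.copy()
        e[0] = "singleton"
        with pytest.raises(ValidationError, match="merge"):
            fit_three_way(y, d, e, s)


class TestClinicalReport:
    def test_tier_assignment_matches_construction(self):
        rng = np.random.default_rng(45)
        n = 320
        d = rng.choice(["ctl", "dz"], n)
        e = rng.choice(["afr", "cau"], n)
        s = rng.choice(["f", "m"], n)
        genes = {
            "THREEWAY": rng.normal(size=n)
            + 1.5 * ((d == "dz") & (e == "cau") & (s == "m")),
            "TWOWAY": rng.normal(size=n) + 1.0 * ((d == "dz") & (s == "m")),
            "MAINONLY": rng.normal(size=n) + 1.0 * (d == "dz"),
            "NULL": rng.normal(size=n),
        }
        results = {g: fit_three_way(y, d, e, s) for g, y in genes.items()}
        report = rank_clinical_genes(results, alpha=0.05)
        tiers = dict(zip(report["gene"], report["tier"]))
        assert tiers["THREEWAY"] == 1
        assert tiers["TWOWAY"] == 2
        assert tiers["MAINONLY"] == 3
        assert report["gene"].iloc[0] == "THREEWAY"

    def test_empty_results_give_valid_empty_report(self):
        report = rank_clinical_genes({})
        assert list(report.columns) == [
            "gene", "tier", "p_three_way", "p_two_way_min", "p_main_min"
        ]
        assert report.empty


def test_merge_rare_levels_pools_singletons():
    block = ["Caucasian"] * 10 + ["African"] * 6 + ["SE Asia"]
    annot = pd.DataFrame(
        {
            "ethnicity": block + block,
            "split": ["train"] * len(block) + ["test"] * len(block),
        }
    )
    merged = merge_rare_levels(annot, "ethnicity", min_count=4)
    assert "SE Asia" not in merged["ethnicity"].values
    assert (merged["ethnicity"] == "other").sum() == 2
    assert (merged["ethnicity"] == "Caucasian").sum() == 20
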
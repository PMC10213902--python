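"""Contrast battery: Welch t against the closed formula, BH against brute
force, intersection counts against exhaustive enumeration."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radage import preprocess
from radage.diffexp import (
    ContrastSet,
    bh_adjust,
    default_contrasts,
    dose_trend,
    intersect_significant,
    run_contrasts,
    two_group_de,
)
from radage.preprocess import ValidationError


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j)/j, original order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestWelch:
    def test_matches_independent_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        expr = pd.DataFrame([np.r_[a, b]], index=["G"],
                            columns=["A1", "A2", "A3", "B1", "B2", "B3"])
        table = two_group_de(expr, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        # independent arithmetic: Welch statistic and Welch-Satterthwaite df
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_expected = (a.mean() - b.mean()) / np.sqrt(va / 3 + vb / 3)
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        p_expected = 2 * stats.t.sf(abs(t_expected), df)
        assert table.loc["G", "t"] == pytest.approx(t_expected, abs=1e-10)
        assert table.loc["G", "p"] == pytest.approx(p_expected, abs=1e-10)
        assert table.loc["G", "log2FC"] == pytest.approx(-3.0, abs=1e-12)

    def test_exact_shift_gives_exact_log2fc(self, null_matrix):
        expr, ids_a, ids_b = null_matrix
        shifted = expr.copy()
        shifted[ids_a] += 2.0
        table = two_group_de(shifted, ids_a, ids_b)
        base = two_group_de(expr, ids_a, ids_b)
        np.testing.assert_allclose(table["log2FC"], base["log2FC"] + 2.0, atol=1e-10)

    def test_group_swap_negates_t_and_fc(self, null_matrix):
        expr, ids_a, ids_b = null_matrix
        ab = two_group_de(expr, ids_a, ids_b)
        ba = two_group_de(expr, ids_b, ids_a)
        np.testing.assert_allclose(ab["t"], -ba["t"], atol=1e-10)
        np.testing.assert_allclose(ab["log2FC"], -ba["log2FC"], atol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)
        np.testing.assert_allclose(ab["fdr"], ba["fdr"], atol=1e-12)

    def test_null_rate_within_binomial_bounds(self):
        rng = np.random.default_rng(20)
        expr = pd.DataFrame(rng.normal(size=(1000, 60)),
                            columns=[f"S{i}" for i in range(60)])
        table = two_group_de(expr, list(expr.columns[:30]), list(expr.columns[30:]))
        frac = (table["p"] < 0.05).mean()
        # Binomial(1000, 0.05), 99% bounds
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.05) / 1000
        assert lo <= frac <= hi

    def test_overlapping_groups_rejected(self, null_matrix):
        expr, ids_a, ids_b = null_matrix
        with pytest.raises(ValidationError, match="overlap"):
            two_group_de(expr, ids_a, ids_a[:5] + ids_b)

    def test_degenerate_gene_reported_flat(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]],
            index=["const", "varying"], columns=["A1", "A2", "B1", "B2"],
        )
        with pytest.warns(UserWarning, match="constant"):
            table = two_group_de(expr, ["A1", "A2"], ["B1", "B2"])
        assert table.loc["const", "t"] == 0.0
        assert table.loc["const", "p"] == 1.0


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(21)
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m)
            q = bh_adjust(p)
            np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_q_dominates_p_and_is_rank_monotone(self):
        rng = np.random.default_rng(22)
        p = rng.random(100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestContrastBattery:
    def test_six_tables_on_full_annotations(self, radiation_cohort):
        expr, annot = radiation_cohort
        annot = preprocess.annotate_bins_and_age(annot, cutoff=29)
        tables = run_contrasts(expr, annot)
        assert set(tables) == {
            "control_vs_any_radiation", "control_vs_low", "low_vs_medium",
            "medium_vs_high", "young_vs_old", "male_vs_female",
        }
        for table in tables.values():
            assert len(table) == len(expr)

    def test_dose_responsive_gene_detected(self):
        rng = np.random.default_rng(23)
        n_side = 60
        cols = [f"S{i}" for i in range(2 * n_side)]
        expr = pd.DataFrame(rng.normal(8, 1, size=(200, 2 * n_side)), columns=cols)
        rad_code = np.r_[np.zeros(n_side, dtype=int), rng.integers(1, 4, n_side)]
        expr.iloc[0] += 1.0 * rad_code  # +1 log2 per ordinal bin
        annot = pd.DataFrame({"rad_code": rad_code}, index=cols)
        tables = run_contrasts(
            expr, annot,
            ContrastSet((("control_vs_any_radiation", "rad_code == 0", "rad_code > 0"),)),
        )
        assert tables["control_vs_any_radiation"].iloc[0]["fdr"] < 0.05

    def test_empty_side_skipped_with_warning(self, radiation_cohort):
        expr, annot = radiation_cohort
        annot = preprocess.annotate_bins_and_age(annot, cutoff=29)
        battery = ContrastSet(
            default_contrasts().contrasts + (("impossible", "rad_code == 9", "rad_code == 0"),)
        )
        with pytest.warns(UserWarning, match="impossible"):
            tables = run_contrasts(expr, annot, battery)
        assert "impossible" not in tables

    def test_null_data_fdr_controls_discoveries(self):
        flagged = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            expr = pd.DataFrame(rng.normal(size=(500, 50)),
                                columns=[f"S{i}" for i in range(50)])
            table = two_group_de(expr, list(expr.columns[:25]), list(expr.columns[25:]))
            flagged += int((table["fdr"] < 0.05).any())
        assert flagged <= 1


class TestIntersections:
    @staticmethod
    def _table(sig_genes, all_genes):
        q = pd.Series(1.0, index=all_genes)
        q[sig_genes] = 0.001
        return pd.DataFrame({"fdr": q, "p": q})

    def test_identical_tables_all_in_both_cell(self):
        genes = [f"G{i}" for i in range(10)]
        t = self._table(genes[:4], genes)
        out = intersect_significant({"a": t, "b": t})
        both = out[(out["a"]) & (out["b"])]
        assert both["count"].tolist() == [4]
        assert len(out) == 1

    def test_disjoint_sets_have_empty_intersection_cell(self):
        genes = [f"G{i}" for i in range(10)]
        out = intersect_significant(
            {"a": self._table(genes[:3], genes), "b": self._table(genes[3:6], genes)}
        )
        both = out[(out["a"]) & (out["b"])]
        assert both.empty

    def test_counts_match_exhaustive_enumeration(self):
        genes = [f"G{i}" for i in range(12)]
        sets = {
            "a": {"G0", "G1", "G2", "G5"},
            "b": {"G1", "G2", "G6", "G7"},
            "c": {"G2", "G5", "G7", "G8"},
        }
        tables = {k: self._table(sorted(v), genes) for k, v in sets.items()}
        out = intersect_significant(tables)
        # oracle: enumerate every gene's exact membership pattern
        expected = {}
        for g in set().union(*sets.values()):
            key = tuple(g in sets[k] for k in ("a", "b", "c"))
            expected[key] = expected.get(key, 0) + 1
        for _, row in out.iterrows():
            key = (row["a"], row["b"], row["c"])
            assert row["count"] == expected.pop(key)
        assert not expected

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(24)
        genes = [f"G{i}" for i in range(50)]
        sets = {k: set(rng.choice(genes, 15, replace=False)) for k in "abcd"}
        tables = {k: self._table(sorted(v), genes) for k, v in sets.items()}
        out = intersect_significant(tables)
        assert out["count"].sum() == len(set().union(*sets.values()))


class TestDoseTrend:
    @staticmethod
    def _cohort():
        cols = [f"S{i}" for i in range(40)]
        rad_code = np.repeat([0, 1, 2, 3], 10)
        annot = pd.DataFrame({"rad_code": rad_code}, index=cols)
        expr = pd.DataFrame(
            {
                "monotone": rad_code.astype(float),
                "flat": np.ones(40),
                "dip_then_rise": np.select([rad_code == 0, rad_code == 1], [1.0, 0.2], 2.0 * rad_code),
            }
        ).T
        expr.columns = cols
        return expr, annot

    def test_profiles(self):
        expr, annot = self._cohort()
        out = dose_trend(expr, annot, ["monotone", "flat", "dip_then_rise"])
        assert out.loc["monotone", "profile"] == "(+,+,+)"
        assert out.loc["flat", "profile"] == "(0,0,0)"
        assert out.loc["dip_then_rise", "profile"] == "(-,+,+)"

    def test_empty_bin_named(self):
        expr, annot = self._cohort()
        keep = annot.index[annot["rad_code"] != 2]
        with pytest.raises(ValidationError, match="medium"):
            dose_trend(expr[keep], annot.loc[keep], ["monotone"])
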
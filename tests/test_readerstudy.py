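"""MRMC statistics: crossover assignment, DBM pseudovalue ANOVA, the DeLong
test, miss-rate reduction and read-time endpoints."""

import numpy as np
import pandas as pd
import pytest

from cxrcad import synthdata as sd
from cxrcad.evaluation import roc_auc
from cxrcad.readerstudy import (
    assign_conditions,
    dbm_analysis,
    delong_test,
    jackknife_auc,
    miss_rate_reduction,
    mrmc_report,
    readtime_test,
)


class TestAssignConditions:
    def test_half_split_with_stratification(self):
        cases = [f"c{i}" for i in range(238)]
        strata = {c: i % 2 for i, c in enumerate(cases)}
        design = assign_conditions(cases, ["r1"], seed=4, strata=strata)
        s1 = design[design.session == 1]
        n_aided = (s1.condition == "aided").sum()
        assert abs(n_aided - 119) <= 2  # near-half within strata (+-1 each)

    def test_every_pair_covered_in_both_conditions(self):
        design = assign_conditions([f"c{i}" for i in range(11)],
                                   ["r1", "r2"], seed=1)
        per = design.groupby(["reader_id", "case_id"])["condition"].apply(set)
        assert (per == {"aided", "unaided"}).all()

    def test_deterministic(self):
        a = assign_conditions(list("abcdef"), ["r1", "r2"], seed=9)
        b = assign_conditions(list("abcdef"), ["r1", "r2"], seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_conditions(["c1"], ["r1"], seed=0)
        with pytest.raises(ValueError):
            assign_conditions(["c1", "c2"], [], seed=0)


class TestJackknifeAuc:
    def test_matches_direct_leave_one_out(self):
        rng = np.random.default_rng(0)
        n = 40
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        groups = np.arange(n) // 2  # two pairs per case
        auc, loo = jackknife_auc(scores, labels, groups)
        assert auc == pytest.approx(roc_auc(scores, labels), abs=1e-12)
        for gi, g in enumerate(np.unique(groups)):
            keep = groups != g
            expected = roc_auc(scores[keep], labels[keep])
            assert loo[gi] == pytest.approx(expected, abs=1e-10)

    def test_degenerate_deletion_falls_back_with_warning(self):
        scores = np.array([0.9, 0.1, 0.2])
        labels = np.array([1, 0, 0])
        with pytest.warns(UserWarning):
            auc, loo = jackknife_auc(scores, labels, np.array([0, 1, 2]))
        assert loo[0] == auc  # deleting the only positive


def _study_table(seed, n_readers=4, n_cases=60, delta=0.0, n_cat=2):
    cats = sd.CATEGORIES[:n_cat]
    design = sd.StudyDesignConfig(
        readers_per_specialty={"radiology": n_readers},
        n_cases=n_cases, n_abnormal=int(0.7 * n_cases), categories=cats,
        unaided_auc=0.78, aided_auc=0.78 + delta)
    return sd.generate_reader_study(design, seed=seed)


class TestDbmAnalysis:
    def test_identical_conditions_give_zero_difference(self):
        table = _study_table(3)
        # force aided scores identical to unaided per (reader, case, category)
        piv = table.pivot_table(index=["reader_id", "case_id", "category"],
                                columns="condition", values="confidence")
        lookup = piv["unaided"].to_dict()
        table = table.copy()
        table["confidence"] = [
            lookup[(r, c, k)] for r, c, k in
            zip(table.reader_id, table.case_id, table.category)]
        res = dbm_analysis(table)
        assert res.difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_difference_is_aided_minus_unaided(self):
        table = _study_table(5, delta=0.1)
        res = dbm_analysis(table)
        assert res.difference == pytest.approx(
            res.ls_mean_auc_aided - res.ls_mean_auc_unaided, abs=1e-12)
        assert res.ci_low <= res.difference <= res.ci_high

    def test_antisymmetric_under_condition_swap(self):
        table = _study_table(7, delta=0.08)
        swapped = table.copy()
        swapped["condition"] = swapped["condition"].map(
            {"aided": "unaided", "unaided": "aided"})
        a = dbm_analysis(table)
        b = dbm_analysis(swapped)
        assert a.difference == pytest.approx(-b.difference, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-9)

    def test_ls_means_close_to_mean_reader_auc(self):
        """Jackknife LS means track the plain mean of reader AUCs."""
        table = _study_table(11, n_readers=6, n_cases=80)
        res = dbm_analysis(table)
        aucs = []
        for cond in ("unaided", "aided"):
            vals = []
            for _, g in table[table.condition == cond].groupby("reader_id"):
                vals.append(jackknife_auc(g.confidence.to_numpy(),
                                          g.reference.to_numpy(),
                                          g.case_id.to_numpy())[0])
            aucs.append(np.mean(vals))
        assert res.ls_mean_auc_unaided == pytest.approx(aucs[0], abs=0.02)
        assert res.ls_mean_auc_aided == pytest.approx(aucs[1], abs=0.02)

    def test_too_small_tables_rejected(self):
        table = _study_table(1, n_readers=1)
        with pytest.raises(ValueError):
            dbm_analysis(table)


class TestDelong:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        auc_a, auc_b, z, p = delong_test(s, s, y)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_auc_matches_roc_auc(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.integers(0, 2, 60)
            y[:2] = [0, 1]
            a, b = rng.random(60), rng.random(60)
            auc_a, auc_b, _, _ = delong_test(a, b, y)
            assert auc_a == pytest.approx(roc_auc(a, y), abs=1e-12)
            assert auc_b == pytest.approx(roc_auc(b, y), abs=1e-12)

    def test_variance_matches_case_bootstrap(self):
        """DeLong variance of the AUC difference vs a case-bootstrap
        estimate on correlated scores, n = 500."""
        rng = np.random.default_rng(2)
        n = 500
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        signal = y + rng.normal(0, 1, n)
        a = signal + rng.normal(0, 0.5, n)
        b = 0.8 * signal + rng.normal(0, 0.6, n)
        auc_a, auc_b, z, _ = delong_test(a, b, y)
        var_delong = ((auc_a - auc_b) / z) ** 2
        boots = []
        boot_rng = np.random.default_rng(1000)
        for _ in range(2000):
            idx = boot_rng.integers(0, n, n)
            yy = y[idx]
            if yy.min() == yy.max():
                continue
            boots.append(roc_auc(a[idx], yy) - roc_auc(b[idx], yy))
        var_boot = np.var(boots, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3, 0.4], [1, 1])


class TestMissRateReduction:
    def test_printed_study_values(self):
        assert miss_rate_reduction(0.757, 0.856) == pytest.approx(40.74,
                                                                  abs=0.01)

    def test_no_change_is_zero(self):
        assert miss_rate_reduction(0.6, 0.6) == 0.0

    def test_all_misses_eliminated(self):
        assert miss_rate_reduction(0.5, 1.0) == 100.0

    def test_invariant_to_common_miss_rate_scaling(self):
        base = miss_rate_reduction(0.8, 0.9)  # miss rates 0.2 -> 0.1
        scaled = miss_rate_reduction(1 - 0.4, 1 - 0.2)  # x2 both
        assert base == pytest.approx(scaled)

    def test_perfect_unaided_undefined(self):
        with pytest.raises(ValueError):
            miss_rate_reduction(1.0, 1.0)


class TestReadTime:
    def test_identical_times_null(self):
        t = np.array([50.0, 60.0, 70.0])
        res = readtime_test(t, t)
        assert res.t == 0.0 and res.p == 1.0
        assert res.relative_median_change_pct == 0.0

    def test_printed_median_change(self):
        res = readtime_test(np.full(10, 107.0), np.full(10, 98.5))
        assert res.relative_median_change_pct == pytest.approx(7.94,
                                                               abs=0.005)

    def test_reader_level_pairing_df(self):
        rng = np.random.default_rng(3)
        readers = np.repeat(np.arange(18), 20)
        tu = rng.lognormal(np.log(100), 0.3, 18 * 20)
        ta = rng.lognormal(np.log(90), 0.3, 18 * 20)
        res = readtime_test(tu, ta, readers, readers)
        assert res.df == 17

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            readtime_test([10.0, 0.0], [5.0, 5.0])


def test_mrmc_report_structure():
    design = sd.StudyDesignConfig(
        readers_per_specialty={"radiology": 2, "internal": 2},
        n_cases=40, n_abnormal=30, categories=sd.CATEGORIES[:2])
    table = sd.generate_reader_study(design, seed=21)
    report = mrmc_report(table)
    assert set(report) >= {"dbm", "per_specialty_auc",
                           "delong_rad_vs_nonrad", "secondary_endpoints"}
    assert len(report["per_specialty_auc"]) == 4  # 2 specialties x 2 conds
    for cond in ("unaided", "aided"):
        assert 0 <= report["delong_rad_vs_nonrad"][cond]["p"] <= 1
    for grp in ("radiologists", "non_radiologists"):
        assert "read_time" in report["secondary_endpoints"][grp]
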
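"""Evaluation statistics: ROC AUC vs pair counting, micro-averaging,
bootstrap CIs (determinism and coverage), and box-set IoU."""

import numpy as np
import pytest

from cxrcad.evaluation import (
    bootstrap_ci,
    iou_report,
    micro_average,
    roc_auc,
    subset_sensitivity,
    summed_iou,
)
from cxrcad.synthdata import CATEGORIES
from tests.conftest import brute_force_auc


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_chance_level_on_independent_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(20000)
        labels = rng.integers(0, 2, 20000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_worked_example_three_quarters(self):
        # pos {0.4, 0.8} vs neg {0.1, 0.45}: 3 of 4 pairs correctly ordered
        assert roc_auc([0.1, 0.4, 0.45, 0.8], [0, 1, 0, 1]) == 0.75

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            scores = rng.integers(0, 6, n) / 5.0  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels) == \
                pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestMicroAverage:
    def test_identical_categories_equal_pooled_value(self):
        scores = np.array([0.9, 0.7, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0])
        out = micro_average({c: scores for c in CATEGORIES},
                            {c: labels for c in CATEGORIES})
        assert out["auc"] == roc_auc(scores, labels)

    def test_pooled_auc_strictly_between_extremes(self):
        good_s = np.array([0.8, 0.9, 0.1, 0.2])
        bad_s = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([1, 1, 0, 0])
        per_s = {c: (good_s if i < 4 else bad_s)
                 for i, c in enumerate(CATEGORIES)}
        per_l = {c: labels for c in CATEGORIES}
        out = micro_average(per_s, per_l)
        assert 0.0 < out["auc"] < 1.0

    def test_pooled_vector_length(self):
        n = 250
        rng = np.random.default_rng(2)
        per_s = {c: rng.random(n) for c in CATEGORIES}
        per_l = {c: rng.integers(0, 2, n) for c in CATEGORIES}
        out = micro_average(per_s, per_l)
        assert out["n_pairs"] == n * 8

    def test_invariant_to_case_and_category_order(self):
        rng = np.random.default_rng(3)
        n = 50
        per_s = {c: rng.random(n) for c in CATEGORIES}
        per_l = {c: rng.integers(0, 2, n) for c in CATEGORIES}
        out1 = micro_average(per_s, per_l)
        perm = rng.permutation(n)
        per_s2 = {c: per_s[c][perm] for c in reversed(CATEGORIES)}
        per_l2 = {c: per_l[c][perm] for c in reversed(CATEGORIES)}
        out2 = micro_average(per_s2, per_l2)
        assert out1["auc"] == pytest.approx(out2["auc"], abs=1e-12)

    def test_pooled_sens_spec_from_determinations(self):
        labels = np.array([1, 1, 0, 0])
        det = np.array([1, 0, 0, 1])
        out = micro_average({c: np.array([.9, .4, .3, .8])
                             for c in CATEGORIES},
                            {c: labels for c in CATEGORIES},
                            {c: det for c in CATEGORIES})
        assert out["sensitivity"] == pytest.approx(0.5)
        assert out["specificity"] == pytest.approx(0.5)


class TestBootstrapCi:
    def test_constant_metric_zero_width(self):
        lo, hi = bootstrap_ci(lambda idx: 0.7, 50, m=200, seed=1)
        assert lo == hi == 0.7

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        fn = lambda idx: float(np.mean(x[idx]))
        assert bootstrap_ci(fn, 80, m=300, seed=9) == \
            bootstrap_ci(fn, 80, m=300, seed=9)

    def test_coverage_for_the_normal_mean(self):
        """Percentile bootstrap on the mean of N(0,1), n=100: coverage of
        the true mean ~95% over 500 simulations."""
        rng = np.random.default_rng(5)
        covered = 0
        sims = 500
        for s in range(sims):
            x = rng.normal(size=100)
            lo, hi = bootstrap_ci(lambda idx: float(np.mean(x[idx])), 100,
                                  m=400, seed=s)
            covered += lo <= 0.0 <= hi
        rate = covered / sims
        se = np.sqrt(0.95 * 0.05 / sims)
        assert abs(rate - 0.95) < 3.5 * se + 0.01

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=120)
        fn = lambda idx: float(np.mean(x[idx]))
        lo, hi = bootstrap_ci(fn, 120, m=500, seed=3)
        assert lo <= np.mean(x) <= hi

    def test_excess_degenerate_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda idx: np.nan, 10, m=50, seed=0)


class TestSummedIou:
    def test_identical_boxes(self):
        assert summed_iou([(2, 2, 10, 10)], [(2, 2, 10, 10)], (20, 20)) == 1.0

    def test_disjoint_boxes(self):
        assert summed_iou([(0, 0, 5, 5)], [(10, 10, 15, 15)], (20, 20)) == 0.0

    def test_half_overlap_strip(self):
        # 10x10 boxes overlapping on a 5x10 strip: 50 / 150
        assert summed_iou([(0, 0, 10, 10)], [(5, 0, 15, 10)], (20, 20)) == \
            pytest.approx(1 / 3)

    def test_overlapping_boxes_within_a_set_not_double_counted(self):
        pred = [(0, 0, 10, 10), (0, 0, 10, 10)]  # duplicates
        assert summed_iou(pred, [(0, 0, 10, 10)], (20, 20)) == 1.0
        rep = iou_report(pred, [(0, 0, 10, 10)], (20, 20))
        assert rep["summed_pred_area"] == 200  # raw sums reported alongside
        assert rep["summed_ref_area"] == 100

    def test_matches_pixel_mask_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            def rand_boxes():
                out = []
                for _ in range(rng.integers(1, 4)):
                    r0, c0 = rng.integers(0, 20, 2)
                    out.append((r0, c0, r0 + rng.integers(1, 10),
                                c0 + rng.integers(1, 10)))
                return out

            pred, ref = rand_boxes(), rand_boxes()
            shape = (32, 32)
            pm = np.zeros(shape, bool)
            rm = np.zeros(shape, bool)
            for (r0, c0, r1, c1) in pred:
                pm[r0:min(r1, 32), c0:min(c1, 32)] = True
            for (r0, c0, r1, c1) in ref:
                rm[r0:min(r1, 32), c0:min(c1, 32)] = True
            oracle = (pm & rm).sum() / (pm | rm).sum()
            assert summed_iou(pred, ref, shape) == pytest.approx(oracle,
                                                                 abs=1e-12)

    def test_symmetry(self):
        a = [(0, 0, 8, 8), (10, 10, 15, 18)]
        b = [(4, 4, 12, 12)]
        assert summed_iou(a, b, (20, 20)) == summed_iou(b, a, (20, 20))

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            summed_iou([], [], (10, 10))


class TestSubsetSensitivity:
    @staticmethod
    def _table(n_cases, key):
        import pandas as pd

        rng = np.random.default_rng(8)
        rows = []
        for i in range(n_cases):
            ref = int(rng.random() < 0.6)
            det = ref if rng.random() < 0.85 else 1 - ref
            rows.append({"case_id": f"c{i}", "reference": ref,
                         "determination": det, "score": rng.random(),
                         "stratum": key(i)})
        return pd.DataFrame(rows)

    def test_single_stratum_matches_global(self):
        t = self._table(60, lambda i: "all")
        out = subset_sensitivity(t, "stratum", m=50)
        global_sens = t[t.reference == 1]["determination"].mean()
        assert len(out) == 1
        assert out.iloc[0]["sensitivity"] == pytest.approx(global_sens)

    def test_small_stratum_suppressed(self):
        t = self._table(60, lambda i: "small" if i < 19 else "big")
        out = subset_sensitivity(t, "stratum", m=50)
        assert list(out["stratum"]) == ["big"]

    def test_difficulty_ordering_recovered(self):
        """Strata with a planted accuracy gap keep their ordering."""
        import pandas as pd

        rng = np.random.default_rng(9)
        rows = []
        for i in range(400):
            stratum = "easy" if i % 2 == 0 else "hard"
            acc = 0.95 if stratum == "easy" else 0.6
            ref = 1
            det = int(rng.random() < acc)
            rows.append({"case_id": f"c{i}", "reference": ref,
                         "determination": det, "score": rng.random(),
                         "stratum": stratum})
        out = subset_sensitivity(pd.DataFrame(rows), "stratum", m=50)
        sens = dict(zip(out["stratum"], out["sensitivity"]))
        assert sens["easy"] > sens["hard"]
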
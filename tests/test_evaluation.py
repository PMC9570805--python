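"""Confusion charts and performance measures against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from sladl.evaluation import (ClassCounts, class_counts, confusion,
                              export_timeline, fold_records, metrics,
                              normalize_chart, precision_distribution,
                              summarize)
from sladl.loso import FoldResult, LosoResult
from sladl.preprocessing import SensorCombination


def brute_force_counts(y_true, y_pred, c):
    """Independent enumeration oracle for one-vs-rest counts."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != c and p != c)
    return tp, fp, fn, tn


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self, rng):
        y = rng.integers(0, 8, 200)
        chart = confusion(y, y)
        assert (chart.sum() == 200
                and (chart == np.diag(np.diag(chart))).all())

    def test_small_enumeration_example(self):
        chart = confusion([0, 0, 1], [0, 1, 1])
        assert chart[0, 0] == 1 and chart[0, 1] == 1 and chart[1, 1] == 1
        assert chart.sum() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    def test_matches_sklearn_on_random_label_sets(self, rng):
        from sklearn.metrics import confusion_matrix
        for _ in range(20):
            y_true = rng.integers(0, 8, 150)
            y_pred = rng.integers(0, 8, 150)
            np.testing.assert_array_equal(
                confusion(y_true, y_pred),
                confusion_matrix(y_true, y_pred, labels=range(8)))


class TestClassCounts:
    def test_hand_counted_example(self):
        chart = confusion([0, 0, 1], [0, 1, 1], n_classes=2)
        c = class_counts(chart, 0)
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 0, 1)

    def test_perfect_chart_has_no_errors(self, rng):
        y = rng.integers(0, 8, 100)
        chart = confusion(y, y)
        for c in range(8):
            cc = class_counts(chart, c)
            assert cc.FP == 0 and cc.FN == 0

    def test_fp_and_fn_sums_equal_off_diagonal_mass(self, rng):
        """Sum over classes of FP = sum of FN = total off-diagonal count."""
        for _ in range(100):
            y_true = rng.integers(0, 8, 80)
            y_pred = rng.integers(0, 8, 80)
            chart = confusion(y_true, y_pred)
            off = chart.sum() - np.trace(chart)
            assert sum(class_counts(chart, c).FP for c in range(8)) == off
            assert sum(class_counts(chart, c).FN for c in range(8)) == off

    def test_equivalence_with_brute_force_oracle(self, rng):
        for _ in range(100):
            y_true = rng.integers(0, 8, 60)
            y_pred = rng.integers(0, 8, 60)
            chart = confusion(y_true, y_pred)
            c = int(rng.integers(0, 8))
            got = class_counts(chart, c)
            assert (got.TP, got.FP, got.FN, got.TN) == \
                brute_force_counts(y_true, y_pred, c)


class TestMetrics:
    def test_perfect_counts_give_ones(self):
        m = metrics(ClassCounts(TP=50, FP=0, FN=0, TN=50))
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "sensitivity", "precision", "specificity"))

    def test_hand_arithmetic_example(self):
        m = metrics(ClassCounts(TP=8, FP=4, FN=2, TN=86))
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.94)
        assert m["specificity"] == pytest.approx(86 / 90)
        assert m["specificity_tn_fn"] == pytest.approx(86 / 88)

    def test_undefined_precision_flagged_as_nan(self):
        m = metrics(ClassCounts(TP=0, FP=0, FN=5, TN=95))
        assert np.isnan(m["precision"])
        assert m["sensitivity"] == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ClassCounts(TP=0, FP=0, FN=0, TN=0))

    def test_micro_consistency_against_chart(self, rng):
        """Per-class accuracy equals 1 - (FP+FN)/total on random charts."""
        for _ in range(50):
            y_true = rng.integers(0, 8, 120)
            y_pred = rng.integers(0, 8, 120)
            chart = confusion(y_true, y_pred)
            total = chart.sum()
            assert np.trace(chart) / total == pytest.approx(
                np.mean(y_true == y_pred))
            for c in range(8):
                cc = class_counts(chart, c)
                m = metrics(cc)
                assert m["accuracy"] == pytest.approx(
                    1 - (cc.FP + cc.FN) / total)

    def test_bounds_whenever_defined(self, rng):
        for _ in range(50):
            chart = confusion(rng.integers(0, 8, 40), rng.integers(0, 8, 40))
            for c in range(8):
                for v in metrics(class_counts(chart, c)).values():
                    assert np.isnan(v) or 0.0 <= v <= 1.0


class TestNormalizeChart:
    def test_row_normalized_diagonal_equals_sensitivity(self, rng):
        y_true = rng.integers(0, 8, 300)
        y_pred = np.where(rng.random(300) < 0.8, y_true,
                          rng.integers(0, 8, 300))
        chart = confusion(y_true, y_pred)
        row = normalize_chart(chart, axis="row")
        col = normalize_chart(chart, axis="column")
        for c in range(8):
            m = metrics(class_counts(chart, c))
            if not np.isnan(row[c, c]):
                assert row[c, c] == pytest.approx(m["sensitivity"] * 100)
            if not np.isnan(col[c, c]):
                assert col[c, c] == pytest.approx(m["precision"] * 100)

    def test_rows_sum_to_hundred(self, rng):
        chart = confusion(rng.integers(0, 8, 100), rng.integers(0, 8, 100))
        row = normalize_chart(chart, axis="row")
        sums = np.nansum(row, axis=1)
        np.testing.assert_allclose(sums[~np.isnan(row).all(axis=1)], 100.0,
                                   atol=1e-9)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            normalize_chart(np.eye(8), axis="diag")


def _fold(pid, y_true, y_pred, train_ids=("PX",)):
    return FoldResult(val_participant_id=pid, train_participant_ids=train_ids,
                      best_repeat_index=0,
                      val_accuracy=float(np.mean(np.array(y_true) == np.array(y_pred))),
                      y_true=np.array(y_true), y_pred=np.array(y_pred),
                      stopped_at_iter=1)


class TestSummaries:
    def test_perfect_single_fold_summarizes_to_hundred(self, rng):
        y = rng.integers(0, 8, 400)
        res = LosoResult(combination=SensorCombination.C1,
                         folds=[_fold("P01", y, y)])
        table = summarize({SensorCombination.C1: res})
        assert table.loc[0, "accuracy_mean"] == pytest.approx(100.0)
        assert table.loc[0, "sensitivity_sd"] == pytest.approx(0.0)

    def test_mean_and_sample_sd_convention(self):
        """Two accuracy records 0.9 and 1.0 -> mean 95.0, SD 7.07 (ddof=1)."""
        vals = np.array([90.0, 100.0])
        assert vals.mean() == 95.0
        assert vals.std(ddof=1) == pytest.approx(7.0710678)

    def test_four_combination_rows(self, rng):
        y = rng.integers(0, 8, 100)
        results = {c: LosoResult(combination=c, folds=[_fold("P01", y, y)])
                   for c in SensorCombination}
        assert len(summarize(results)) == 4

    def test_undefined_cells_excluded_from_means(self):
        # class 7 never occurs nor is predicted: precision/sensitivity NaN
        y_true = np.repeat(np.arange(7), 10)
        res = LosoResult(combination=SensorCombination.C2,
                         folds=[_fold("P01", y_true, y_true)])
        rec = fold_records(res)
        assert rec["sensitivity"].isna().sum() == 1
        table = summarize({SensorCombination.C2: res})
        assert table.loc[0, "sensitivity_mean"] == pytest.approx(100.0)


class TestTimeline:
    def test_timeline_alignment_and_mismatch_mass(self, rng):
        y_true = rng.integers(0, 8, 200)
        y_pred = np.where(rng.random(200) < 0.9, y_true,
                          rng.integers(0, 8, 200))
        fold = _fold("P01", y_true, y_pred)
        tl = export_timeline(fold)
        assert len(tl) == 200
        np.testing.assert_allclose(np.diff(tl["time_s"]), 0.1, atol=1e-12)
        chart = confusion(y_true, y_pred)
        off_diag = chart.sum() - np.trace(chart)
        assert (tl["true"] != tl["pred"]).sum() == off_diag

    def test_perfect_fold_has_no_mismatch(self, rng):
        y = rng.integers(0, 8, 50)
        tl = export_timeline(_fold("P01", y, y))
        assert (tl["true"] == tl["pred"]).all()


class TestPrecisionDistribution:
    def test_identical_records_zero_width_box(self):
        rec = pd.DataFrame({"class": ["WRL"] * 5, "precision": [0.8] * 5})
        box = precision_distribution(rec)
        assert box.loc[0, "q1"] == box.loc[0, "q3"] == box.loc[0, "median"] == 0.8
        assert box.loc[0, "outliers"] == []

    def test_quantiles_linear_interpolation_oracle(self):
        vals = [0.6, 0.7, 0.8, 0.9, 1.0]
        rec = pd.DataFrame({"class": ["MMH"] * 5, "precision": vals})
        box = precision_distribution(rec)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        assert box.loc[0, "median"] == pytest.approx(med)
        assert box.loc[0, "q1"] == pytest.approx(q1)
        assert box.loc[0, "q3"] == pytest.approx(q3)

    def test_iqr_outlier_rule(self):
        vals = [0.9] * 9 + [0.1]
        rec = pd.DataFrame({"class": ["Desk"] * 10, "precision": vals})
        box = precision_distribution(rec)
        assert box.loc[0, "outliers"] == [0.1]
        assert box.loc[0, "whisker_low"] == pytest.approx(0.9)
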
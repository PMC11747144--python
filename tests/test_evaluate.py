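"""Cohort splitting, fold construction, metrics and the cohort report."""

import numpy as np
import pytest

from cupclf import (
    CLASSES,
    SampleSheet,
    SplitSpec,
    ValidationError,
    cohort_report,
    compute_metrics,
    make_stratified_folds,
    split_cohort,
)
from conftest import brute_force_metrics, random_instance

# class counts of the real 509-sample cohort
COHORT_COUNTS = {"breast": 143, "gyn": 91, "testis": 86, "lung": 85,
                 "kidney": 84, "colon": 20}


def _sheet(counts, met_count=0):
    ids, labels = [], []
    for organ, n in counts.items():
        for i in range(n):
            ids.append(f"{organ}{i}")
            labels.append(organ)
    mets = [i < met_count for i in range(len(ids))]
    return SampleSheet(ids, labels, ["b0"] * len(ids), mets)


class TestSplitCohort:
    def test_509_sample_split_sizes(self):
        sheet = _sheet(COHORT_COUNTS)
        spec = SplitSpec(0.70, 0.15, 0.15, seed=0)
        train, val, test = split_cohort(sheet, spec)
        assert (len(train), len(val), len(test)) == (356, 76, 77)
        assert set(train) | set(val) | set(test) == set(sheet.sample_ids)
        assert not set(train) & set(val) and not set(val) & set(test)

    def test_stratification_within_one_sample_per_class(self):
        sheet = _sheet(COHORT_COUNTS)
        train, val, test = split_cohort(sheet, SplitSpec(seed=1))
        label_of = sheet.label_of()
        n = sheet.n_samples
        for subset, size in ((train, 356), (val, 76), (test, 77)):
            for organ, count in COHORT_COUNTS.items():
                got = sum(label_of[s] == organ for s in subset)
                assert abs(got - count * size / n) <= 1.0

    def test_small_cohort_exact_arithmetic(self):
        sheet = _sheet({"breast": 5, "lung": 5})
        sizes = tuple(map(len, split_cohort(sheet, SplitSpec(0.8, 0.1, 0.1))))
        assert sizes == (8, 1, 1)

    def test_same_seed_reproducible(self):
        sheet = _sheet(COHORT_COUNTS)
        assert split_cohort(sheet, SplitSpec(seed=5)) == split_cohort(sheet, SplitSpec(seed=5))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            SplitSpec(0.7, 0.2, 0.2)


class TestStratifiedFolds:
    def test_balanced_two_class_deal(self):
        labels = ["a", "b"] * 5
        folds = make_stratified_folds(labels, 5, seed=0)
        for f in range(5):
            members = [labels[i] for i in np.flatnonzero(folds == f)]
            assert sorted(members) == ["a", "b"]

    def test_leave_one_out(self):
        labels = ["a"] * 4 + ["b"] * 4
        with pytest.warns(UserWarning):
            folds = make_stratified_folds(labels, 8, seed=0)
        assert sorted(folds) == list(range(8))

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        labels = [CLASSES[i] for i in rng.integers(0, 6, size=80)]
        folds = make_stratified_folds(labels, 10, seed=3)
        assert len(folds) == 80
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 80 and sizes.max() - sizes.min() <= 1

    def test_per_fold_class_counts_within_one(self):
        rng = np.random.default_rng(4)
        labels = [CLASSES[i] for i in rng.integers(0, 6, size=120)]
        folds = make_stratified_folds(labels, 6, seed=4)
        for organ in CLASSES:
            per_fold = [
                sum(1 for i in np.flatnonzero(folds == f) if labels[i] == organ)
                for f in range(6)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_small_class_warns_and_spreads(self):
        labels = ["breast"] * 20 + ["colon"] * 3
        with pytest.warns(UserWarning, match="colon"):
            folds = make_stratified_folds(labels, 5, seed=0)
        colon_folds = [folds[i] for i in range(20, 23)]
        assert len(set(colon_folds)) == 3


class TestComputeMetrics:
    def test_perfect_predictions(self):
        truth = list(CLASSES)
        p = np.eye(6)
        m = compute_metrics(p, truth, CLASSES)
        assert m["accuracy"] == m["top2_accuracy"] == m["macro_f1"] == 1.0
        np.testing.assert_array_equal(m["confusion"], np.eye(6, dtype=int))

    def test_hand_computed_toy_table(self):
        # truth (A,A,B,C) vs predicted (A,B,B,B):
        # accuracy 0.5; F1 = {A: 2/3, B: 1/2, C: 0}; macro = 7/18
        order = ["A", "B", "C"]
        p = np.array(
            [[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.1, 0.8, 0.1], [0.3, 0.5, 0.2]]
        )
        m = compute_metrics(p, ["A", "A", "B", "C"], order)
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["macro_f1"] == pytest.approx(7 / 18)

    def test_top2_tie_broken_by_class_order(self):
        order = ["A", "B", "C"]
        p = np.array([[0.4, 0.3, 0.3]])  # rank-2 tie between B and C
        assert compute_metrics(p, ["B"], order)["top2_accuracy"] == 1.0
        assert compute_metrics(p, ["C"], order)["top2_accuracy"] == 0.0

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p, truth = random_instance(rng)
            got = compute_metrics(p, truth, CLASSES)
            want = brute_force_metrics(p, truth, CLASSES)
            assert abs(got["accuracy"] - want["accuracy"]) < 1e-12
            assert abs(got["top2_accuracy"] - want["top2_accuracy"]) < 1e-12
            assert abs(got["macro_f1"] - want["macro_f1"]) < 1e-12
            np.testing.assert_array_equal(got["confusion"], want["confusion"])

    def test_confusion_row_sums_and_trace(self):
        rng = np.random.default_rng(1)
        p, truth = random_instance(rng)
        m = compute_metrics(p, truth, CLASSES)
        conf = m["confusion"]
        for ci, organ in enumerate(CLASSES):
            assert conf[ci].sum() == truth.count(organ)
        assert conf.sum() == len(truth)
        assert m["accuracy"] == pytest.approx(np.trace(conf) / len(truth))
        assert m["top2_accuracy"] >= m["accuracy"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(np.eye(6), ["breast"], CLASSES)


class TestCohortReport:
    def test_reference_cohort_arithmetic(self):
        sheet = _sheet(COHORT_COUNTS, met_count=82)
        rep = cohort_report(sheet)
        assert rep["total"] == 509
        assert rep["classes"]["breast"] == {"count": 143, "percent": 28}
        assert rep["classes"]["gyn"]["percent"] == 18
        assert rep["classes"]["testis"]["percent"] == 17
        assert rep["classes"]["lung"]["percent"] == 17
        assert rep["classes"]["colon"]["percent"] == 4
        # kidney: 84/509 = 16.503% -> 17 under round-half-up (documented)
        assert rep["classes"]["kidney"]["count"] == 84
        assert rep["metastasis_count"] == 82
        assert rep["metastasis_percent"] == 16

    def test_single_class_is_100_percent(self):
        rep = cohort_report(_sheet({"testis": 7}))
        assert rep["classes"]["testis"]["percent"] == 100

    def test_empty_sheet_rejected(self):
        with pytest.raises(ValidationError):
            cohort_report(SampleSheet([], [], [], []))
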
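"""Metrics, stratified fold assignment, cross-validation and split evaluation."""

import numpy as np
import pytest

from tfpartner.evaluate import (
    ConfusionCounts,
    assign_folds,
    cross_validate,
    metrics_from_counts,
    split_evaluate,
)
from tfpartner.features import Task, featurize_proteins
from tfpartner.models import Hyperparameters
from tfpartner.sequences import InteractionPair
from tfpartner.simulate import SyntheticConfig, generate_dataset

FAST_HP = Hyperparameters(n_trees=15)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(tp=90, fn=10, tn=80, fp=20), (0.85, 0.90, 0.80)),
            (ConfusionCounts(tp=5, fn=0, tn=5, fp=0), (1.0, 1.0, 1.0)),
            (ConfusionCounts(tp=0, fn=0, tn=7, fp=3), (0.7, None, 0.7)),
            (ConfusionCounts(tp=4, fn=6, tn=0, fp=0), (0.4, 0.4, None)),
        ],
    )
    def test_hand_computed_rates(self, counts, expected):
        m = metrics_from_counts(counts)
        assert (m.accuracy, m.sensitivity, m.specificity) == expected

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            metrics_from_counts(ConfusionCounts())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=1)

    def test_rates_are_exact_rationals(self):
        m = metrics_from_counts(ConfusionCounts(tp=1, fn=2, tn=1, fp=2))
        assert m.sensitivity == 1 / 3
        assert m.accuracy == 2 / 6


def _toy_pairs(n_pos=60, n_neg=40):
    pairs = [InteractionPair(f"T{i:03d}", f"P{i:03d}", "TCOF") for i in range(n_pos)]
    pairs += [InteractionPair(f"T{i:03d}", f"P{i:03d}", "OTHER")
              for i in range(n_pos, n_pos + n_neg)]
    return pairs


class TestAssignFolds:
    def test_partition_property(self):
        pairs = _toy_pairs()
        folds = assign_folds(pairs, k=10, seed=3)
        assert len(folds) == 100
        sizes = np.bincount(folds, minlength=10)
        assert sizes.tolist() == [10] * 10

    def test_stratification_within_one(self):
        pairs = _toy_pairs(55, 34)
        folds = assign_folds(pairs, k=7, seed=1)
        for cls in ("TCOF", "OTHER"):
            members = np.array([f for f, p in zip(folds, pairs) if p.label == cls])
            per_fold = np.bincount(members, minlength=7)
            assert per_fold.max() - per_fold.min() <= 1

    def test_deterministic_and_order_insensitive(self):
        pairs = _toy_pairs()
        folds = assign_folds(pairs, k=5, seed=9)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(pairs))
        shuffled = [pairs[i] for i in order]
        reassigned = assign_folds(shuffled, k=5, seed=9)
        by_pair = {shuffled[i]: reassigned[i] for i in range(len(pairs))}
        assert all(by_pair[p] == f for p, f in zip(pairs, folds))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            assign_folds(_toy_pairs(3, 3), k=10, seed=0)

    def test_tiny_class_rejected_with_suggestion(self):
        pairs = _toy_pairs(9, 0) + [InteractionPair("TX", "PX", "OTHER")]
        with pytest.raises(ValueError, match="at least 2 per class"):
            assign_folds(pairs, k=5, seed=0)


@pytest.fixture(scope="module")
def tiny_eval_data():
    cfg = SyntheticConfig(n_tf_tcof=20, n_tf_tf=20, n_tf_other=20,
                          length_range=(40, 80), n_indices=8, seed=23)
    ds = generate_dataset(cfg)
    features = featurize_proteins(ds.records, ds.index_set)
    return ds, features


class TestCrossValidate:
    def test_each_pair_tested_exactly_once(self, tiny_eval_data):
        ds, features = tiny_eval_data
        report = cross_validate(ds.pairs, features, Task.MODEL1, k=5,
                                hyperparameters=FAST_HP, seed=2)
        assert sum(f.n_test for f in report.folds) == len(ds.pairs)
        assert report.aggregate_counts.total == len(ds.pairs)

    def test_same_seed_same_report(self, tiny_eval_data):
        ds, features = tiny_eval_data
        a = cross_validate(ds.pairs, features, Task.MODEL2, k=3,
                           hyperparameters=FAST_HP, seed=4)
        b = cross_validate(ds.pairs, features, Task.MODEL2, k=3,
                           hyperparameters=FAST_HP, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_input_order_does_not_change_report(self, tiny_eval_data):
        ds, features = tiny_eval_data
        a = cross_validate(ds.pairs, features, Task.MODEL1, k=3,
                           hyperparameters=FAST_HP, seed=4)
        shuffled = [ds.pairs[i] for i in np.random.default_rng(1).permutation(len(ds.pairs))]
        b = cross_validate(shuffled, features, Task.MODEL1, k=3,
                           hyperparameters=FAST_HP, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_aggregate_equals_sum_of_folds_and_rates_recompute(self, tiny_eval_data):
        ds, features = tiny_eval_data
        report = cross_validate(ds.pairs, features, Task.MODEL1, k=4,
                                hyperparameters=FAST_HP, seed=0)
        agg = ConfusionCounts()
        for f in report.folds:
            agg = agg + f.counts
        assert agg == report.aggregate_counts
        m = metrics_from_counts(agg)
        assert report.metrics == m

    def test_leave_one_out_on_toy_set(self, tiny_eval_data):
        _, features = tiny_eval_data
        ds, _f = _small_loo_data(features)
        report = cross_validate(ds, features, Task.MODEL1, k=10,
                                hyperparameters=FAST_HP, seed=1)
        assert len(report.folds) == 10
        assert all(f.n_test == 1 for f in report.folds)

    def test_unlabeled_pair_rejected(self, tiny_eval_data):
        ds, features = tiny_eval_data
        pairs = list(ds.pairs) + [InteractionPair(ds.pairs[0].tf_id, ds.pairs[1].partner_id)]
        with pytest.raises(ValueError, match="unlabeled"):
            cross_validate(pairs, features, Task.MODEL1, k=3, hyperparameters=FAST_HP)


def _small_loo_data(features):
    ids = sorted(features)
    pairs = [
        InteractionPair(ids[i], ids[i + 1], "TCOF" if i < 5 else "OTHER")
        for i in range(10)
    ]
    return pairs, features


class TestSplitEvaluate:
    def test_stratified_ninety_ten(self, tiny_eval_data):
        ds, features = tiny_eval_data
        report = split_evaluate(ds.pairs, features, Task.MODEL1, train_fraction=0.9,
                                hyperparameters=FAST_HP, seed=5)
        (fold,) = report.folds
        assert fold.n_train == 54 and fold.n_test == 6
        # 40 positives (TCOF+TF) and 20 negatives: the 10% hold-out keeps 2:1
        assert fold.class_balance.get("OTHER", 0) == 2
        assert sum(fold.class_balance.values()) == 6

    def test_two_thirds_split_sizes(self):
        ds = generate_dataset(SyntheticConfig(n_tf_tcof=66, n_tf_tf=0, n_tf_other=33,
                                              length_range=(30, 50), n_indices=6, seed=3))
        features = featurize_proteins(ds.records, ds.index_set)
        report = split_evaluate(ds.pairs, features, Task.MODEL1, train_fraction=2 / 3,
                                hyperparameters=FAST_HP, seed=5)
        (fold,) = report.folds
        assert fold.n_train == 66 and fold.n_test == 33

    def test_invalid_fraction_rejected(self, tiny_eval_data):
        ds, features = tiny_eval_data
        with pytest.raises(ValueError, match="between 0 and 1"):
            split_evaluate(ds.pairs, features, Task.MODEL1, train_fraction=1.0)

    def test_class_absent_from_subset_rejected(self, tiny_eval_data):
        ds, features = tiny_eval_data
        few = [p for p in ds.pairs if p.label == "TCOF"][:1] + \
              [p for p in ds.pairs if p.label == "OTHER"]
        with pytest.raises(ValueError, match="absent"):
            split_evaluate(few, features, Task.MODEL1, train_fraction=0.95,
                           hyperparameters=FAST_HP)


def test_report_tsv_row_format(tiny_eval_data):
    ds, features = tiny_eval_data
    report = cross_validate(ds.pairs, features, Task.MODEL2, k=3,
                            hyperparameters=FAST_HP, seed=0)
    row = report.tsv_row().split("\t")
    assert row[0] == "MODEL2" and row[1] == "3-fold"
    assert 0.0 <= float(row[3]) <= 1.0
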
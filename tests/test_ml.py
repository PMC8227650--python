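"""Classifier-evaluation protocols: grids, leakage rules, metrics."""

import numpy as np
import pandas as pd
import pytest

from edapain.ml import (
    GRIDS,
    ClassifierSpec,
    ConfusionCounts,
    evaluate_cross_dataset,
    evaluate_protocol1,
    grid_search_subjectwise,
    metrics,
)
from edapain.records import ValidationError
from edapain.segments import FEATURE_COLUMNS


def make_table(n_subjects, n_events=10, shift=2.0, seed=0, prefix="s", dataset="synthetic"):
    """Separable (shift>0) or null (shift=0) synthetic feature table."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        offset = rng.normal(0, 0.5)
        for e in range(n_events):
            for label in (0, 1):
                feats = rng.normal(offset, 1.0, len(FEATURE_COLUMNS))
                if label:
                    feats = feats + shift
                rows.append(
                    {
                        "subject_id": f"{prefix}{i}",
                        "dataset": dataset,
                        "event_time_s": float(e),
                        "label": label,
                        **dict(zip(FEATURE_COLUMNS, feats)),
                    }
                )
    return pd.DataFrame(rows)


class TestGridsAndMetrics:
    def test_grid_contents(self):
        assert [g["C"] for g in GRIDS["L-SVM"]] == [1, 10, 100, 1000]
        gammas = sorted({g["gamma"] for g in GRIDS["R-SVM"]})
        assert gammas == [0.0001, 0.001, 0.1]
        assert {g["criterion"] for g in GRIDS["RandomForest"]} == {"gini", "entropy"}
        assert {g["n_neighbors"] for g in GRIDS["KNN"]} == {3, 5, 7, 9}
        assert len(GRIDS["MLP"]) == 3 * 3 * 3 * 3
        assert len(GRIDS["LogisticRegression"]) == 5

    def test_standardization_flag(self):
        assert not ClassifierSpec("RandomForest").standardize
        assert not ClassifierSpec("DecisionTree").standardize
        assert ClassifierSpec("L-SVM").standardize

    def test_perfect_and_coin_flip_metrics(self):
        assert metrics(ConfusionCounts(5, 5, 0, 0)) == (1.0, 1.0, 1.0)
        assert metrics(ConfusionCounts(1, 1, 1, 1)) == (0.5, 0.5, 0.5)

    def test_zero_denominator_flagged_missing(self):
        acc, sens, spec = metrics(ConfusionCounts(tp=0, tn=3, fp=1, fn=0))
        assert sens is None and spec is not None and acc is not None

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierSpec("GradientBoosting")


class TestGridSearch:
    def test_single_point_grid_returned(self):
        table = make_table(6, n_events=3, seed=1)
        spec = ClassifierSpec("L-SVM", grid=[{"C": 10}])
        assert grid_search_subjectwise(table, spec, seed=0) == {"C": 10}

    def test_separable_data_recovers_good_params(self):
        table = make_table(8, n_events=5, shift=3.0, seed=2)
        spec = ClassifierSpec("KNN")
        params = grid_search_subjectwise(table, spec, seed=0)
        assert params in GRIDS["KNN"]

    def test_deterministic_given_seed(self):
        table = make_table(7, n_events=4, shift=0.5, seed=3)
        spec = ClassifierSpec("R-SVM")
        assert grid_search_subjectwise(table, spec, seed=5) == grid_search_subjectwise(
            table, spec, seed=5
        )


class TestProtocol1:
    def test_strong_effect_high_accuracy(self):
        table = make_table(8, n_events=6, shift=3.0, seed=4)
        res = evaluate_protocol1(table, ClassifierSpec("RandomForest"), seed=0)
        assert res.accuracy >= 0.9
        assert len(res.fold_metrics) == 8  # one fold per subject

    def test_null_labels_near_chance(self):
        table = make_table(8, n_events=6, shift=0.0, seed=5)
        res = evaluate_protocol1(table, ClassifierSpec("RandomForest"), seed=0)
        assert 0.4 <= res.accuracy <= 0.6

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_protocol1(make_table(4), ClassifierSpec("KNN"), seed=0)

    def test_no_leakage_of_test_subject_into_any_fit(self):
        # instrumentation: for every model fit (grid-search or final) of a
        # fold, the held-out subject must be absent from the training subjects
        table = make_table(6, n_events=4, shift=2.0, seed=6)
        seen = []

        def audit(held, train_subjects):
            seen.append((held, frozenset(train_subjects)))
            assert held not in train_subjects

        evaluate_protocol1(table, ClassifierSpec("KNN"), seed=0, audit=audit)
        assert len(seen) > 6  # grid-search fits plus one final fit per fold
        assert {h for h, _ in seen} == set(table["subject_id"])


class TestCrossDataset:
    def test_same_generator_matches_protocol1(self):
        train = make_table(8, n_events=6, shift=2.5, seed=7, prefix="a", dataset="EP")
        test = make_table(8, n_events=6, shift=2.5, seed=8, prefix="b", dataset="TG")
        res2 = evaluate_cross_dataset(train, test, ClassifierSpec("L-SVM"), seed=0, n_boot=200)
        pooled = make_table(8, n_events=6, shift=2.5, seed=9)
        res1 = evaluate_protocol1(pooled, ClassifierSpec("L-SVM"), seed=0)
        assert abs(res2.accuracy - res1.accuracy) <= 0.1

    def test_flipped_labels_mirror_accuracy(self):
        train = make_table(6, n_events=5, shift=2.5, seed=10, prefix="a")
        test = make_table(6, n_events=5, shift=2.5, seed=11, prefix="b")
        res = evaluate_cross_dataset(train, test, ClassifierSpec("L-SVM"), seed=0, n_boot=50)
        flipped = test.copy()
        flipped["label"] = 1 - flipped["label"]
        res_f = evaluate_cross_dataset(train, flipped, ClassifierSpec("L-SVM"), seed=0, n_boot=50)
        assert res_f.accuracy == pytest.approx(1.0 - res.accuracy, abs=1e-9)

    def test_empty_test_rejected(self):
        train = make_table(6, n_events=3, seed=12)
        with pytest.raises(ValidationError):
            evaluate_cross_dataset(train, train.iloc[:0], ClassifierSpec("KNN"), seed=0)

    def test_overlapping_subjects_rejected(self):
        t = make_table(6, n_events=3, seed=13)
        with pytest.raises(ValidationError):
            evaluate_cross_dataset(t, t, ClassifierSpec("KNN"), seed=0)
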
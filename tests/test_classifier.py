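"""Classifier training protocol: stratified split, CV model selection,
prediction, and persistence."""

import warnings

import numpy as np
import pytest

from orgscreen import classify
from orgscreen.classify import (
    CVReport,
    cross_validate,
    load_bundle,
    predict,
    read_predictions,
    save_bundle,
    stratified_split,
    train_best,
    write_predictions,
)
from orgscreen.errors import InputError, SchemaError

from conftest import make_labeled_table


class TestStratifiedSplit:
    def test_proportions_and_partition(self, separable_table):
        train, test = stratified_split(separable_table, seed=3)
        # default ratio train:test = 1:5
        assert len(train) + len(test) == len(separable_table)
        assert set(train.seq_ids).isdisjoint(test.seq_ids)
        y = separable_table.label_array()
        for cls in ("nuclear", "mitochondrion", "plastid"):
            total = int((y == cls).sum())
            in_train = sum(1 for s in train.seq_ids if train.labels[s] == cls)
            assert abs(in_train - total / 6) <= 1

    def test_deterministic(self, separable_table):
        a = stratified_split(separable_table, seed=5)
        b = stratified_split(separable_table, seed=5)
        assert a[0].seq_ids == b[0].seq_ids and a[1].seq_ids == b[1].seq_ids

    def test_tiny_class_rejected(self):
        table = make_labeled_table(n_nuclear=20, n_mito=1, n_plastid=0, seed=0)
        with pytest.raises(InputError, match="mitochondrion"):
            stratified_split(table)


class TestCrossValidate:
    def test_separable_table_reaches_perfect_mcc(self, separable_table):
        report = cross_validate(separable_table, k=5, seed=0)
        best = report.best_family()
        assert report.mean_mcc[best] == 1.0
        assert all(len(v) == 5 for v in report.fold_mcc.values())

    def test_permuted_labels_give_no_signal(self):
        table = make_labeled_table(n_nuclear=800, n_mito=100, n_plastid=100, seed=2, separable=False)
        report = cross_validate(table, families=("linear",), k=5, seed=2)
        assert -0.2 <= report.mean_mcc["linear"] <= 0.2

    def test_k_lowered_for_small_minority(self):
        table = make_labeled_table(n_nuclear=40, n_mito=5, n_plastid=5, seed=1)
        with pytest.warns(UserWarning, match="lowering k"):
            report = cross_validate(table, families=("linear",), k=10, seed=1)
        assert report.k == 5

    def test_empty_family_list_rejected(self, separable_table):
        with pytest.raises(InputError):
            cross_validate(separable_table, families=())

    def test_deterministic_given_seed(self, separable_table):
        a = cross_validate(separable_table, families=("linear", "adaboost"), k=4, seed=9)
        b = cross_validate(separable_table, families=("linear", "adaboost"), k=4, seed=9)
        assert a.fold_mcc == b.fold_mcc and a.mean_mcc == b.mean_mcc


class TestTrainBest:
    def test_highest_mcc_family_wins(self, separable_table):
        report = CVReport(k=2, seed=0, fold_mcc={"linear": [0.9], "knn": [0.5]},
                          mean_mcc={"linear": 0.9, "knn": 0.5},
                          ovr_mean_mcc={"linear": {}, "knn": {}})
        bundle = train_best(separable_table, report, seed=0)
        assert bundle.model_family == "linear"

    def test_tie_goes_to_adaboost(self, separable_table):
        report = CVReport(k=2, seed=0,
                          fold_mcc={f: [1.0] for f in classify.FAMILIES},
                          mean_mcc={f: 1.0 for f in classify.FAMILIES},
                          ovr_mean_mcc={f: {} for f in classify.FAMILIES})
        assert report.best_family() == "adaboost"
        bundle = train_best(separable_table, report, seed=0)
        assert bundle.model_family == "adaboost"

    def test_training_rows_memorized_on_separable_fixture(self, separable_table):
        report = cross_validate(separable_table, families=("random_forest",), k=3, seed=0)
        bundle = train_best(separable_table, report, seed=0)
        preds = predict(bundle, separable_table)
        truth = separable_table.labels
        agree = sum(p.predicted_class == truth[p.seq_id] for p in preds)
        assert agree == len(preds)


@pytest.fixture(scope="module")
def bundle(separable_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = cross_validate(separable_table, families=("linear",), k=3, seed=0)
        return train_best(separable_table, report, seed=0)


class TestPredict:

    def test_scores_sum_to_one(self, bundle, separable_table):
        for p in predict(bundle, separable_table):
            assert sum(p.class_scores.values()) == pytest.approx(1.0, abs=1e-9)
            assert max(p.class_scores, key=p.class_scores.get) == p.predicted_class

    def test_all_zero_row_goes_to_majority_class(self):
        # majority-prior fixture: features carry no class signal and no
        # re-weighting is applied, so the dominant class wins everywhere
        table = make_labeled_table(n_nuclear=150, n_mito=10, n_plastid=10, seed=4, separable=False)
        report = cross_validate(table, families=("linear",), k=3, seed=0, weighting="none")
        b = train_best(table, report, seed=0, weighting="none")
        frame = table.frame.iloc[:1].copy()
        for col in frame.columns:
            if col == "seq_id":
                continue
            frame[col] = 1 if col == "length_bp" else 0
        from orgscreen.features import LabeledTable

        p = predict(b, LabeledTable(frame=frame))[0]
        assert p.predicted_class == "nuclear"

    def test_schema_mismatch_lists_columns(self, bundle, separable_table):
        frame = separable_table.frame.drop(columns=["trna_density"]).copy()
        frame["bogus"] = 1.0
        broken = separable_table.frame.__class__(frame)
        table = type(separable_table)(frame=separable_table.frame, labels=None)
        table.frame = broken  # bypass column validation to hit predict's check
        with pytest.raises(SchemaError, match="trna_density"):
            predict(bundle, table)

    def test_persistence_round_trip(self, bundle, separable_table, tmp_path):
        p = tmp_path / "model.joblib"
        save_bundle(bundle, p)
        reloaded = load_bundle(p)
        a = predict(bundle, separable_table)
        b = predict(reloaded, separable_table)
        assert a == b

    def test_bad_archive_rejected(self, tmp_path):
        import joblib

        p = tmp_path / "bad.joblib"
        joblib.dump({"something": "else"}, p)
        with pytest.raises(SchemaError):
            load_bundle(p)

    def test_predictions_tsv_round_trip(self, bundle, separable_table, tmp_path):
        preds = predict(bundle, separable_table)
        p = tmp_path / "preds.tsv"
        write_predictions(preds, p)
        back = read_predictions(p)
        assert back == {x.seq_id: x.predicted_class for x in preds}
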
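"""Metrics (with independent oracles), tuning, ensemble training, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import precision_score

from stratims.containers import FeatureMatrix, PeakAxis
from stratims.exceptions import (
    DegenerateLabelError,
    EmptyInputError,
    FoldConstructionError,
    MetadataJoinError,
)
from stratims.feature_engineering import build_stratified_subsets
from stratims.subtype_model import (
    HyperParams,
    aggregate_core_predictions,
    auc_one_vs_one,
    balanced_accuracy,
    confusion_matrix,
    evaluate_ensemble,
    false_discovery_rate,
    predict_spectra,
    train_subtype_ensemble,
    tune_hyperparameters,
)


class TestBalancedAccuracy:
    def test_worked_example(self):
        assert balanced_accuracy([[8, 2], [4, 6]]) == pytest.approx(0.7)

    def test_perfect_matrix_is_one(self):
        assert balanced_accuracy(np.diag([5, 9, 2, 7])) == 1.0

    def test_random_four_class_assignment_near_quarter(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 40000)
        p = rng.integers(0, 4, 40000)
        cm = confusion_matrix([str(v) for v in y], [str(v) for v in p])
        assert balanced_accuracy(cm) == pytest.approx(0.25, abs=0.02)

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyInputError):
            balanced_accuracy(np.zeros((3, 3)))


class TestFalseDiscoveryRate:
    def test_worked_example(self):
        per_class, macro = false_discovery_rate(np.array([[8, 2], [4, 6]]))
        assert per_class.iloc[0] == pytest.approx(4 / 12)
        assert per_class.iloc[1] == pytest.approx(0.25)
        assert macro == pytest.approx((4 / 12 + 0.25) / 2)

    def test_perfect_predictions_are_zero(self):
        _, macro = false_discovery_rate(np.diag([3, 4, 5]))
        assert macro == 0.0

    def test_complement_of_precision_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.choice(["a", "b"], 500)
        p = np.where(rng.random(500) < 0.8, y, rng.choice(["a", "b"], 500))
        cm = confusion_matrix(y, p, classes=["a", "b"])
        _, macro = false_discovery_rate(cm)
        oracle = 1.0 - precision_score(y, p, average="macro")
        assert macro == pytest.approx(oracle, abs=1e-12)


class TestAucOneVsOne:
    def test_perfect_separation_is_one(self):
        scores = pd.DataFrame({"C1": [0.9, 0.8, 0.2, 0.1]})
        scores["C2"] = 1 - scores["C1"]
        _, auc = auc_one_vs_one(scores, ["C1", "C1", "C2", "C2"])
        assert auc == 1.0

    def test_two_class_equals_rank_sum_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n2 = rng.integers(5, 40, 2)
            s1, s2 = rng.normal(0.3, 1, n1), rng.normal(0.0, 1, n2)
            scores = pd.DataFrame({"C1": np.concatenate([s1, s2])})
            scores["C2"] = -scores["C1"]
            labels = ["C1"] * n1 + ["C2"] * n2
            _, auc = auc_one_vs_one(scores, labels)
            u = mannwhitneyu(s1, s2, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        n = 2000
        labels = np.repeat(["C1", "C2", "C4", "C5"], n)
        scores = pd.DataFrame(rng.random((4 * n, 4)), columns=["C1", "C2", "C4", "C5"])
        _, auc = auc_one_vs_one(scores, labels)
        assert abs(auc - 0.5) < 0.03

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["C1", "C2", "C4"], 300)
        scores = pd.DataFrame(rng.random((300, 3)), columns=["C1", "C2", "C4"])
        _, auc = auc_one_vs_one(scores, labels)
        perm = {"C1": "C4", "C2": "C1", "C4": "C2"}
        relabeled = np.array([perm[l] for l in labels])
        renamed = scores.rename(columns=perm)
        _, auc2 = auc_one_vs_one(renamed, relabeled)
        assert auc == pytest.approx(auc2, abs=1e-12)


def _labeled_matrix(n_per_class=30, n_features=6, separation=3.0, seed=0, cores_per_class=3):
    rng = np.random.default_rng(seed)
    classes = ["C1", "C2", "C4", "C5"]
    rows, labels, cores = [], [], []
    for k, cls in enumerate(classes):
        mean = np.zeros(n_features)
        mean[k] = separation
        for i in range(n_per_class):
            rows.append(rng.normal(mean, 1.0))
            labels.append(cls)
            cores.append(f"{cls}_c{i % cores_per_class}")
    meta = pd.DataFrame({
        "x": np.arange(len(rows)), "y": 0, "core_id": cores, "patient_id": cores,
        "subtype": labels,
    })
    axis = PeakAxis(900.0 + np.arange(n_features, dtype=float))
    return FeatureMatrix(values=np.asarray(rows), axis=axis, meta=meta)


class TestTuneHyperparameters:
    def test_result_lies_on_declared_grid_and_is_deterministic(self):
        matrix = _labeled_matrix(n_per_class=15, seed=2)
        params = tune_hyperparameters(matrix, seed=9, trees=10)
        fps_grid = np.geomspace(0.05, 0.8, 4)
        assert any(np.isclose(params.features_per_split, fps_grid))
        assert params.min_node_size in (1, 5, 10, 20)
        params2 = tune_hyperparameters(matrix, seed=9, trees=10)
        assert params == params2

    def test_class_smaller_than_fold_count_rejected(self):
        matrix = _labeled_matrix(n_per_class=2, seed=3)
        with pytest.raises(FoldConstructionError):
            tune_hyperparameters(matrix, cv_folds=3, trees=5)


@pytest.fixture(scope="module")
def trained():
    matrix = _labeled_matrix(n_per_class=40, separation=4.0, seed=4, cores_per_class=4)
    subsets = build_stratified_subsets(matrix, seed=8, split_unit="core")
    params = HyperParams(trees=50, features_per_split=0.5, min_node_size=1)
    ensemble = train_subtype_ensemble(
        matrix, subsets, params, selection_fraction=1.0, selection_forest_size=20
    )
    return matrix, subsets, ensemble


class TestEnsembleTrainingAndPrediction:
    def test_three_members_paired_with_their_subsets(self, trained):
        matrix, subsets, ensemble = trained
        assert len(ensemble.members) == 3
        for member, subset in zip(ensemble.members, subsets):
            assert member.subset.replicate_id == subset.replicate_id
            assert member.held_out_metrics["n_test"] == len(subset.test_rows)

    def test_separable_data_gives_high_held_out_accuracy(self, trained):
        _, _, ensemble = trained
        for member in ensemble.members:
            assert member.held_out_metrics["balanced_accuracy"] >= 0.9

    def test_probability_rows_are_simplices(self, trained):
        matrix, _, ensemble = trained
        table = predict_spectra(ensemble, matrix)
        np.testing.assert_allclose(table.mean.sum(axis=1), 1.0, atol=1e-9)
        for member_table in table.members:
            np.testing.assert_allclose(member_table.sum(axis=1), 1.0, atol=1e-9)

    def test_training_rows_recover_their_class(self, trained):
        matrix, _, ensemble = trained
        table = predict_spectra(ensemble, matrix)
        pred = table.mean.idxmax(axis=1)
        assert (pred.to_numpy() == matrix.labels("subtype").to_numpy()).mean() > 0.95

    def test_empty_matrix_gives_empty_table(self, trained):
        matrix, _, ensemble = trained
        empty = matrix.take_rows(np.array([], dtype=int))
        table = predict_spectra(ensemble, empty)
        assert len(table.mean) == 0

    def test_evaluation_report_fields(self, trained):
        matrix, _, ensemble = trained
        report = evaluate_ensemble(ensemble, matrix)
        assert 0.9 <= report.mean_ovo_auc <= 1.0
        assert 0.0 <= report.fdr_macro_mean <= 1.0
        assert len(report.confusions) == 3
        for cm, n in zip(report.confusions, report.per_member["n_test"]):
            assert cm.to_numpy().sum() == n


class TestAggregateCorePredictions:
    def test_uniform_core_keeps_its_class(self):
        probs = pd.DataFrame({"C1": [0.1, 0.2], "C2": [0.9, 0.8]})
        agg = aggregate_core_predictions(probs, ["a", "a"])
        assert agg.loc["a", "label"] == "C2"

    def test_exact_tie_resolves_to_canonical_order(self):
        probs = pd.DataFrame({"C1": [0.5, 0.5], "C5": [0.5, 0.5]})
        agg = aggregate_core_predictions(probs, ["a", "a"])
        assert agg.loc["a", "label"] == "C1"

    def test_unmapped_spectrum_rejected(self):
        probs = pd.DataFrame({"C1": [1.0], "C2": [0.0]})
        with pytest.raises(MetadataJoinError):
            aggregate_core_predictions(probs, [np.nan])
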
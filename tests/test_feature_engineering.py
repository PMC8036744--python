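"""Parity alignment, scaling, stratified subsets, Gini feature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stratims.containers import FeatureMatrix, PeakAxis
from stratims.exceptions import DegenerateLabelError, ParameterError, StratificationError
from stratims.feature_engineering import (
    align_to_reference_axis,
    build_stratified_subsets,
    scale_features,
    select_top_features,
)


def _axis(centers):
    return PeakAxis(np.asarray(centers, dtype=float))


class TestAlignToReferenceAxis:
    def test_nearest_within_tolerance_wins(self):
        mapping = align_to_reference_axis(_axis([999.80, 1000.10, 1000.30]), _axis([1000.00]))
        assert mapping.n_pairs == 1
        row = mapping.pairs.iloc[0]
        assert (row["source"], row["reference"]) == (1000.10, 1000.00)
        assert abs(row["abs_diff"] - 0.10) < 1e-9
        assert set(mapping.unmatched_source) == {999.80, 1000.30}

    def test_reference_without_partner_reported_unmatched(self):
        mapping = align_to_reference_axis(_axis([1000.0]), _axis([1000.1, 1005.0]))
        assert 1005.0 in mapping.unmatched_reference

    def test_identical_axes_map_identically(self):
        centers = [900.0, 950.5, 1000.25]
        mapping = align_to_reference_axis(_axis(centers), _axis(centers))
        assert mapping.n_pairs == 3
        assert mapping.unmatched_reference.size == 0
        assert mapping.unmatched_source.size == 0
        assert np.allclose(mapping.pairs["abs_diff"], 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(800, 1200), min_size=1, max_size=30, unique=True),
           st.lists(st.floats(800, 1200), min_size=1, max_size=30, unique=True))
    def test_symmetric_under_swap(self, a, b):
        ax_a, ax_b = _axis(sorted(a)), _axis(sorted(b))
        fwd = align_to_reference_axis(ax_a, ax_b)
        rev = align_to_reference_axis(ax_b, ax_a)
        fwd_pairs = set(zip(fwd.pairs["source"], fwd.pairs["reference"]))
        rev_pairs = set(zip(rev.pairs["reference"], rev.pairs["source"]))
        assert fwd_pairs == rev_pairs

    def test_empty_reference_rejected(self):
        with pytest.raises(ParameterError):
            align_to_reference_axis(_axis([900.0]), PeakAxis(np.empty(0)))


def _matrix(values, labels=None, cores=None, axis=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    meta = pd.DataFrame({
        "x": np.arange(n), "y": 0,
        "core_id": cores if cores is not None else [f"c{i}" for i in range(n)],
        "patient_id": "p",
    })
    if labels is not None:
        meta["subtype"] = labels
    if axis is None:
        axis = _axis(900.0 + np.arange(values.shape[1]))
    return FeatureMatrix(values=values, axis=axis, meta=meta)


class TestScaleFeatures:
    def test_column_standardized(self):
        scaled, stats = scale_features(_matrix([[1.0], [2.0], [3.0]]))
        assert abs(scaled.values.mean()) < 1e-12
        assert abs(scaled.values.std() - 1.0) < 1e-12

    def test_constant_column_maps_to_zero(self):
        scaled, _ = scale_features(_matrix([[7.0], [7.0], [7.0]]))
        np.testing.assert_array_equal(scaled.values, 0.0)

    def test_rescaling_standardized_data_is_noop(self):
        scaled, _ = scale_features(_matrix([[1.0, 5.0], [2.0, 9.0], [4.0, 2.0]]))
        again, _ = scale_features(scaled)
        np.testing.assert_allclose(again.values, scaled.values, atol=1e-12)

    def test_train_stats_applied_to_test_matrix(self):
        train = _matrix([[0.0], [2.0]])
        test = _matrix([[4.0]])
        _, stats = scale_features(train)
        scaled_test, _ = scale_features(test, stats=stats)
        assert scaled_test.values[0, 0] == pytest.approx((4.0 - 1.0) / 1.0)


def _toy_cohort():
    """Classes C1: 100 spectra/10 cores, C2: 40/4, C4: 20/2, C5: 30/3."""
    rows, labels, cores = [], [], []
    spec = {"C1": (10, 10), "C2": (4, 10), "C4": (2, 10), "C5": (3, 10)}
    rng = np.random.default_rng(0)
    for cls, (n_cores, per_core) in spec.items():
        for c in range(n_cores):
            for _ in range(per_core):
                rows.append(rng.normal(size=3))
                labels.append(cls)
                cores.append(f"{cls}_core{c}")
    return _matrix(np.asarray(rows), labels=labels, cores=cores)


class TestBuildStratifiedSubsets:
    def test_rarest_class_fully_included_and_balance_bounded(self):
        matrix = _toy_cohort()
        for subset in build_stratified_subsets(matrix, seed=1, split_unit="spectrum"):
            rows = subset.rows
            labels = matrix.meta.loc[rows, "subtype"]
            counts = labels.value_counts()
            assert counts["C4"] == 20  # never subsampled
            for cls in ("C1", "C2", "C5"):
                assert 20 <= counts[cls] < 20 + 10  # within one core's worth

    def test_split_disjoint_and_70_30_per_class(self):
        matrix = _toy_cohort()
        for subset in build_stratified_subsets(matrix, seed=3, split_unit="spectrum"):
            assert not set(subset.train_rows) & set(subset.test_rows)
            labels = matrix.meta["subtype"]
            for cls in ("C1", "C2", "C4", "C5"):
                n_cls = np.isin(subset.rows, np.flatnonzero(labels == cls)).sum()
                n_test = np.isin(subset.test_rows, np.flatnonzero(labels == cls)).sum()
                assert abs(n_test - 0.3 * n_cls) <= 1

    def test_core_split_keeps_cores_whole(self):
        matrix = _toy_cohort()
        for subset in build_stratified_subsets(matrix, seed=4, split_unit="core"):
            train_cores = set(matrix.meta.loc[subset.train_rows, "core_id"])
            test_cores = set(matrix.meta.loc[subset.test_rows, "core_id"])
            assert not train_cores & test_cores

    def test_replicates_sample_different_cores(self):
        matrix = _toy_cohort()
        subsets = build_stratified_subsets(matrix, seed=5, split_unit="spectrum")
        assert len({tuple(sorted(s.sampled_cores)) for s in subsets}) > 1

    def test_no_duplicate_rows_within_replicate(self):
        matrix = _toy_cohort()
        for subset in build_stratified_subsets(matrix, seed=6, split_unit="spectrum"):
            assert len(subset.rows) == len(set(subset.rows))

    def test_single_class_rejected(self):
        matrix = _matrix(np.zeros((10, 2)), labels=["C1"] * 10)
        with pytest.raises(StratificationError):
            build_stratified_subsets(matrix, seed=0)


class TestSelectTopFeatures:
    def _labeled(self, n_rows, n_features, seed=0, informative=None):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n_rows, n_features))
        labels = rng.choice(["C1", "C2"], size=n_rows)
        if informative is not None:
            values[:, informative] += 3.0 * (labels == "C1")
        return _matrix(values, labels=labels)

    def test_540_features_at_quarter_cutoff_gives_135(self):
        sig = select_top_features(self._labeled(60, 540), fraction=0.25, forest_size=15, seed=1)
        assert len(sig) == 135

    def test_fraction_one_keeps_everything(self):
        sig = select_top_features(self._labeled(40, 12), fraction=1.0, forest_size=15, seed=1)
        assert len(sig) == 12

    def test_informative_feature_outranks_noise(self):
        matrix = self._labeled(200, 2, seed=3, informative=0)
        sig = select_top_features(matrix, fraction=0.5, forest_size=50, seed=2)
        scores = sig.scores.set_index("center")["importance"]
        # independent oracle: single-feature stump accuracy
        labels = matrix.labels("subtype").to_numpy()
        accs = []
        for j in range(2):
            thr = np.median(matrix.values[:, j])
            pred = np.where(matrix.values[:, j] > thr, "C1", "C2")
            accs.append(max((pred == labels).mean(), 1 - (pred == labels).mean()))
        assert accs[0] > accs[1]
        assert scores.iloc[0] > scores.iloc[1]
        assert sig.centers[0] == matrix.axis.centers[0]

    def test_selected_centers_subset_of_axis(self):
        matrix = self._labeled(50, 20, seed=4)
        sig = select_top_features(matrix, fraction=0.3, forest_size=15, seed=5)
        assert set(sig.centers) <= set(matrix.axis.centers)
        assert len(sig) == int(0.3 * 20)

    def test_deterministic_given_seed(self):
        matrix = self._labeled(60, 30, seed=6)
        a = select_top_features(matrix, fraction=0.2, forest_size=20, seed=7)
        b = select_top_features(matrix, fraction=0.2, forest_size=20, seed=7)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_single_class_labels_rejected(self):
        matrix = _matrix(np.zeros((10, 4)), labels=["C1"] * 10)
        with pytest.raises(DegenerateLabelError):
            select_top_features(matrix, forest_size=10, seed=0)
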
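"""Subtype random-forest ensemble: tuning, training, prediction, evaluation.

The classifier follows the triplicate design: three class-balanced
stratified subsets, each feature-selected on its own training rows, one
forest per subset trained with one shared set of tuned hyperparameters, and
evaluation of each member on its own held-out test rows. Multiclass ROC is
the one-vs-one (Hand-and-Till) mean AUC; the other headline metrics are
balanced accuracy (mean per-class recall) and the macro-averaged false
discovery rate (1 - precision per predicted class).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .containers import SUBTYPES, FeatureMatrix, PeakAxis
from .ensemble import EnsembleMember, ModelEnsemble
from .exceptions import (
    DegenerateLabelError,
    EmptyInputError,
    FoldConstructionError,
    MetadataJoinError,
    ParameterError,
)
from .feature_engineering import (
    FeatureSignature,
    StratifiedSubset,
    scale_features,
    select_top_features,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "EvaluationReport",
    "tune_hyperparameters",
    "train_subtype_ensemble",
    "predict_spectra",
    "PredictionTable",
    "aggregate_core_predictions",
    "auc_one_vs_one",
    "balanced_accuracy",
    "false_discovery_rate",
    "confusion_matrix",
    "evaluate_ensemble",
]


@dataclass(frozen=True)
class HyperParams:
    """Random-forest hyperparameters; tree count is fixed, not tuned."""

    trees: int = 500
    features_per_split: float = 0.25
    min_node_size: int = 1

    def __post_init__(self):
        if self.trees < 1 or self.min_node_size < 1:
            raise ParameterError("trees and min_node_size must be positive")
        if not 0 < self.features_per_split <= 1:
            raise ParameterError("features_per_split must be in (0, 1]")

    def make_forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.trees,
            max_features=self.features_per_split,
            min_samples_leaf=self.min_node_size,
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )


def _class_order(classes: Sequence[str]) -> list[str]:
    """Canonical tie-break order: C1 < C2 < C4 < C5 (lexicographic otherwise)."""
    return sorted(classes)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion_matrix(
    labels: Sequence[str], predicted: Sequence[str], classes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Confusion matrix with true classes as rows, predictions as columns."""
    labels = pd.Series(list(labels))
    predicted = pd.Series(list(predicted))
    if classes is None:
        classes = _class_order(set(labels) | set(predicted))
    classes = list(classes)
    cm = pd.crosstab(labels, predicted, dropna=False)
    return cm.reindex(index=classes, columns=classes, fill_value=0)


def balanced_accuracy(cm) -> float:
    """Mean per-class recall (diagonal over row sum).

    Classes with zero true samples are excluded with a warning.
    """
    m = np.asarray(cm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError("confusion matrix must be square")
    row_sums = m.sum(axis=1)
    if m.sum() == 0:
        raise EmptyInputError("confusion matrix is all zero")
    present = row_sums > 0
    if not present.all():
        warnings.warn("classes with zero true samples excluded from balanced accuracy")
    recall = np.diag(m)[present] / row_sums[present]
    return float(recall.mean())


def false_discovery_rate(cm) -> tuple[pd.Series, float]:
    """Per predicted class, the fraction of its predictions that are wrong.

    Returns (per-class FDR, macro mean over classes with >= 1 prediction);
    never-predicted classes are excluded from the macro mean with a warning.
    """
    if isinstance(cm, pd.DataFrame):
        names = list(cm.columns)
        m = cm.to_numpy(dtype=float)
    else:
        m = np.asarray(cm, dtype=float)
        names = [f"class_{i}" for i in range(m.shape[1])]
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError("confusion matrix must be square")
    col_sums = m.sum(axis=0)
    predicted = col_sums > 0
    fdr = np.full(m.shape[1], np.nan)
    fdr[predicted] = (col_sums[predicted] - np.diag(m)[predicted]) / col_sums[predicted]
    if not predicted.all():
        warnings.warn("never-predicted classes excluded from macro FDR")
    per_class = pd.Series(fdr, index=names, name="fdr")
    return per_class, float(np.nanmean(fdr))


def _binary_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based probability that a positive outscores a negative (tie = 1/2)."""
    n_pos, n_neg = pos_scores.size, neg_scores.size
    ranks = rankdata(np.concatenate([pos_scores, neg_scores]))
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_one_vs_one(scores: pd.DataFrame, labels: Sequence[str]) -> tuple[pd.DataFrame, float]:
    """One-vs-one multiclass AUC (Hand-and-Till M measure).

    For each unordered class pair (i, j), restricted to samples of those two
    classes, A(i|j) is the probability that a random i-sample has the higher
    class-i score, and A(j|i) analogously on class-j scores; the pair value
    is their mean and the overall value is the mean over pairs. Pairs where
    a class has no samples are skipped with a warning.
    """
    labels = np.asarray(list(labels))
    present = [c for c in _class_order(set(labels)) if c in scores.columns]
    if len(present) < 2:
        raise DegenerateLabelError("one-vs-one AUC needs >= 2 classes with samples")
    rows = []
    for ci, cj in itertools.combinations(present, 2):
        mask_i, mask_j = labels == ci, labels == cj
        if mask_i.sum() == 0 or mask_j.sum() == 0:
            warnings.warn(f"pair ({ci}, {cj}) skipped: a class has no samples")
            continue
        a_ij = _binary_auc(scores.loc[mask_i, ci].to_numpy(), scores.loc[mask_j, ci].to_numpy())
        a_ji = _binary_auc(scores.loc[mask_j, cj].to_numpy(), scores.loc[mask_i, cj].to_numpy())
        rows.append((ci, cj, a_ij, a_ji, (a_ij + a_ji) / 2))
    table = pd.DataFrame(rows, columns=["class_a", "class_b", "auc_a_given_b", "auc_b_given_a", "auc"])
    if table.empty:
        raise DegenerateLabelError("no computable class pairs")
    return table, float(table["auc"].mean())


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

_MIN_NODE_GRID_AT_4 = (1, 5, 10, 20)


def _grids(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    fps = np.geomspace(0.05, 0.8, resolution)
    if resolution == 4:
        mns = np.array(_MIN_NODE_GRID_AT_4)
    else:
        mns = np.unique(np.rint(np.geomspace(1, 20, resolution)).astype(int))
    return fps, mns


def tune_hyperparameters(
    train: FeatureMatrix,
    grid_resolution: int = 4,
    cv_folds: int = 3,
    seed: int = 0,
    trees: int = 500,
    label_column: str = "subtype",
    max_rows: Optional[int] = None,
) -> HyperParams:
    """Grid-search forest hyperparameters by stratified cross-validation.

    Two dimensions are tuned at ``grid_resolution`` values each: the fraction
    of features considered per split (log-spaced over [0.05, 0.8]) and the
    minimum node size ({1, 5, 10, 20} at the default resolution). The
    objective is mean balanced accuracy over stratified folds; ties prefer
    the smaller features-per-split, then the smaller node size. ``max_rows``
    caps the tuning set by seeded stratified subsampling (grid search cost
    control; the final fit always uses all training rows).
    """
    x_all = train.values
    y = train.labels(label_column).to_numpy()
    if max_rows is not None and len(y) > max_rows:
        rng = np.random.default_rng(seed)
        frac = max_rows / len(y)
        take = []
        for cls in np.unique(y):
            rows = np.flatnonzero(y == cls)
            take.append(rng.choice(rows, size=max(cv_folds, int(round(frac * rows.size))),
                                   replace=False))
        take = np.sort(np.concatenate(take))
        x_all, y = x_all[take], y[take]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateLabelError("tuning needs >= 2 classes")
    if counts.min() < cv_folds:
        raise FoldConstructionError(
            f"smallest class has {counts.min()} samples, fewer than {cv_folds} folds"
        )
    fps_grid, mns_grid = _grids(grid_resolution)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2**31))
    folds = list(skf.split(x_all, y))

    results = []
    for fps in fps_grid:
        for mns in mns_grid:
            params = HyperParams(trees=trees, features_per_split=float(fps), min_node_size=int(mns))
            accs = []
            for f, (tr, te) in enumerate(folds):
                forest = params.make_forest(seed + 7919 * f)
                forest.fit(x_all[tr], y[tr])
                cm = confusion_matrix(y[te], forest.predict(x_all[te]), classes=list(classes))
                accs.append(balanced_accuracy(cm))
            results.append((float(np.mean(accs)), float(fps), int(mns)))
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    best = results[0]
    logger.info("tuned hyperparameters: balanced accuracy %.4f at fps=%.3f, min_node=%d", *best)
    return HyperParams(trees=trees, features_per_split=best[1], min_node_size=best[2])


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def fit_member(
    matrix: FeatureMatrix,
    subset: StratifiedSubset,
    params: HyperParams,
    signature: Optional[FeatureSignature] = None,
    selection_fraction: float = 0.25,
    selection_forest_size: int = 500,
    label_column: str = "subtype",
) -> EnsembleMember:
    """Fit one member on a subset's training rows only.

    Scaling statistics and (when not supplied) the feature signature are
    computed from the training rows alone; test rows are never touched.
    """
    train_m = matrix.take_rows(subset.train_rows)
    scaled_train, stats = scale_features(train_m)
    if signature is None:
        signature = select_top_features(
            scaled_train,
            fraction=selection_fraction,
            forest_size=selection_forest_size,
            seed=subset.seed,
            label_column=label_column,
        )
    idx = signature.indices_in(matrix.axis)
    forest = params.make_forest(subset.seed)
    forest.fit(scaled_train.values[:, idx], scaled_train.labels(label_column).to_numpy())
    return EnsembleMember(
        model=forest, signature=signature, scaler_stats=stats, subset=subset, seed=subset.seed
    )


def train_subtype_ensemble(
    matrix: FeatureMatrix,
    subsets: Sequence[StratifiedSubset],
    params: HyperParams,
    signatures: Optional[Sequence[FeatureSignature]] = None,
    selection_fraction: float = 0.25,
    selection_forest_size: int = 500,
    label_column: str = "subtype",
    task: str = "subtype",
) -> ModelEnsemble:
    """Train the triplicate ensemble: one member per stratified subset."""
    if len(subsets) != 3:
        raise ParameterError("the ensemble design uses exactly three subsets")
    if signatures is not None and len(signatures) != 3:
        raise ParameterError("provide one signature per subset")
    members = [
        fit_member(
            matrix,
            subset,
            params,
            signature=None if signatures is None else signatures[i],
            selection_fraction=selection_fraction,
            selection_forest_size=selection_forest_size,
            label_column=label_column,
        )
        for i, subset in enumerate(subsets)
    ]
    classes = tuple(_class_order(set(matrix.labels(label_column))))
    ensemble = ModelEnsemble(members=members, axis=matrix.axis, task=task, classes=classes)
    for member in ensemble.members:
        test_m = matrix.take_rows(member.subset.test_rows)
        proba = member.predict_proba(test_m, matrix.axis)
        y_true = test_m.labels(label_column).to_numpy()
        cm = confusion_matrix(y_true, proba.columns[np.argmax(proba.to_numpy(), axis=1)],
                              classes=list(classes))
        _, mean_auc = auc_one_vs_one(proba, y_true)
        member.held_out_metrics = {
            "balanced_accuracy": balanced_accuracy(cm),
            "mean_ovo_auc": mean_auc,
            "n_test": int(len(test_m.meta)),
        }
    return ensemble


@dataclass
class PredictionTable:
    """Per-member class-probability simplices plus their member mean."""

    mean: pd.DataFrame
    members: list[pd.DataFrame]


def predict_spectra(ensemble: ModelEnsemble, matrix: FeatureMatrix) -> PredictionTable:
    """Predict per-spectrum class probabilities with every member.

    The matrix must be aligned to the ensemble's reference axis; each member
    applies its own training scaler internally. An empty matrix yields an
    empty table.
    """
    cols = _class_order(ensemble.classes)
    if matrix.n_rows == 0:
        empty = pd.DataFrame(columns=cols)
        return PredictionTable(mean=empty, members=[empty.copy() for _ in ensemble.members])
    member_tables = [
        m.predict_proba(matrix, ensemble.axis).reindex(columns=cols, fill_value=0.0)
        for m in ensemble.members
    ]
    mean = sum(t.to_numpy() for t in member_tables) / len(member_tables)
    return PredictionTable(mean=pd.DataFrame(mean, columns=cols), members=member_tables)


def aggregate_core_predictions(
    predictions: pd.DataFrame, core_ids: Sequence[str]
) -> pd.DataFrame:
    """Roll spectrum-level probabilities up to cores.

    Core label is the argmax of the mean simplex over the core's spectra;
    ties resolve to the first class in canonical order.
    """
    core_ids = pd.Series(list(core_ids), name="core_id")
    if core_ids.isna().any() or len(core_ids) != len(predictions):
        raise MetadataJoinError("every spectrum must map to a core")
    cols = _class_order(predictions.columns)
    probs = predictions[cols].copy()
    probs["core_id"] = core_ids.to_numpy()
    agg = probs.groupby("core_id")[cols].mean()
    agg["label"] = [cols[i] for i in np.argmax(agg[cols].to_numpy(), axis=1)]
    return agg


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Headline metrics of a trained ensemble on its held-out test rows."""

    pair_auc: pd.DataFrame  # per member x class pair
    mean_ovo_auc: float
    balanced_accuracy_mean: float
    balanced_accuracy_sd: float
    fdr_per_class: pd.DataFrame  # per member x predicted class
    fdr_macro_mean: float
    confusions: list[pd.DataFrame]
    per_member: pd.DataFrame  # replicate_id, mean_ovo_auc, balanced_accuracy, fdr_macro, n_test

    def to_dict(self) -> dict:
        return {
            "mean_ovo_auc": self.mean_ovo_auc,
            "balanced_accuracy_mean": self.balanced_accuracy_mean,
            "balanced_accuracy_sd": self.balanced_accuracy_sd,
            "fdr_macro_mean": self.fdr_macro_mean,
            "per_member": self.per_member.to_dict("records"),
            "pair_auc": self.pair_auc.to_dict("records"),
            "confusions": [cm.to_dict() for cm in self.confusions],
        }


def evaluate_ensemble(
    ensemble: ModelEnsemble, matrix: FeatureMatrix, label_column: str = "subtype"
) -> EvaluationReport:
    """Evaluate each member on its own subset's test rows and aggregate."""
    classes = list(_class_order(ensemble.classes))
    pair_rows, fdr_rows, member_rows, confusions = [], [], [], []
    for member in ensemble.members:
        test_m = matrix.take_rows(member.subset.test_rows)
        proba = member.predict_proba(test_m, ensemble.axis).reindex(columns=classes, fill_value=0.0)
        y_true = test_m.labels(label_column).to_numpy()
        y_pred = np.asarray(classes)[np.argmax(proba.to_numpy(), axis=1)]
        pair_table, mean_auc = auc_one_vs_one(proba, y_true)
        cm = confusion_matrix(y_true, y_pred, classes=classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fdr_class, fdr_macro = false_discovery_rate(cm)
        bal = balanced_accuracy(cm)
        rep = member.subset.replicate_id
        pair_rows.append(pair_table.assign(replicate_id=rep))
        fdr_rows.append(fdr_class.rename(rep))
        confusions.append(cm)
        member_rows.append(
            {
                "replicate_id": rep,
                "mean_ovo_auc": mean_auc,
                "balanced_accuracy": bal,
                "fdr_macro": fdr_macro,
                "n_test": int(len(y_true)),
            }
        )
    per_member = pd.DataFrame(member_rows)
    return EvaluationReport(
        pair_auc=pd.concat(pair_rows, ignore_index=True),
        mean_ovo_auc=float(per_member["mean_ovo_auc"].mean()),
        balanced_accuracy_mean=float(per_member["balanced_accuracy"].mean()),
        balanced_accuracy_sd=float(per_member["balanced_accuracy"].std(ddof=1)),
        fdr_per_class=pd.DataFrame(fdr_rows),
        fdr_macro_mean=float(per_member["fdr_macro"].mean()),
        confusions=confusions,
        per_member=per_member,
    )
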
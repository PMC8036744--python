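"""Consensus exclusion of stroma-origin spectra.

Three stroma-vs-malignant forests are trained on a compartment-labeled
dataset (after feature-parity alignment to the reference axis). A spectrum
of the subtype-labeled dataset is excluded only when all three members
independently classify it as stromal — a deliberately conservative rule that
removes the intersection, never the union, of the members' stroma calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .ensemble import EnsembleMember, ModelEnsemble
from .exceptions import DegenerateLabelError, ParameterError
from .feature_engineering import build_stratified_subsets
from .subtype_model import HyperParams, fit_member, auc_one_vs_one, confusion_matrix, balanced_accuracy

logger = logging.getLogger(__name__)

__all__ = ["ConsensusDecision", "train_stroma_ensemble", "consensus_exclude"]

STROMA_LABEL = "stroma"


@dataclass
class ConsensusDecision:
    """Votes of the three members for one spectrum and the resulting flag."""

    votes: tuple[str, str, str]
    excluded: bool


def train_stroma_ensemble(
    stroma_matrix: FeatureMatrix,
    params: Optional[HyperParams] = None,
    seed: int = 0,
    selection_fraction: float = 0.25,
    selection_forest_size: int = 500,
    trees: int = 500,
    split_unit: str = "core",
    shared_signature: bool = False,
) -> ModelEnsemble:
    """Train three compartment classifiers on balanced, feature-selected subsets.

    Each member gets its own stratified subset (binary stratification on the
    compartment label), its own training-row scaling statistics and — unless
    ``shared_signature`` — its own Gini-selected signature. Held-out binary
    AUC and balanced accuracy are logged per member.
    """
    labels = stroma_matrix.labels("compartment")
    if labels.nunique() < 2:
        raise DegenerateLabelError("stroma training needs both compartments present")
    if params is None:
        params = HyperParams(trees=trees)
    subsets = build_stratified_subsets(
        stroma_matrix,
        n_replicates=3,
        seed=seed,
        label_column="compartment",
        split_unit=split_unit,
    )
    signatures = None
    if shared_signature:
        from .feature_engineering import scale_features, select_top_features

        scaled, _ = scale_features(stroma_matrix.take_rows(subsets[0].train_rows))
        sig = select_top_features(
            scaled, fraction=selection_fraction, forest_size=selection_forest_size,
            seed=subsets[0].seed, label_column="compartment",
        )
        signatures = [sig, sig, sig]

    members = []
    for i, subset in enumerate(subsets):
        member = fit_member(
            stroma_matrix,
            subset,
            params,
            signature=None if signatures is None else signatures[i],
            selection_fraction=selection_fraction,
            selection_forest_size=selection_forest_size,
            label_column="compartment",
        )
        test_m = stroma_matrix.take_rows(subset.test_rows)
        proba = member.predict_proba(test_m, stroma_matrix.axis)
        y_true = test_m.labels("compartment").to_numpy()
        _, mean_auc = auc_one_vs_one(proba, y_true)
        cm = confusion_matrix(y_true, member.predict(test_m, stroma_matrix.axis))
        member.held_out_metrics = {
            "binary_auc": mean_auc,
            "balanced_accuracy": balanced_accuracy(cm),
            "n_test": int(len(y_true)),
        }
        logger.info("stroma member %d held-out AUC %.4f", i + 1, mean_auc)
        members.append(member)
    classes = tuple(sorted(labels.unique()))
    return ModelEnsemble(members=members, axis=stroma_matrix.axis, task="compartment", classes=classes)


def consensus_exclude(
    ensemble: ModelEnsemble, matrix: FeatureMatrix
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Remove rows unanimously voted stromal; return the decision log.

    The decision log has one row per input spectrum with the three member
    votes and the exclusion flag; removal counts are logged per core.
    """
    if ensemble.task != "compartment":
        raise ParameterError("consensus exclusion requires a compartment ensemble")
    votes = np.stack(
        [member.predict(matrix, ensemble.axis) for member in ensemble.members], axis=1
    )
    excluded = np.all(votes == STROMA_LABEL, axis=1)
    log = pd.DataFrame(
        {
            "core_id": matrix.meta["core_id"].to_numpy(),
            "vote_1": votes[:, 0],
            "vote_2": votes[:, 1],
            "vote_3": votes[:, 2],
            "excluded": excluded,
        }
    )
    removed_per_core = log[log["excluded"]].groupby("core_id").size()
    logger.info(
        "consensus exclusion removed %d of %d spectra (%d cores affected)",
        int(excluded.sum()), len(log), len(removed_per_core),
    )
    return matrix.take_rows(np.flatnonzero(~excluded)), log
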
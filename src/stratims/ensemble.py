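"""Shared ensemble container: three forests with per-member provenance.

Both the compartment (stroma vs malignant) filter and the subtype classifier
use the same structure: exactly three independently trained random forests,
each carrying its own stratified subset, scaling statistics and selected
feature signature, all referring to one shared reference feature axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import FeatureMatrix, PeakAxis
from .exceptions import FeatureParityError
from .feature_engineering import FeatureSignature, StratifiedSubset, scale_features

__all__ = ["EnsembleMember", "ModelEnsemble"]


@dataclass
class EnsembleMember:
    """One trained forest with everything needed to apply it to new spectra."""

    model: RandomForestClassifier
    signature: FeatureSignature
    scaler_stats: pd.DataFrame
    subset: StratifiedSubset
    seed: int
    held_out_metrics: dict = field(default_factory=dict)

    def _prepare(self, matrix: FeatureMatrix, axis: PeakAxis) -> np.ndarray:
        if len(matrix.axis) != len(axis) or not np.allclose(matrix.axis.centers, axis.centers):
            raise FeatureParityError(
                "matrix feature axis does not match the ensemble axis; "
                "run align_to_reference_axis first"
            )
        scaled, _ = scale_features(matrix, stats=self.scaler_stats)
        idx = self.signature.indices_in(axis)
        return scaled.values[:, idx]

    def predict_proba(self, matrix: FeatureMatrix, axis: PeakAxis) -> pd.DataFrame:
        x = self._prepare(matrix, axis)
        proba = self.model.predict_proba(x)
        return pd.DataFrame(proba, columns=list(self.model.classes_))

    def predict(self, matrix: FeatureMatrix, axis: PeakAxis) -> np.ndarray:
        x = self._prepare(matrix, axis)
        return self.model.predict(x)


@dataclass
class ModelEnsemble:
    """Exactly three members sharing a task and a reference feature axis."""

    members: list[EnsembleMember]
    axis: PeakAxis
    task: str  # "compartment" or "subtype"
    classes: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) != 3:
            raise ValueError("an ensemble has exactly three members")
        if self.task not in ("compartment", "subtype"):
            raise ValueError("task must be 'compartment' or 'subtype'")
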
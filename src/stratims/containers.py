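"""Core in-memory containers shared by all pipeline stages.

A :class:`SpatialIMSDataset` holds one continuous-mode imaging run: a single
shared m/z axis plus one intensity row per pixel, with pixel/core/patient
metadata in a tidy :class:`pandas.DataFrame`. Downstream stages reduce it to a
:class:`FeatureMatrix` over a discrete :class:`PeakAxis` of aligned peak
centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, MetadataJoinError

#: Canonical molecular subtype order; all tie-breaks use this order.
SUBTYPES = ("C1", "C2", "C4", "C5")

#: Tissue compartment labels.
COMPARTMENTS = ("malignant", "stroma")


def cohort_percentages(counts: dict) -> dict:
    """Per-class percentages of a labeled cohort, rounded to one decimal.

    E.g. subtype counts of a ground-truth labeling {C1: 105, C2: 77, C4: 44,
    C5: 53} over 279 patients give {C1: 37.6, C2: 27.6, C4: 15.8, C5: 19.0}.
    """
    total = sum(counts.values())
    if total <= 0:
        raise EmptyInputError("cohort is empty")
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


@dataclass
class Spectrum:
    """A single per-pixel mass spectrum."""

    mz: np.ndarray
    intensity: np.ndarray
    pixel: tuple[int, int] = (0, 0)
    core_id: str = ""
    patient_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.shape != self.mz.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class SpatialIMSDataset:
    """Continuous-mode imaging dataset: shared m/z axis, one row per pixel.

    ``pixels`` carries columns ``x, y, core_id, patient_id`` and optionally
    ``subtype`` and ``compartment``; its row order matches ``intensities``.
    """

    mz: np.ndarray
    intensities: np.ndarray
    pixels: pd.DataFrame
    compartment_labeled: bool = False
    native_axis: Optional["PeakAxis"] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.mz.size:
            raise ValueError("intensities must be (n_spectra, len(mz))")
        if len(self.pixels) != self.intensities.shape[0]:
            raise ValueError("pixel table length must match spectrum count")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        row = self.pixels.iloc[i]
        return Spectrum(
            mz=self.mz,
            intensity=np.asarray(self.intensities[i], dtype=float),
            pixel=(int(row["x"]), int(row["y"])),
            core_id=str(row["core_id"]),
            patient_id=str(row["patient_id"]),
        )

    def select(self, mask: np.ndarray) -> "SpatialIMSDataset":
        mask = np.asarray(mask)
        return SpatialIMSDataset(
            mz=self.mz,
            intensities=self.intensities[mask],
            pixels=self.pixels.loc[mask].reset_index(drop=True),
            compartment_labeled=self.compartment_labeled,
            native_axis=self.native_axis,
        )


@dataclass
class PeakAxis:
    """Sorted, unique m/z feature centers with an assignment half-width."""

    centers: np.ndarray
    tolerance: float = 0.25
    occurrence: Optional[np.ndarray] = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 1:
            raise ValueError("centers must be 1-D")
        if self.centers.size and np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly ascending and unique")

    def __len__(self) -> int:
        return self.centers.size

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"center": self.centers})
        if self.occurrence is not None:
            out["occurrence_rate"] = self.occurrence
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tolerance: float = 0.25) -> "PeakAxis":
        occ = frame["occurrence_rate"].to_numpy() if "occurrence_rate" in frame else None
        return cls(frame["center"].to_numpy(dtype=float), tolerance=tolerance, occurrence=occ)


@dataclass
class FeatureMatrix:
    """Spectra x aligned-m/z intensity table with row metadata.

    ``meta`` columns: ``x, y, core_id, patient_id`` plus optional ``subtype``
    and ``compartment`` labels. Absent peaks are 0, never missing.
    """

    values: np.ndarray
    axis: PeakAxis
    meta: pd.DataFrame

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.axis):
            raise ValueError("column count must equal axis length")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta length must match row count")
        if "core_id" not in self.meta.columns or self.meta["core_id"].isna().any():
            raise MetadataJoinError("every spectrum requires a core_id")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels(self, column: str) -> pd.Series:
        if column not in self.meta.columns:
            raise MetadataJoinError(f"label column {column!r} missing from metadata")
        return self.meta[column]

    def take_rows(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            values=self.values[rows],
            axis=self.axis,
            meta=self.meta.iloc[rows].reset_index(drop=True),
        )

    def take_features(self, feature_idx: Sequence[int]) -> "FeatureMatrix":
        feature_idx = np.asarray(feature_idx)
        return FeatureMatrix(
            values=self.values[:, feature_idx],
            axis=PeakAxis(self.axis.centers[feature_idx], tolerance=self.axis.tolerance),
            meta=self.meta,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"mz_{c:.4f}" for c in self.axis.centers]
        vals = pd.DataFrame(self.values, columns=cols)
        return pd.concat([self.meta.reset_index(drop=True), vals], axis=1)


@dataclass
class GroundTruth:
    """What the synthetic generator planted: labels and marker channels.

    ``markers`` has columns ``mz, kind, target, effect, symbol`` where ``kind``
    is one of ``subtype`` (fold-change in one subtype's malignant pixels),
    ``stroma_up`` (elevated in stroma) or ``malignant_only`` (suppressed to
    near zero in stroma).
    """

    core_subtypes: pd.Series
    pixel_compartments: pd.Series
    markers: pd.DataFrame

    def marker_centers(self, kind: Optional[str] = None) -> np.ndarray:
        m = self.markers if kind is None else self.markers[self.markers["kind"] == kind]
        return m["mz"].to_numpy(dtype=float)
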
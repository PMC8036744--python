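"""Spectral preprocessing: baseline removal, TIC normalization, peak picking.

Follows the fixed order used throughout the package: convolution baseline
removal (moving-average lower envelope, default window 20 points) first, then
total-ion-count normalization, then peak picking across the whole dataset to
derive the aligned feature axis, and finally feature-matrix extraction.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .containers import FeatureMatrix, PeakAxis, SpatialIMSDataset, Spectrum
from .exceptions import (
    DegenerateSpectrumError,
    EmptyInputError,
    MetadataJoinError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "remove_baseline",
    "tic_normalize",
    "preprocess_dataset",
    "pick_peaks",
    "build_feature_matrix",
]

_ENVELOPE_ITERATIONS = 4


def _baseline_2d(arr: np.ndarray, width: int) -> np.ndarray:
    """Moving-average-smoothed lower envelope of each row.

    Iterative minimum suppression: repeatedly replace each row by the
    pointwise minimum of itself and its moving average, which erodes peaks
    out of the envelope while tracking the smooth baseline, then smooth once
    more. Exact for a flat baseline; preserves narrow peak apexes because
    they never pull the envelope up.
    """
    env = np.array(arr, dtype=np.float64, copy=True)
    for _ in range(_ENVELOPE_ITERATIONS):
        sm = uniform_filter1d(env, size=width, axis=-1, mode="nearest")
        np.minimum(env, sm, out=env)
    return uniform_filter1d(env, size=width, axis=-1, mode="nearest")


def remove_baseline(spectrum: Spectrum, width: int = 20) -> Spectrum:
    """Subtract the convolution-baseline estimate; clamp the result at 0."""
    if width < 1:
        raise ParameterError("width must be >= 1")
    if spectrum.intensity.size == 0:
        raise EmptyInputError("spectrum is empty")
    if width > spectrum.intensity.size:
        raise ParameterError("baseline width exceeds spectrum length")
    baseline = _baseline_2d(spectrum.intensity[None, :], width)[0]
    corrected = np.clip(spectrum.intensity - baseline, 0.0, None)
    return Spectrum(spectrum.mz, corrected, spectrum.pixel, spectrum.core_id, spectrum.patient_id)


def tic_normalize(spectrum: Spectrum, target_sum: float = 1.0) -> Spectrum:
    """Scale intensities so they sum to ``target_sum``; m/z unchanged."""
    if target_sum <= 0:
        raise ParameterError("target_sum must be positive")
    total = spectrum.intensity.sum()
    if total <= 0:
        raise DegenerateSpectrumError(
            f"all-zero spectrum at pixel {spectrum.pixel} (core {spectrum.core_id})",
            pixel=spectrum.pixel,
        )
    scaled = spectrum.intensity * (target_sum / total)
    return Spectrum(spectrum.mz, scaled, spectrum.pixel, spectrum.core_id, spectrum.patient_id)


def preprocess_dataset(
    dataset: SpatialIMSDataset, width: int = 20, target_sum: float = 1.0
) -> SpatialIMSDataset:
    """Baseline-remove then TIC-normalize every spectrum of a dataset.

    All-zero spectra (after baseline removal) are dropped with a logged
    warning rather than aborting the batch.
    """
    if dataset.n_spectra == 0:
        raise EmptyInputError("dataset has no spectra")
    if width > dataset.mz.size:
        raise ParameterError("baseline width exceeds spectrum length")
    x = dataset.intensities.astype(np.float64, copy=True)
    x -= _baseline_2d(x, width)
    np.clip(x, 0.0, None, out=x)
    totals = x.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        bad = dataset.pixels.loc[~keep, ["x", "y", "core_id"]]
        logger.warning("dropping %d all-zero spectra: %s", n_dropped, bad.to_dict("records"))
        x, totals = x[keep], totals[keep]
    x *= (target_sum / totals)[:, None]
    return SpatialIMSDataset(
        mz=dataset.mz,
        intensities=x.astype(np.float32),
        pixels=dataset.pixels.loc[keep].reset_index(drop=True),
        compartment_labeled=dataset.compartment_labeled,
        native_axis=dataset.native_axis,
    )


def pick_peaks(
    dataset: SpatialIMSDataset,
    snr_threshold: float = 6.0,
    bin_tolerance: float = 0.25,
    min_occurrence: float = 0.01,
) -> PeakAxis:
    """Derive the aligned peak axis from a preprocessed dataset.

    Per spectrum, local maxima exceeding ``snr_threshold`` times the
    MAD-based noise estimate are centroided (3-point intensity-weighted mean
    m/z); candidates pooled over all spectra are single-linkage clustered
    with a gap threshold of ``bin_tolerance``, and clusters present in at
    least ``min_occurrence`` of spectra become axis centers
    (intensity-weighted mean of their members).
    """
    if dataset.n_spectra == 0:
        raise EmptyInputError("dataset has no spectra")
    x = dataset.intensities
    n_spec, npts = x.shape
    if npts < 3:
        raise ParameterError("spectra too short for peak detection")

    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1)
    noise = np.maximum(mad * 1.4826, np.finfo(np.float32).tiny)

    core = x[:, 1:-1]
    is_max = (core > x[:, :-2]) & (core >= x[:, 2:]) & (core > snr_threshold * noise[:, None])
    spec_idx, j = np.nonzero(is_max)
    j = j + 1
    if j.size == 0:
        return PeakAxis(np.empty(0), tolerance=bin_tolerance, occurrence=np.empty(0))

    w_left, w_mid, w_right = x[spec_idx, j - 1], x[spec_idx, j], x[spec_idx, j + 1]
    wsum = w_left + w_mid + w_right
    mz = dataset.mz
    centroid = (w_left * mz[j - 1] + w_mid * mz[j] + w_right * mz[j + 1]) / wsum

    order = np.argsort(centroid, kind="stable")
    centroid, height, spec_idx = centroid[order], w_mid[order].astype(np.float64), spec_idx[order]

    gap = np.diff(centroid) > bin_tolerance
    cluster = np.concatenate([[0], np.cumsum(gap)])
    n_clusters = cluster[-1] + 1

    weight_sum = np.bincount(cluster, weights=height, minlength=n_clusters)
    center = np.bincount(cluster, weights=height * centroid, minlength=n_clusters) / weight_sum

    # occurrence = fraction of distinct spectra contributing to the cluster
    pair = cluster.astype(np.int64) * n_spec + spec_idx
    uniq_pair = np.unique(pair)
    occ_counts = np.bincount((uniq_pair // n_spec).astype(np.int64), minlength=n_clusters)
    occurrence = occ_counts / n_spec

    keep = occurrence >= min_occurrence
    centers, occurrence = center[keep], occurrence[keep]
    order = np.argsort(centers, kind="stable")
    return PeakAxis(centers[order], tolerance=bin_tolerance, occurrence=occurrence[order])


def build_feature_matrix(dataset: SpatialIMSDataset, axis: PeakAxis) -> FeatureMatrix:
    """Extract the spectra x features table: max intensity within tolerance.

    Each cell is the maximum intensity of the spectrum within +/- the axis
    tolerance of the center, 0 when no signal falls in the window.
    """
    if len(axis) == 0:
        raise EmptyInputError("peak axis is empty")
    if "core_id" not in dataset.pixels.columns or dataset.pixels["core_id"].isna().any():
        raise MetadataJoinError("dataset pixels lack core_id metadata")
    mz = dataset.mz
    lo = np.searchsorted(mz, axis.centers - axis.tolerance, side="left")
    hi = np.searchsorted(mz, axis.centers + axis.tolerance, side="right")
    w = int(max(1, (hi - lo).max()))
    idx = lo[:, None] + np.arange(w)[None, :]
    valid = idx < hi[:, None]
    np.clip(idx, 0, mz.size - 1, out=idx)

    x = dataset.intensities
    vals = np.where(valid[None, :, :], x[:, idx], 0.0).max(axis=2)
    vals[:, (hi - lo) == 0] = 0.0
    return FeatureMatrix(values=vals.astype(np.float64), axis=axis,
                         meta=dataset.pixels.reset_index(drop=True).copy())
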
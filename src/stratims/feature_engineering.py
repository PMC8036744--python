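"""Feature parity, scaling, stratified subset construction, Gini selection.

These are the dataset-preparation steps between preprocessing and model
training: map one dataset's peak axis onto another's within a mass tolerance
(so a model trained on one applies to the other), standardize features with
train-only statistics, build class-balanced train/test subsets by iterative
core sampling, and select the top fraction of features by random-forest Gini
importance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import FeatureMatrix, PeakAxis
from .exceptions import (
    DegenerateLabelError,
    EmptyInputError,
    ParameterError,
    StratificationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AxisMapping",
    "StratifiedSubset",
    "FeatureSignature",
    "align_to_reference_axis",
    "scale_features",
    "build_stratified_subsets",
    "select_top_features",
]


@dataclass
class AxisMapping:
    """Injective nearest-pair mapping between two peak axes."""

    pairs: pd.DataFrame  # columns: source, reference, abs_diff
    unmatched_reference: np.ndarray
    unmatched_source: np.ndarray
    max_diff: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def align_to_reference_axis(
    source: PeakAxis, reference: PeakAxis, max_diff: float = 0.25
) -> AxisMapping:
    """Greedy nearest-pair matching of source centers onto reference centers.

    Candidate pairs closer than ``max_diff`` are taken in ascending
    absolute-difference order; every source and reference center is used at
    most once, making the mapping injective in both directions.
    """
    if len(reference) == 0:
        raise ParameterError("reference axis is empty")
    if max_diff <= 0:
        raise ParameterError("max_diff must be positive")
    src, ref = source.centers, reference.centers

    # Candidate pairs: for each source center, the reference neighbours that
    # could lie within max_diff (insertion point and its left neighbour are
    # the only nearest candidates, but keep a +/-1 window for safety).
    pos = np.searchsorted(ref, src)
    cand = []
    for off in (-1, 0, 1):
        jj = np.clip(pos + off, 0, len(ref) - 1)
        cand.append(np.stack([np.arange(len(src)), jj]))
    cand = np.unique(np.concatenate(cand, axis=1), axis=1)
    i, j = cand
    diff = np.abs(src[i] - ref[j])
    ok = diff < max_diff
    i, j, diff = i[ok], j[ok], diff[ok]

    order = np.lexsort((ref[j], src[i], diff))
    used_src = np.zeros(len(src), dtype=bool)
    used_ref = np.zeros(len(ref), dtype=bool)
    rows = []
    for k in order:
        si, rj = i[k], j[k]
        if used_src[si] or used_ref[rj]:
            continue
        used_src[si] = used_ref[rj] = True
        rows.append((src[si], ref[rj], diff[k]))
    pairs = pd.DataFrame(rows, columns=["source", "reference", "abs_diff"])
    pairs = pairs.sort_values("reference").reset_index(drop=True)
    return AxisMapping(
        pairs=pairs,
        unmatched_reference=ref[~used_ref],
        unmatched_source=src[~used_src],
        max_diff=max_diff,
    )


def scale_features(
    matrix: FeatureMatrix, stats: Optional[pd.DataFrame] = None
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Per-feature standardization (zero mean, unit spread).

    Zero-spread features map to 0. When ``stats`` (columns ``center, mean,
    sd``) are provided — the apply/test mode — those statistics are used
    instead of recomputing, so test rows never influence scaling.
    """
    if matrix.n_rows == 0:
        raise EmptyInputError("cannot scale an empty matrix")
    if stats is None:
        mean = matrix.values.mean(axis=0)
        sd = matrix.values.std(axis=0)
        stats = pd.DataFrame({"center": matrix.axis.centers, "mean": mean, "sd": sd})
    else:
        if len(stats) != matrix.n_features or not np.allclose(
            stats["center"].to_numpy(), matrix.axis.centers
        ):
            raise ParameterError("scaling stats do not match the matrix feature axis")
        mean = stats["mean"].to_numpy(dtype=float)
        sd = stats["sd"].to_numpy(dtype=float)
    denom = np.where(sd > 0, sd, 1.0)
    scaled = (matrix.values - mean) / denom
    scaled[:, sd == 0] = 0.0
    return FeatureMatrix(values=scaled, axis=matrix.axis, meta=matrix.meta.copy()), stats


@dataclass
class StratifiedSubset:
    """One class-balanced replicate with a train/test partition.

    Row indices refer to the matrix the subset was built from.
    """

    train_rows: np.ndarray
    test_rows: np.ndarray
    sampled_cores: list[str]
    replicate_id: int
    seed: int
    label_column: str = "subtype"

    @property
    def rows(self) -> np.ndarray:
        return np.concatenate([self.train_rows, self.test_rows])


def _sample_balanced_rows(
    meta: pd.DataFrame, label_col: str, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Step (i)-(ii): include all rows of the rarest class; sample whole cores
    of every other class until its row count first reaches the rarest count."""
    labels = meta[label_col]
    counts = labels.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise StratificationError("need at least two classes with spectra")
    rarest = counts.idxmin()
    target = int(counts.min())

    picked: dict[str, np.ndarray] = {}
    sampled_cores: list[str] = []
    for cls in sorted(counts.index):
        cls_meta = meta[labels == cls]
        if cls == rarest:
            picked[cls] = cls_meta.index.to_numpy()
            sampled_cores.extend(sorted(cls_meta["core_id"].unique()))
            continue
        cores = np.array(sorted(cls_meta["core_id"].unique()))
        rng.shuffle(cores)
        rows: list[np.ndarray] = []
        total = 0
        for core in cores:
            core_rows = cls_meta.index[cls_meta["core_id"] == core].to_numpy()
            rows.append(core_rows)
            sampled_cores.append(core)
            total += core_rows.size
            if total >= target:
                break
        if total < target:
            raise StratificationError(f"class {cls!r} has fewer spectra than the rarest class")
        picked[cls] = np.concatenate(rows)
    return picked, sampled_cores


def _split_rows(
    picked: dict[str, np.ndarray],
    meta: pd.DataFrame,
    train_frac: float,
    split_unit: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    train_parts, test_parts = [], []
    test_frac = 1.0 - train_frac
    for cls in sorted(picked):
        rows = picked[cls]
        if split_unit == "spectrum":
            rows = rng.permutation(rows)
            n_test = int(round(test_frac * rows.size))
            test_parts.append(rows[:n_test])
            train_parts.append(rows[n_test:])
        elif split_unit == "core":
            cores = np.array(sorted(meta.loc[rows, "core_id"].unique()))
            if cores.size < 2:
                raise StratificationError(
                    f"class {cls!r} has a single core; core-level split impossible"
                )
            rng.shuffle(cores)
            core_of = meta.loc[rows, "core_id"]
            target = test_frac * rows.size
            test_cores, got = [], 0
            for core in cores[:-1]:  # always leave >= 1 core for training
                if got >= target:
                    break
                test_cores.append(core)
                got += int((core_of == core).sum())
            if not test_cores:
                test_cores = [cores[0]]
            in_test = core_of.isin(test_cores).to_numpy()
            test_parts.append(rows[in_test])
            train_parts.append(rows[~in_test])
        else:
            raise ParameterError("split_unit must be 'core' or 'spectrum'")
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def build_stratified_subsets(
    matrix: FeatureMatrix,
    n_replicates: int = 3,
    train_frac: float = 0.7,
    balance_tol: Optional[int] = None,
    seed: int = 0,
    label_column: str = "subtype",
    split_unit: str = "core",
) -> list[StratifiedSubset]:
    """Build class-balanced replicates with stratified 70/30 splits.

    Per replicate: all spectra of the rarest class are included; cores of
    every other class are sampled uniformly without replacement until that
    class's spectrum count first reaches the rarest count (overshoot bounded
    by one core); rows are then split 70/30 per class, by whole cores
    (default, prevents pixel-level leakage) or by spectra. Replicates differ
    only through the seed stream.
    """
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must be in (0, 1)")
    labels = matrix.labels(label_column)
    if labels.isna().any():
        raise StratificationError("rows with missing labels cannot be stratified")
    meta = matrix.meta.reset_index(drop=True)

    root = np.random.default_rng(seed)
    subsets = []
    for rep in range(1, n_replicates + 1):
        rep_seed = int(root.integers(2**31))
        rng = np.random.default_rng(rep_seed)
        picked, sampled_cores = _sample_balanced_rows(meta, label_column, rng)

        sizes = {cls: rows.size for cls, rows in picked.items()}
        tol = balance_tol
        if tol is None:
            tol = int(meta.groupby("core_id").size().max())
        if max(sizes.values()) - min(sizes.values()) > tol:
            raise StratificationError(
                f"replicate {rep}: class sizes {sizes} exceed balance tolerance {tol}"
            )
        train_rows, test_rows = _split_rows(picked, meta, train_frac, split_unit, rng)
        subsets.append(
            StratifiedSubset(
                train_rows=train_rows,
                test_rows=test_rows,
                sampled_cores=sampled_cores,
                replicate_id=rep,
                seed=rep_seed,
                label_column=label_column,
            )
        )
    return subsets


@dataclass
class FeatureSignature:
    """Features retained by importance ranking, with scores for all inputs."""

    centers: np.ndarray  # selected centers, ascending
    scores: pd.DataFrame  # columns: center, importance (all input features)
    fraction: float

    def __len__(self) -> int:
        return self.centers.size

    def indices_in(self, axis: PeakAxis) -> np.ndarray:
        idx = np.searchsorted(axis.centers, self.centers)
        if np.any(idx >= len(axis)) or not np.allclose(axis.centers[idx], self.centers):
            from .exceptions import FeatureParityError

            raise FeatureParityError("signature centers are not on the given axis")
        return idx


def select_top_features(
    train: FeatureMatrix,
    fraction: float = 0.25,
    forest_size: int = 500,
    seed: int = 0,
    label_column: str = "subtype",
) -> FeatureSignature:
    """Rank features by random-forest Gini importance; keep the top fraction.

    Retains ``floor(fraction * n_features)`` features (e.g. 540 -> 135 at the
    default 25 % cut-off). Ties at the cut are broken by ascending m/z.
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    y = train.labels(label_column).to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("feature selection needs >= 2 label classes")
    forest = RandomForestClassifier(
        n_estimators=forest_size,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(train.values, y)
    importance = forest.feature_importances_
    centers = train.axis.centers
    order = np.lexsort((centers, -importance))
    k = math.floor(fraction * train.n_features)
    if k == 0:
        raise ParameterError("fraction retains zero features for this matrix")
    selected = np.sort(centers[order[:k]])
    scores = pd.DataFrame({"center": centers, "importance": importance})
    return FeatureSignature(centers=selected, scores=scores, fraction=fraction)
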
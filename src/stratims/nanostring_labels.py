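"""NanoString-style count normalization and subtype ground-truth labeling.

The normalization chain runs in the fixed order: background thresholding
(negative-control mean + 2 SD per sample), positive-control normalization
(geometric-mean factors), housekeeping CodeSet-content normalization over
ACTB/GAPDH/GUSB/TBP, then log2 transformation. Labels are assigned by a
pluggable nearest-centroid rule (highest Pearson correlation over a
signature gene set); the published 39-gene classifier itself is proprietary
and is not reconstructed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import SUBTYPES
from .exceptions import EmptyInputError, ParameterError

__all__ = [
    "NanoStringPanel",
    "SubtypeCentroids",
    "background_threshold",
    "positive_control_normalize",
    "housekeeping_normalize",
    "log_transform",
    "assign_subtype_labels",
    "normalize_panel",
]

HOUSEKEEPING_GENES = ("ACTB", "GAPDH", "GUSB", "TBP")
PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")


@dataclass
class NanoStringPanel:
    """Probe x sample count table with a probe-class annotation.

    ``truth`` optionally carries generator ground truth (synthetic panels).
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    truth: Optional[dict] = None

    def __post_init__(self):
        if not self.counts.index.equals(self.probe_class.index):
            raise ParameterError("probe_class must be indexed like counts")
        unknown = set(self.probe_class) - set(PROBE_CLASSES)
        if unknown:
            raise ParameterError(f"unknown probe classes: {sorted(unknown)}")
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("counts must be non-negative")
        for cls in PROBE_CLASSES:
            if not (self.probe_class == cls).any():
                raise ParameterError(f"panel has no {cls!r} probes")

    def probes(self, cls: str) -> pd.Index:
        return self.counts.index[self.probe_class == cls]

    def with_counts(self, counts: pd.DataFrame) -> "NanoStringPanel":
        return NanoStringPanel(counts=counts, probe_class=self.probe_class, truth=self.truth)

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.counts.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.to_csv(path, index_label="probe")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "NanoStringPanel":
        frame = pd.read_csv(path, index_col="probe")
        probe_class = frame.pop("probe_class")
        return cls(counts=frame, probe_class=probe_class)


def _geomean(values: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of a probe subset (requires positive counts)."""
    if (values.to_numpy() <= 0).any():
        raise ParameterError("geometric mean undefined for non-positive counts")
    return np.exp(np.log(values).mean(axis=0))


def background_threshold(panel: NanoStringPanel, include_housekeeping: bool = True) -> NanoStringPanel:
    """Raise sub-background counts to mean + 2 SD of the negative controls.

    The threshold is computed per sample (sample standard deviation);
    control probes are left untouched. Idempotent by construction.
    """
    neg = panel.counts.loc[panel.probes("negative")]
    if len(neg) < 2:
        raise ParameterError("need >= 2 negative-control probes to estimate the background SD")
    threshold = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    targets = list(panel.probes("endogenous"))
    if include_housekeeping:
        targets += list(panel.probes("housekeeping"))
    counts = panel.counts.copy()
    counts.loc[targets] = counts.loc[targets].clip(lower=threshold, axis=1)
    return panel.with_counts(counts)


def positive_control_normalize(panel: NanoStringPanel) -> NanoStringPanel:
    """Scale each sample by its positive-control geometric-mean factor.

    factor(s) = (arithmetic mean over samples of the per-sample geometric
    means) / geometric mean of sample s; applied to all non-control counts.
    """
    g = _geomean(panel.counts.loc[panel.probes("positive")])
    factors = g.mean() / g
    counts = panel.counts.copy()
    targets = list(panel.probes("endogenous")) + list(panel.probes("housekeeping"))
    counts.loc[targets] = counts.loc[targets].mul(factors, axis=1)
    return panel.with_counts(counts)


def housekeeping_normalize(panel: NanoStringPanel) -> NanoStringPanel:
    """Scale endogenous counts by housekeeping geometric-mean factors.

    Uses the four canonical housekeeping genes; after this step the
    per-sample housekeeping geometric means (rescaled by the same factors)
    are equal across samples.
    """
    hk_probes = panel.probes("housekeeping")
    for gene in HOUSEKEEPING_GENES:
        if gene not in hk_probes:
            raise ParameterError(f"housekeeping gene {gene!r} missing from the panel")
    hk = panel.counts.loc[list(HOUSEKEEPING_GENES)]
    g = _geomean(hk)
    factors = g.mean() / g
    counts = panel.counts.copy()
    targets = list(panel.probes("endogenous")) + list(HOUSEKEEPING_GENES)
    counts.loc[targets] = counts.loc[targets].mul(factors, axis=1)
    return panel.with_counts(counts)


def log_transform(panel: NanoStringPanel) -> pd.DataFrame:
    """log2 expression of the endogenous probes (thresholding must precede)."""
    endo = panel.counts.loc[panel.probes("endogenous")]
    if (endo.to_numpy() < 1).any():
        raise ParameterError("counts below 1 present; apply background_threshold first")
    return np.log2(endo)


def normalize_panel(panel: NanoStringPanel, include_housekeeping_threshold: bool = True) -> pd.DataFrame:
    """Full chain: threshold -> positive controls -> housekeeping -> log2."""
    panel = background_threshold(panel, include_housekeeping=include_housekeeping_threshold)
    panel = positive_control_normalize(panel)
    panel = housekeeping_normalize(panel)
    return log_transform(panel)


@dataclass
class SubtypeCentroids:
    """Per-subtype mean log2 expression over a shared signature gene set."""

    values: pd.DataFrame  # genes x subtypes

    def __post_init__(self):
        missing = set(SUBTYPES) - set(self.values.columns)
        if missing:
            raise ParameterError(f"centroids missing subtypes: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def assign_subtype_labels(
    expression: pd.DataFrame, centroids: SubtypeCentroids
) -> pd.DataFrame:
    """Nearest-centroid labels by Pearson correlation over the signature genes.

    Returns one row per sample with the per-subtype correlations and the
    assigned label; ties resolve to the first subtype in canonical order.
    """
    missing = [g for g in centroids.genes if g not in expression.index]
    if missing:
        raise ParameterError(f"expression table missing signature genes: {missing[:5]}")
    x = expression.loc[centroids.genes]
    out = {}
    for subtype in SUBTYPES:
        c = centroids.values[subtype]
        out[subtype] = x.corrwith(c, axis=0)
    table = pd.DataFrame(out)
    labels = [SUBTYPES[i] for i in np.argmax(table[list(SUBTYPES)].to_numpy(), axis=1)]
    table["label"] = labels
    return table
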
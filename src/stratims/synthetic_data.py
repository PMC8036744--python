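"""Synthetic spatial MALDI imaging data with known ground truth.

Real tissue-microarray (TMA) imaging runs of high-grade serous ovarian cancer
are not publicly distributable, so every downstream stage of this package is
exercised on simulated data with the same statistical structure: per-core
pixel grids of continuous profile spectra over an m/z axis, four molecular
subtypes (C1 mesenchymal, C2 immunoreactive, C4 differentiated, C5
proliferative) acting at core level, and a stroma/malignant compartment
structure within each core.

The generative model per pixel spectrum is

    I(m) = t * [ b(m) + sum_k h_k * g(m; c_k + d_k, w) ] + e(m)

where ``g`` is a Gaussian peak profile of FWHM ``w`` at a jittered center,
``h_k`` are channel peak heights with multiplicative log-normal pixel noise,
``b`` is a smooth additive baseline with a slow drift toward low mass,
``t`` is a per-spectrum log-normal total-ion-count factor, and ``e`` is a
small additive detector noise floor. Subtype marker channels are scaled by a
fold-change in the malignant pixels of cores of the associated subtype only;
stroma pixels elevate stroma marker channels and suppress malignant-exclusive
channels to near zero.

Three anchor channels carry the identities used throughout the docs: a
malignant-exclusive channel at 1106.719 m/z (histone H1.2, symbol H1-2), a
stroma-elevated channel at 836.359 m/z (collagen COL1A1), and a
C1-associated subtype marker at 976.490 m/z (smooth-muscle actin ACTA2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import COMPARTMENTS, SUBTYPES, GroundTruth, PeakAxis, SpatialIMSDataset
from .exceptions import ConfigurationError, EmptyInputError

__all__ = [
    "SynthConfig",
    "generate_tma",
    "generate_stroma_labeled",
    "generate_nanostring_panel",
    "generate_peptide_reference",
    "stroma_reference_config",
    "ANCHOR_CHANNELS",
]

#: (m/z, protein symbol, role) anchors planted when inside the configured range.
ANCHOR_CHANNELS = (
    (836.359, "COL1A1", "stroma_up"),
    (976.490, "ACTA2", "subtype"),
    (1106.719, "H1-2", "malignant_only"),
)

#: Fold-elevation of stroma-marker channels in stroma pixels.
STROMA_UP_FOLD = 3.0
#: Residual fraction of malignant-exclusive channels in stroma pixels.
MALIGNANT_ONLY_RESIDUAL = 0.02


@dataclass
class SynthConfig:
    """Study conditions for one synthetic TMA imaging run.

    Defaults emulate the published acquisition scale: ~60 cores of 10x10
    pixels, 540 true peak channels over m/z 800-3200, subtype prevalences
    matching the 279-patient cohort (37.6/27.6/15.8/19.0 %), a 2-fold marker
    effect size and 20 % multiplicative intensity noise.
    """

    n_patients: int = 60
    cores_per_patient: Union[int, Sequence[int]] = 1
    pixels_per_core: tuple[int, int] = (10, 10)
    mz_range: tuple[float, float] = (800.0, 3200.0)
    n_channels: int = 540
    subtype_proportions: tuple[float, float, float, float] = (0.376, 0.276, 0.158, 0.190)
    n_subtype_markers: int = 24
    effect_size: float = 2.0
    stroma_fraction: float = 0.3
    n_stroma_markers: int = 12
    mz_jitter_sd: float = 0.03
    baseline_level: float = 2.0
    noise_cv: float = 0.2
    tic_variation_cv: float = 0.25
    additive_noise_sd: float = 0.05
    peak_fwhm: float = 0.5
    mz_step: float = 0.25
    calibration_offset_sd: float = 0.04
    seed: int = 0
    #: Seed for the shared "proteome panel": channel positions, base peak
    #: heights and marker assignment. Two datasets generated with the same
    #: panel_seed share the underlying molecular structure (as two tissue
    #: cohorts measured with the same assay do), differing only in sampling
    #: noise, labels and mass calibration.
    panel_seed: int = 777

    def cores_per_patient_list(self) -> list[int]:
        if isinstance(self.cores_per_patient, int):
            return [self.cores_per_patient] * self.n_patients
        return list(self.cores_per_patient)

    @property
    def n_cores(self) -> int:
        return int(sum(self.cores_per_patient_list()))

    def validate(self) -> None:
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != len(SUBTYPES) or np.any(props < 0):
            raise ConfigurationError("subtype_proportions must be 4 non-negative weights")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subtype_proportions must sum to 1 within 1e-9")
        low, high = self.mz_range
        if not low < high:
            raise ConfigurationError("mz_range low must be < high")
        r, c = self.pixels_per_core
        if r < 1 or c < 1:
            raise ConfigurationError("pixels_per_core must be a non-empty grid")
        if self.n_patients < 1 or any(k < 1 for k in self.cores_per_patient_list()):
            raise ConfigurationError("need at least one patient and one core per patient")
        if len(self.cores_per_patient_list()) != self.n_patients:
            raise ConfigurationError("cores_per_patient sequence length must equal n_patients")
        if not 0.0 <= self.stroma_fraction < 1.0:
            raise ConfigurationError("stroma_fraction must be in [0, 1)")
        if self.n_channels < 1:
            raise ConfigurationError("need at least one channel")
        if self.n_subtype_markers + self.n_stroma_markers > self.n_channels:
            raise ConfigurationError("marker counts exceed channel count")
        if self.effect_size <= 0 or self.peak_fwhm <= 0 or self.mz_step <= 0:
            raise ConfigurationError("effect_size, peak_fwhm and mz_step must be positive")


def stroma_reference_config(**overrides) -> SynthConfig:
    """Config emulating the compartment-annotated cohort scale: 19 patients, 35 cores."""
    cores = [2] * 16 + [1] * 3  # 16*2 + 3 = 35 cores over 19 patients
    cfg = SynthConfig(n_patients=19, cores_per_patient=cores, stroma_fraction=0.4, seed=1)
    return replace(cfg, **overrides)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal factor with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _channel_centers(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Channel centers on a jittered grid with a guaranteed minimum gap.

    A uniform grid over the usable range is jittered within each cell so that
    neighbouring channels never come closer than ~1.2 Da, keeping single-
    linkage peak clustering at 0.25 Da well posed. Anchor channels replace the
    nearest grid channel when they fall inside the range.
    """
    low, high = cfg.mz_range
    pad = 5.0
    usable_low, usable_high = low + pad, high - pad
    gap = (usable_high - usable_low) / cfg.n_channels
    if gap < 1.3:
        raise ConfigurationError("too many channels for the m/z range")
    grid = usable_low + gap * (np.arange(cfg.n_channels) + 0.5)
    play = max(0.0, (gap - 1.3) / 2.0)
    centers = grid + rng.uniform(-play, play, size=cfg.n_channels)
    for mz, _, _ in ANCHOR_CHANNELS:
        if usable_low < mz < usable_high:
            centers[int(np.argmin(np.abs(centers - mz)))] = mz
    return np.sort(centers)


def _assign_markers(cfg: SynthConfig, centers: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Pick disjoint subtype- and compartment-marker channels, honouring anchors."""
    n = cfg.n_channels
    anchor_idx: dict[str, int] = {}
    for mz, symbol, role in ANCHOR_CHANNELS:
        j = int(np.argmin(np.abs(centers - mz)))
        if abs(centers[j] - mz) < 1e-6:
            anchor_idx[role + ":" + symbol] = j

    taken = set(anchor_idx.values())
    free = np.array([i for i in range(n) if i not in taken])
    rng.shuffle(free)
    free = list(free)

    rows = []
    # Subtype markers, spread round-robin over the four classes. The ACTA2
    # anchor, when present, is the first C1 marker.
    sub_needed = cfg.n_subtype_markers
    classes = list(SUBTYPES)
    k = 0
    if "subtype:ACTA2" in anchor_idx and sub_needed > 0:
        rows.append((centers[anchor_idx["subtype:ACTA2"]], "subtype", "C1", cfg.effect_size, "ACTA2"))
        sub_needed -= 1
        k = 1
    for i in range(sub_needed):
        idx = free.pop()
        cls = classes[(k + i) % 4]
        rows.append((centers[idx], "subtype", cls, cfg.effect_size, f"SYNS{i:03d}"))

    # Compartment markers: alternate stroma-elevated / malignant-exclusive.
    stro_needed = cfg.n_stroma_markers
    j = 0
    if "stroma_up:COL1A1" in anchor_idx and stro_needed > 0:
        rows.append((centers[anchor_idx["stroma_up:COL1A1"]], "stroma_up", "stroma", STROMA_UP_FOLD, "COL1A1"))
        stro_needed -= 1
        j += 1
    if "malignant_only:H1-2" in anchor_idx and stro_needed > 0:
        rows.append((centers[anchor_idx["malignant_only:H1-2"]], "malignant_only", "malignant", MALIGNANT_ONLY_RESIDUAL, "H1-2"))
        stro_needed -= 1
        j += 1
    for i in range(stro_needed):
        idx = free.pop()
        if (j + i) % 2 == 0:
            rows.append((centers[idx], "stroma_up", "stroma", STROMA_UP_FOLD, f"SYNC{i:03d}"))
        else:
            rows.append((centers[idx], "malignant_only", "malignant", MALIGNANT_ONLY_RESIDUAL, f"SYNC{i:03d}"))

    markers = pd.DataFrame(rows, columns=["mz", "kind", "target", "effect", "symbol"])
    return markers.sort_values("mz").reset_index(drop=True)


def _stroma_mask(shape: tuple[int, int], fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous stroma blob: lowest quantile of a smoothed random field."""
    r, c = shape
    npix = r * c
    k = int(round(fraction * npix))
    if k == 0:
        return np.zeros(npix, dtype=bool)
    fld = gaussian_filter(rng.standard_normal((r, c)), sigma=max(1.0, min(r, c) / 5.0))
    order = np.argsort(fld.ravel(), kind="stable")
    mask = np.zeros(npix, dtype=bool)
    mask[order[:k]] = True
    return mask


def _render_core(
    grid_mz: np.ndarray,
    heights: np.ndarray,
    centers: np.ndarray,
    sigma_peak: float,
    step: float,
    low: float,
) -> np.ndarray:
    """Accumulate Gaussian peaks for one core's pixels onto the shared grid."""
    npix, nch = heights.shape
    npts = grid_mz.size
    hw = max(2, int(math.ceil(3.0 * sigma_peak / step)))
    w = 2 * hw + 1
    start = np.round((centers - low) / step).astype(np.int64) - hw  # (npix, nch)
    offs = np.arange(w, dtype=np.int64)
    idx = start[..., None] + offs  # (npix, nch, w)
    np.clip(idx, 0, npts - 1, out=idx)
    mz_at = low + idx * step
    contrib = heights[..., None] * np.exp(
        -0.5 * ((mz_at - centers[..., None]) / sigma_peak) ** 2
    )
    flat_idx = (np.arange(npix, dtype=np.int64)[:, None, None] * npts + idx).ravel()
    out = np.bincount(flat_idx, weights=contrib.ravel(), minlength=npix * npts)
    return out.reshape(npix, npts)


def _generate(cfg: SynthConfig, compartment_labeled: bool, calibrated_offset: bool,
              axis_densify: int = 1) -> tuple[SpatialIMSDataset, GroundTruth]:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel_rng = np.random.default_rng(cfg.panel_seed)

    low, high = cfg.mz_range
    grid_mz = np.arange(low, high + cfg.mz_step / 2, cfg.mz_step)
    npts = grid_mz.size
    sigma_peak = cfg.peak_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    # Channel structure is a property of the assayed proteome, not of one
    # acquisition run: datasets sharing a panel_seed share it.
    centers = _channel_centers(cfg, panel_rng)
    markers = _assign_markers(cfg, centers, panel_rng)
    offset = rng.normal(0.0, cfg.calibration_offset_sd) if calibrated_offset else 0.0

    # Base channel heights, bounded away from the additive noise floor.
    base_heights = np.clip(panel_rng.lognormal(math.log(20.0), 0.5, size=cfg.n_channels), 5.0, 200.0)

    # Per-channel marker bookkeeping as index arrays.
    ch_index = {mz: i for i, mz in enumerate(centers)}
    sub_marker_idx = {cls: [] for cls in SUBTYPES}
    stroma_up_idx, mal_only_idx = [], []
    for _, row in markers.iterrows():
        i = ch_index[row["mz"]]
        if row["kind"] == "subtype":
            sub_marker_idx[row["target"]].append(i)
        elif row["kind"] == "stroma_up":
            stroma_up_idx.append(i)
        else:
            mal_only_idx.append(i)
    stroma_up_idx = np.array(stroma_up_idx, dtype=int)
    mal_only_idx = np.array(mal_only_idx, dtype=int)

    cores_per_patient = cfg.cores_per_patient_list()
    patient_subtypes = rng.choice(len(SUBTYPES), size=cfg.n_patients,
                                  p=np.asarray(cfg.subtype_proportions, dtype=float))

    r, c = cfg.pixels_per_core
    npix = r * c
    n_total = cfg.n_cores * npix
    intensities = np.empty((n_total, npts), dtype=np.float32)

    baseline_curve = cfg.baseline_level * (0.5 + 1.5 * np.exp(-(grid_mz - low) / 800.0))

    pix_rows = []
    core_rows = []
    compartments = np.empty(n_total, dtype=object)
    yy, xx = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    xs, ys = xx.ravel(), yy.ravel()

    pos = 0
    for p in range(cfg.n_patients):
        patient_id = f"P{p:03d}"
        subtype = SUBTYPES[patient_subtypes[p]]
        for t in range(cores_per_patient[p]):
            core_id = f"{patient_id}_T{t}"
            core_rows.append((core_id, patient_id, subtype))
            stroma = _stroma_mask((r, c), cfg.stroma_fraction, rng)

            heights = np.tile(base_heights, (npix, 1))
            # Subtype effect only in malignant pixels of this core's subtype.
            idx = sub_marker_idx[subtype]
            if idx:
                heights[np.ix_(~stroma, idx)] *= cfg.effect_size
            if stroma.any():
                if stroma_up_idx.size:
                    heights[np.ix_(stroma, stroma_up_idx)] *= STROMA_UP_FOLD
                if mal_only_idx.size:
                    heights[np.ix_(stroma, mal_only_idx)] *= MALIGNANT_ONLY_RESIDUAL
            heights *= _lognormal_factor(rng, cfg.noise_cv, (npix, cfg.n_channels))

            jittered = centers[None, :] + offset + rng.normal(0.0, cfg.mz_jitter_sd, (npix, cfg.n_channels))
            block = _render_core(grid_mz, heights, jittered, sigma_peak, cfg.mz_step, low)

            bl_scale = _lognormal_factor(rng, 0.1, npix)
            block += bl_scale[:, None] * baseline_curve[None, :]
            if cfg.additive_noise_sd > 0:
                block += rng.normal(0.0, cfg.additive_noise_sd, block.shape)
            tic = _lognormal_factor(rng, cfg.tic_variation_cv, npix)
            block *= tic[:, None]
            np.clip(block, 0.0, None, out=block)
            intensities[pos:pos + npix] = block

            comp = np.where(stroma, "stroma", "malignant")
            compartments[pos:pos + npix] = comp
            for i in range(npix):
                pix_rows.append((int(xs[i]), int(ys[i]), core_id, patient_id, subtype))
            pos += npix

    pixels = pd.DataFrame(pix_rows, columns=["x", "y", "core_id", "patient_id", "subtype"])
    if compartment_labeled:
        pixels["compartment"] = compartments

    native_axis = None
    if axis_densify > 1:
        dense = np.linspace(low + 2.0, high - 2.0, cfg.n_channels * axis_densify)
        native_axis = PeakAxis(dense, tolerance=0.25)

    dataset = SpatialIMSDataset(
        mz=grid_mz,
        intensities=intensities,
        pixels=pixels,
        compartment_labeled=compartment_labeled,
        native_axis=native_axis,
    )
    core_table = pd.DataFrame(core_rows, columns=["core_id", "patient_id", "subtype"])
    truth = GroundTruth(
        core_subtypes=core_table.set_index("core_id")["subtype"],
        pixel_compartments=pd.Series(compartments, name="compartment"),
        markers=markers.assign(mz=markers["mz"] + offset),
    )
    return dataset, truth


def generate_tma(config: SynthConfig) -> tuple[SpatialIMSDataset, GroundTruth]:
    """Generate a subtype-labeled synthetic TMA imaging run.

    Returns one spectrum per pixel, fully reproducible from ``config.seed``.
    """
    return _generate(config, compartment_labeled=False, calibrated_offset=False)


def generate_stroma_labeled(
    config: SynthConfig, axis_densify: int = 1
) -> tuple[SpatialIMSDataset, GroundTruth]:
    """Generate a compartment-labeled run for stroma-classifier training.

    The run carries a small global mass-calibration offset (drawn from the
    seed stream) so that its peak centers differ slightly from a reference
    run, exercising feature-parity alignment. ``axis_densify`` > 1 attaches a
    dense native feature axis (``n_channels * axis_densify`` centers) to mimic
    full-profile feature export.
    """
    if config.stroma_fraction <= 0:
        raise ConfigurationError("stroma_fraction must be > 0 for a stroma-labeled run")
    return _generate(config, compartment_labeled=True, calibrated_offset=True,
                     axis_densify=axis_densify)


# ---------------------------------------------------------------------------
# NanoString-style count panel
# ---------------------------------------------------------------------------

HOUSEKEEPING_GENES = ("ACTB", "GAPDH", "GUSB", "TBP")
_HK_LOG2 = (11.0, 10.5, 9.0, 8.5)
_POS_CONCENTRATIONS = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


def generate_nanostring_panel(
    n_samples: int,
    true_labels: Sequence[str],
    seed: int,
    n_endogenous: int = 40,
    markers_per_class: int = 10,
    noise_sd: float = 0.15,
    content_cv: float = 0.5,
    lane_cv: float = 0.3,
):
    """Simulate an nCounter-style panel: endogenous genes with subtype shifts,
    titrated positive controls, low-count negative controls, and four
    housekeeping genes scaled by a per-sample RNA-content factor.

    Returns a :class:`~stratims.nanostring_labels.NanoStringPanel` whose
    ``truth`` dict holds the injected labels, content factors and log2 class
    centroids.
    """
    from .nanostring_labels import NanoStringPanel  # local import avoids a cycle

    if n_samples == 0:
        raise EmptyInputError("n_samples must be positive")
    if len(true_labels) != n_samples:
        raise ConfigurationError("true_labels length must equal n_samples")
    bad = set(true_labels) - set(SUBTYPES)
    if bad:
        raise ConfigurationError(f"unknown subtype labels: {sorted(bad)}")
    if n_endogenous < 4 * markers_per_class:
        raise ConfigurationError("n_endogenous must cover 4 * markers_per_class signature genes")

    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:03d}" for i in range(n_endogenous)]
    base = rng.uniform(5.0, 9.0, n_endogenous)
    shift = np.zeros((n_endogenous, 4))
    for k in range(4):
        shift[k * markers_per_class:(k + 1) * markers_per_class, k] = 2.0

    content = _lognormal_factor(rng, content_cv, n_samples)
    lane = _lognormal_factor(rng, lane_cv, n_samples)
    label_idx = np.array([SUBTYPES.index(l) for l in true_labels])

    noise = lambda shape: _lognormal_factor(rng, noise_sd, shape)  # noqa: E731

    endo = np.power(2.0, base[:, None] + shift[:, label_idx]) * content[None, :] * lane[None, :]
    endo = np.maximum(np.rint(endo * noise(endo.shape)), 0.0)

    hk = np.power(2.0, np.asarray(_HK_LOG2))[:, None] * content[None, :] * lane[None, :]
    hk = np.maximum(np.rint(hk * noise(hk.shape)), 1.0)

    pos = np.asarray(_POS_CONCENTRATIONS)[:, None] * 60.0 * lane[None, :]
    pos = np.maximum(np.rint(pos * noise(pos.shape)), 1.0)

    neg = rng.poisson(2.0, (8, n_samples)).astype(float)

    samples = [f"S{i:03d}" for i in range(n_samples)]
    counts = pd.DataFrame(
        np.vstack([endo, hk, pos, neg]),
        index=(genes + list(HOUSEKEEPING_GENES)
               + [f"POS_{chr(65 + i)}" for i in range(6)]
               + [f"NEG_{chr(65 + i)}" for i in range(8)]),
        columns=samples,
    )
    probe_class = pd.Series(
        ["endogenous"] * n_endogenous + ["housekeeping"] * 4 + ["positive"] * 6 + ["negative"] * 8,
        index=counts.index, name="probe_class",
    )
    centroids = pd.DataFrame(base[:, None] + shift, index=genes, columns=list(SUBTYPES))
    signature_genes = [genes[i] for i in range(n_endogenous) if shift[i].any()]
    truth = {
        "labels": pd.Series(list(true_labels), index=samples, name="subtype"),
        "content": pd.Series(content, index=samples, name="content_factor"),
        "centroids": centroids.loc[signature_genes],
        "signature_genes": signature_genes,
    }
    return NanoStringPanel(counts=counts, probe_class=probe_class, truth=truth)


# ---------------------------------------------------------------------------
# Peptide reference list
# ---------------------------------------------------------------------------

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_peptide_reference(ground_truth: GroundTruth, decoy_count: int, seed: int):
    """Build an LC-MS/MS-style reference list covering the planted markers.

    Each planted marker channel gets one entry whose mass sits within
    +/- 0.3 Da of the channel center and carries the marker's protein symbol;
    ``decoy_count`` additional entries are placed at least 1.0 Da away from
    every planted center so that correct matching is uniquely determined.
    """
    from .peptide_annotation import PeptideReference

    rng = np.random.default_rng(seed)
    planted = ground_truth.markers
    if len(planted) == 0:
        raise EmptyInputError("ground truth contains no planted marker channels")

    rows = []
    for _, m in planted.iterrows():
        mass = float(m["mz"]) + rng.uniform(-0.3, 0.3)
        seq = "".join(rng.choice(_AMINO_ACIDS, size=rng.integers(8, 15)))
        rows.append((mass, seq, m["symbol"]))

    centers = planted["mz"].to_numpy(dtype=float)
    lo, hi = centers.min() - 60.0, centers.max() + 60.0
    made = 0
    while made < decoy_count:
        mass = rng.uniform(lo, hi)
        if np.min(np.abs(centers - mass)) >= 1.0:
            seq = "".join(rng.choice(_AMINO_ACIDS, size=rng.integers(8, 15)))
            rows.append((mass, seq, f"DECOY{made:03d}"))
            made += 1

    frame = pd.DataFrame(rows, columns=["mass", "sequence", "protein"])
    return PeptideReference(frame.sort_values("mass").reset_index(drop=True))
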
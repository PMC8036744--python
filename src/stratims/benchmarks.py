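"""Reproducible synthetic benchmark studies at the default cohort scale.

These drive the package end to end under its default study conditions
(~60 cores x 100 spectra x 540 channels; compartment cohort of 19 patients /
35 cores) and measure the quantities the method is judged by: recovery of
planted subtype markers in the selected signature, stroma-exclusion recall
and precision against the generator's compartment truth, and mean one-vs-one
AUC of the complete vs stroma-excluded classifier variants.

Forest sizes here (selection 150 trees, tuning 50 trees on at most 1200
stratified rows, final members 200, stroma members 150) are the package's
single-CPU study sizes; importance rankings and forest accuracy are stable
well below the 500-tree library defaults at this data scale.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np

from .feature_engineering import build_stratified_subsets, scale_features, select_top_features
from .pipeline_cli import PipelineConfig, derive_seeds, run_pipeline
from .spectral_preprocessing import build_feature_matrix, pick_peaks, preprocess_dataset
from .synthetic_data import SynthConfig, generate_tma, stroma_reference_config

logger = logging.getLogger(__name__)

__all__ = [
    "study_config",
    "reporting_signature",
    "marker_recovery",
    "run_full_study_seed",
    "stroma_and_auc_study",
    "marker_recovery_study",
]

_BENCH = dict(
    selection_forest_size=150,
    tuning_forest_size=50,
    tuning_max_rows=1200,
    final_forest_size=200,
    stroma_forest_size=150,
)


def study_config(seed: int) -> PipelineConfig:
    """Default-scale pipeline configuration for one study seed."""
    seed = int(seed) % (2**31)
    return PipelineConfig(
        synth=SynthConfig(seed=seed),
        stroma_synth=stroma_reference_config(seed=(seed + 104729) % (2**31)),
        seed=seed,
        **_BENCH,
    )


def reporting_signature(config: PipelineConfig):
    """The pipeline's reporting signature without training the classifiers.

    Reproduces exactly the replicate-1 signature `run_pipeline` would emit:
    same derived seeds, same subset, same scaling, same selection forest.
    Returns (signature, ground truth).
    """
    seeds = derive_seeds(config)
    tma, truth = generate_tma(config.synth)
    pre = preprocess_dataset(tma, width=config.baseline_width, target_sum=config.target_sum)
    axis = pick_peaks(pre, config.snr_threshold, config.bin_tolerance, config.min_occurrence)
    fm = build_feature_matrix(pre, axis)
    subsets = build_stratified_subsets(
        fm, n_replicates=3, train_frac=config.train_frac,
        seed=seeds["subsets_complete"], label_column="subtype", split_unit=config.split_unit,
    )
    prep1, _ = scale_features(fm.take_rows(subsets[0].train_rows))
    sig = select_top_features(prep1, fraction=config.selection_fraction,
                              forest_size=config.selection_forest_size, seed=subsets[0].seed)
    return sig, truth


def marker_recovery(signature, truth, tolerance: float = 0.25) -> np.ndarray:
    """Per planted subtype marker: is it within tolerance of a signature center?"""
    markers = truth.markers.query("kind == 'subtype'")["mz"].to_numpy(dtype=float)
    if signature.centers.size == 0:
        return np.zeros(markers.size, dtype=bool)
    return np.array([np.min(np.abs(signature.centers - m)) < tolerance for m in markers])


def run_full_study_seed(seed: int) -> dict:
    """One full two-variant pipeline run; returns the per-seed study metrics."""
    config = study_config(seed)
    result = run_pipeline(config)
    truth = result.truth
    true_stroma = (truth.pixel_compartments == "stroma").to_numpy()
    excluded = result.decision_log["excluded"].to_numpy()
    tp = int((excluded & true_stroma).sum())
    rec = marker_recovery(result.signature, truth, tolerance=config.bin_tolerance)
    out = {
        "seed": int(seed),
        "auc_complete": result.reports["complete"].mean_ovo_auc,
        "auc_stroma_excluded": result.reports["stroma_excluded"].mean_ovo_auc,
        "balanced_accuracy_complete": result.reports["complete"].balanced_accuracy_mean,
        "balanced_accuracy_excluded": result.reports["stroma_excluded"].balanced_accuracy_mean,
        "fdr_complete": result.reports["complete"].fdr_macro_mean,
        "fdr_excluded": result.reports["stroma_excluded"].fdr_macro_mean,
        "stroma_recall": tp / max(int(true_stroma.sum()), 1),
        "stroma_precision": tp / max(int(excluded.sum()), 1),
        "n_excluded": int(excluded.sum()),
        "marker_recovered": rec,
    }
    logger.info("seed %d: AUC %.4f -> %.4f, recall %.3f, precision %.3f",
                seed, out["auc_complete"], out["auc_stroma_excluded"],
                out["stroma_recall"], out["stroma_precision"])
    return out


def stroma_and_auc_study(seeds: Sequence[int]) -> list[dict]:
    """Full pipeline study over several seeds (both classifier variants)."""
    return [run_full_study_seed(s) for s in seeds]


def marker_recovery_study(seeds: Sequence[int]) -> list[np.ndarray]:
    """Signature-only runs: per seed, the per-marker recovery vector."""
    out = []
    for s in seeds:
        config = study_config(s)
        sig, truth = reporting_signature(config)
        rec = marker_recovery(sig, truth, tolerance=config.bin_tolerance)
        logger.info("seed %d: %d/%d subtype markers in signature", s, rec.sum(), rec.size)
        out.append(rec)
    return out
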
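"""Shared fixtures: small synthetic runs reused across test modules."""

import numpy as np
import pytest

from stratims.synthetic_data import SynthConfig, generate_stroma_labeled, generate_tma


def tiny_config(**overrides) -> SynthConfig:
    """Small, fast study conditions for unit tests (seconds, not minutes)."""
    base = dict(
        n_patients=16,
        cores_per_patient=1,
        pixels_per_core=(6, 6),
        mz_range=(800.0, 1300.0),
        n_channels=30,
        subtype_proportions=(0.25, 0.25, 0.25, 0.25),
        n_subtype_markers=8,
        n_stroma_markers=4,
        stroma_fraction=0.3,
        seed=42,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def tiny_tma():
    cfg = tiny_config()
    dataset, truth = generate_tma(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def tiny_stroma():
    cfg = tiny_config(n_patients=8, cores_per_patient=2, stroma_fraction=0.4, seed=7)
    dataset, truth = generate_stroma_labeled(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_tma):
    from stratims.spectral_preprocessing import build_feature_matrix, pick_peaks, preprocess_dataset

    cfg, dataset, truth = tiny_tma
    pre = preprocess_dataset(dataset)
    axis = pick_peaks(pre)
    matrix = build_feature_matrix(pre, axis)
    return cfg, pre, axis, matrix, truth
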
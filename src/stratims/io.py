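"""Reading and writing standard formats: imzML/.ibd plus CSV sidecar tables.

A dataset is stored as a continuous-mode imzML file (one shared m/z axis)
with two sidecars: ``cores.csv`` (core_id, patient_id, subtype) and
``pixels.csv`` (gx, gy, x, y, core_id[, compartment]) where (gx, gy) are the
global slide coordinates written into the imzML and (x, y) are core-local.
Cores are laid out side by side on the global grid.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .containers import GroundTruth, SpatialIMSDataset
from .exceptions import UnsupportedDialectError

logger = logging.getLogger(__name__)

__all__ = ["write_ims", "read_ims", "write_ground_truth", "read_ground_truth"]


def _global_coordinates(pixels: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Lay cores out left-to-right on one global grid with a 1-pixel gap."""
    gx = np.empty(len(pixels), dtype=int)
    gy = pixels["y"].to_numpy(dtype=int)
    offset = 0
    for core_id, idx in pixels.groupby("core_id", sort=False).groups.items():
        xs = pixels.loc[idx, "x"].to_numpy(dtype=int)
        gx[np.asarray(idx, dtype=int)] = xs + offset
        offset += xs.max() + 2
    return gx, gy


def write_ims(
    dataset: SpatialIMSDataset,
    directory: Union[str, Path],
    stem: str = "data",
) -> Path:
    """Write a dataset as continuous-mode imzML plus CSV sidecars.

    Returns the directory. Files: ``<stem>.imzML``, ``<stem>.ibd``,
    ``cores.csv``, ``pixels.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pixels = dataset.pixels.reset_index(drop=True)
    gx, gy = _global_coordinates(pixels)

    imzml_path = directory / f"{stem}.imzML"
    with ImzMLWriter(str(imzml_path), mode="continuous", spec_type="profile") as writer:
        for i in range(dataset.n_spectra):
            writer.addSpectrum(dataset.mz, dataset.intensities[i],
                               (int(gx[i]) + 1, int(gy[i]) + 1, 1))

    sidecar = pixels.copy()
    sidecar.insert(0, "gy", gy)
    sidecar.insert(0, "gx", gx)
    pixel_cols = ["gx", "gy", "x", "y", "core_id"]
    if "compartment" in sidecar.columns:
        pixel_cols.append("compartment")
    sidecar[pixel_cols].to_csv(directory / "pixels.csv", index=False)

    cores = pixels.drop_duplicates("core_id")[
        [c for c in ("core_id", "patient_id", "subtype") if c in pixels.columns]
    ]
    cores.to_csv(directory / "cores.csv", index=False)
    return directory


def _check_continuous(imzml_path: Path) -> None:
    head = imzml_path.read_text(errors="ignore")[:20000]
    if 'name="processed"' in head:
        raise UnsupportedDialectError(
            f"{imzml_path} is processed-mode imzML; only continuous mode is supported"
        )


def read_ims(
    imzml_path: Union[str, Path],
    core_table: Union[str, Path],
    pixel_table: Union[str, Path],
) -> SpatialIMSDataset:
    """Read continuous-mode imzML with its sidecar tables into a dataset.

    Spectra present in the imzML but absent from the pixel table are dropped
    with a warning; missing files raise :class:`FileNotFoundError` naming
    the offending path.
    """
    imzml_path = Path(imzml_path)
    for p in (imzml_path, Path(core_table), Path(pixel_table)):
        if not p.exists():
            raise FileNotFoundError(f"required input file not found: {p}")
    _check_continuous(imzml_path)

    pixels = pd.read_csv(pixel_table)
    cores = pd.read_csv(core_table)
    key_of = {
        (int(r["gx"]) + 1, int(r["gy"]) + 1): i for i, r in pixels.iterrows()
    }

    parser = ImzMLParser(str(imzml_path))
    mz0, _ = parser.getspectrum(0)
    rows, row_meta_idx = [], []
    for i, (cx, cy, _) in enumerate(parser.coordinates):
        j = key_of.get((int(cx), int(cy)))
        if j is None:
            logger.warning("pixel at (%d, %d) absent from pixel table; excluded", cx, cy)
            continue
        mzs, ints = parser.getspectrum(i)
        if mzs.size != mz0.size or not np.allclose(mzs, mz0):
            raise UnsupportedDialectError("spectra do not share one m/z axis (not continuous mode)")
        rows.append(ints)
        row_meta_idx.append(j)

    meta = pixels.iloc[row_meta_idx].reset_index(drop=True)
    meta = meta.merge(cores, on="core_id", how="left", validate="many_to_one")
    compartment_labeled = "compartment" in meta.columns
    return SpatialIMSDataset(
        mz=np.asarray(mz0, dtype=float),
        intensities=np.vstack(rows).astype(np.float32),
        pixels=meta.drop(columns=["gx", "gy"]),
        compartment_labeled=compartment_labeled,
    )


def write_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    """Serialize planted markers and labels as JSON."""
    payload = {
        "core_subtypes": truth.core_subtypes.to_dict(),
        "pixel_compartments": truth.pixel_compartments.tolist(),
        "markers": truth.markers.to_dict("records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        core_subtypes=pd.Series(payload["core_subtypes"], name="subtype"),
        pixel_compartments=pd.Series(payload["pixel_compartments"], name="compartment"),
        markers=pd.DataFrame(payload["markers"]),
    )
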
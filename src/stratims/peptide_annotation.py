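"""Annotation of discriminative m/z features against an LC-MS/MS peptide list.

Each selected feature is assigned the reference peptide with the smallest
absolute mass difference, provided that difference is below the matching
tolerance (default 1.0 Da). Several features may map to the same peptide;
exact ties between two reference masses resolve to the lower mass and are
flagged as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ParameterError
from .feature_engineering import FeatureSignature

__all__ = ["PeptideReference", "PeptideMatch", "match_peptides", "matches_to_frame"]

_TIE_EPS = 1e-9


@dataclass
class PeptideReference:
    """Processed nLC-MS/MS reference list: (mass Da, sequence, protein symbol)."""

    entries: pd.DataFrame  # columns: mass, sequence, protein

    def __post_init__(self):
        required = {"mass", "sequence", "protein"}
        if not required.issubset(self.entries.columns):
            raise ParameterError(f"reference needs columns {sorted(required)}")
        e = self.entries
        if len(e) and ((e["mass"] <= 0).any() or (e["sequence"] == "").any() or (e["protein"] == "").any()):
            raise ParameterError("masses must be positive; sequences and symbols non-empty")

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PeptideReference":
        return cls(pd.read_csv(path))


@dataclass
class PeptideMatch:
    """One feature-to-peptide assignment."""

    feature_mz: float
    matched_mass: float
    abs_diff: float
    protein: str
    sequence: str
    ambiguous: bool


def match_peptides(
    signature: FeatureSignature,
    reference: PeptideReference,
    max_diff: float = 1.0,
) -> list[PeptideMatch]:
    """Match each signature feature to the reference entry of minimal |Δmass|.

    Features whose nearest reference mass is ``max_diff`` or farther stay
    unmatched. The matching is deterministic and independent of the order of
    the reference list: candidates are compared by (|Δ|, mass), so exact-|Δ|
    ties go to the lower mass and are flagged ambiguous.
    """
    if max_diff <= 0:
        raise ParameterError("max_diff must be positive")
    if len(reference) == 0:
        raise EmptyInputError("peptide reference list is empty")

    entries = reference.entries.sort_values(["mass", "sequence"]).reset_index(drop=True)
    masses = entries["mass"].to_numpy(dtype=float)

    matches = []
    for mz in signature.centers:
        diffs = np.abs(masses - mz)
        best = diffs.min()
        if best >= max_diff:
            continue
        tied = np.flatnonzero(diffs <= best + _TIE_EPS)
        chosen = tied[0]  # lowest mass among exact ties (entries sorted by mass)
        row = entries.iloc[chosen]
        matches.append(
            PeptideMatch(
                feature_mz=float(mz),
                matched_mass=float(row["mass"]),
                abs_diff=float(best),
                protein=str(row["protein"]),
                sequence=str(row["sequence"]),
                ambiguous=len(tied) > 1,
            )
        )
    return matches


def matches_to_frame(signature: FeatureSignature, matches: list[PeptideMatch]) -> pd.DataFrame:
    """Tabulate matches with summary attributes (n features/matched/proteins)."""
    frame = pd.DataFrame(
        [
            {
                "feature_mz": m.feature_mz,
                "matched_mass": m.matched_mass,
                "abs_diff": m.abs_diff,
                "protein": m.protein,
                "sequence": m.sequence,
                "ambiguous": m.ambiguous,
            }
            for m in matches
        ]
    )
    frame.attrs["n_features"] = len(signature)
    frame.attrs["n_matched"] = len(matches)
    frame.attrs["n_proteins"] = int(frame["protein"].nunique()) if len(frame) else 0
    return frame
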
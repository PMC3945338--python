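"""Per-residue water-contact profiles over an ensemble or trajectory.

A residue's hydration in one frame is the number of distinct water oxygens
within a cutoff (default 3.5 A, the first hydration shell) of any of its
heavy atoms; one water may count toward several residues.  The profile is
the per-frame mean, plus a unitless "relative" track normalized by its own
maximum, which is how hydration tracks of transmembrane helices are usually
plotted (peaking at the membrane-interface residues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Conformation, StructureEnsemble

__all__ = ["WaterSet", "HydrationProfile", "water_contacts_frame", "hydration_profile"]

DEFAULT_CUTOFF = 3.5


class WaterSet:
    """Per-frame lists of water oxygen coordinates (Angstrom)."""

    def __init__(self, frames: list[np.ndarray]):
        self.frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]


@dataclass(frozen=True)
class HydrationProfile:
    residue_index: np.ndarray
    mean_contacts: np.ndarray  # waters per frame, per residue
    relative: np.ndarray  # mean_contacts / max, in [0, 1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue": self.residue_index,
                "mean_contacts": self.mean_contacts,
                "relative": self.relative,
            }
        )


def water_contacts_frame(conf: Conformation, waters: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Count distinct waters within ``cutoff`` of each residue's heavy atoms."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = conf.residue_indices()
    counts = np.zeros(len(residues), dtype=float)
    waters = np.asarray(waters, dtype=float).reshape(-1, 3)
    if len(waters) == 0:
        return counts
    tree = cKDTree(waters)
    for i, r in enumerate(residues):
        heavy = np.array([a.coords for a in conf.residue_atoms(r) if a.element != "H"])
        if len(heavy) == 0:
            continue
        hit: set[int] = set()
        for neighbors in tree.query_ball_point(heavy, r=cutoff):
            hit.update(neighbors)
        counts[i] = len(hit)
    return counts


def hydration_profile(
    ensemble: StructureEnsemble, waters: WaterSet, cutoff: float = DEFAULT_CUTOFF
) -> HydrationProfile:
    """Mean water contacts per residue over frames, with max-normalized track."""
    if len(waters) != len(ensemble):
        raise ValueError(
            f"frame count mismatch: {len(ensemble)} conformations vs {len(waters)} water frames"
        )
    residues = np.array(ensemble[0].residue_indices())
    per_frame = np.array(
        [water_contacts_frame(conf, waters[i], cutoff) for i, conf in enumerate(ensemble)]
    )
    mean = per_frame.mean(axis=0)
    peak = mean.max()
    relative = mean / peak if peak > 0 else np.zeros_like(mean)
    return HydrationProfile(residue_index=residues, mean_contacts=mean, relative=relative)
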
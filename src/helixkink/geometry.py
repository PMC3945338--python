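"""Helix axes, kink/bend angles, membrane tilt, and the hinge dihedral CVs.

The kink at the Gly708-Gly709 hinge of the APP transmembrane helix is
quantified two ways in the literature, and both conventions are carried:

* ``bend_deg`` — deviation from straight (0 deg = perfectly straight helix);
* ``axis_angle_deg`` — the inter-segment axis angle on the 180-deg-straight
  convention (``axis_angle_deg = 180 - bend_deg`` exactly).

The two collective-variable dihedrals are the backbone torsions linking the
nitrogen atoms across the hinge: N(708)-CA(708)-C(708)-N(709) and
N(709)-CA(709)-C(709)-N(710) — i.e. the psi torsions of the two hinge
residues.  Hinge residue indices are parameters, defaulting to author
numbering 708/709/710.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Conformation, GeometryError, MembraneFrame

__all__ = [
    "HelixAxis",
    "KinkGeometry",
    "KinkDihedrals",
    "fit_helix_axis",
    "bend_angle",
    "tilt_angle",
    "cv_dihedrals",
    "dihedral",
    "circular_mean_deg",
    "circular_std_deg",
    "wrap_deg",
    "ensemble_geometry_table",
]

DEFAULT_HINGE = (708, 709)
DEFAULT_SEGMENT_N = (700, 708)
DEFAULT_SEGMENT_C = (710, 723)


@dataclass(frozen=True)
class HelixAxis:
    centroid: np.ndarray
    direction: np.ndarray  # unit, oriented N-terminus -> C-terminus
    residue_range: tuple[int, int]

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))


@dataclass(frozen=True)
class KinkGeometry:
    bend_deg: float
    axis_angle_deg: float
    hinge: tuple[int, int]

    def __post_init__(self):
        if not (0.0 <= self.bend_deg <= 180.0):
            raise ValueError("bend angle must lie in [0, 180] degrees")
        if abs(self.axis_angle_deg - (180.0 - self.bend_deg)) > 1e-12:
            raise ValueError("axis_angle_deg must equal 180 - bend_deg")


@dataclass(frozen=True)
class KinkDihedrals:
    cv1_deg: float  # N(h1)-CA(h1)-C(h1)-N(h2)
    cv2_deg: float  # N(h2)-CA(h2)-C(h2)-N(h3)


def wrap_deg(angle) -> np.ndarray | float:
    """Wrap angle(s) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -np.remainder(-a + 180.0, 360.0) + 180.0
    return float(wrapped) if np.isscalar(angle) or wrapped.ndim == 0 else wrapped


def fit_helix_axis(conf: Conformation, residue_range: tuple[int, int]) -> HelixAxis:
    """Fit the helix axis over a residue range.

    Each local center is the mean of a sliding window of 4 consecutive CA
    atoms, which cancels the ~3.6-residue helical wobble; the axis direction
    is the first principal component of those centers, sign-fixed so it
    points from the N- toward the C-terminal end of the range.
    """
    start, end = residue_range
    ca = []
    for r in range(start, end + 1):
        a = conf.get(r, "CA")
        if a is not None:
            ca.append(a.coords)
    if len(ca) < 5:
        raise GeometryError(
            f"helix axis fit needs >=5 consecutive CA atoms in {start}-{end}, found {len(ca)}"
        )
    ca = np.array(ca)
    window = 4
    centers = np.array([ca[i : i + window].mean(axis=0) for i in range(len(ca) - window + 1)])
    centroid = centers.mean(axis=0)
    _, _, vt = np.linalg.svd(centers - centroid)
    direction = vt[0]
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    return HelixAxis(centroid=centroid, direction=direction / np.linalg.norm(direction), residue_range=(start, end))


def bend_angle(
    conf: Conformation,
    segment_n: tuple[int, int] = DEFAULT_SEGMENT_N,
    segment_c: tuple[int, int] = DEFAULT_SEGMENT_C,
    hinge: tuple[int, int] = DEFAULT_HINGE,
) -> KinkGeometry:
    """Angle between the helix axes of the segments flanking the hinge."""
    if segment_n[1] >= segment_c[0]:
        raise ValueError("N- and C-terminal segments must not overlap")
    ax_n = fit_helix_axis(conf, segment_n)
    ax_c = fit_helix_axis(conf, segment_c)
    cosang = float(np.clip(np.dot(ax_n.direction, ax_c.direction), -1.0, 1.0))
    bend = float(np.degrees(np.arccos(cosang)))
    return KinkGeometry(bend_deg=bend, axis_angle_deg=180.0 - bend, hinge=tuple(hinge))


def tilt_angle(axis: HelixAxis, frame: MembraneFrame) -> float:
    """Helix tilt from the membrane normal, in [0, 90] degrees."""
    c = abs(float(np.dot(axis.direction, frame.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle of four points, IUPAC sign convention, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return wrap_deg(np.degrees(np.arctan2(y, x)))


def cv_dihedrals(conf: Conformation, sites: tuple[int, int, int] = (708, 709, 710)) -> KinkDihedrals:
    """The two nitrogen-linked hinge torsions (psi of each hinge residue)."""
    h1, h2, h3 = sites
    cv1 = dihedral(
        conf.atom_coords(h1, "N"),
        conf.atom_coords(h1, "CA"),
        conf.atom_coords(h1, "C"),
        conf.atom_coords(h2, "N"),
    )
    cv2 = dihedral(
        conf.atom_coords(h2, "N"),
        conf.atom_coords(h2, "CA"),
        conf.atom_coords(h2, "C"),
        conf.atom_coords(h3, "N"),
    )
    return KinkDihedrals(cv1_deg=cv1, cv2_deg=cv2)


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, result wrapped to (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular mean of an empty angle list is undefined")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    if np.hypot(s, c) < 1e-9:
        raise ValueError("circular mean undefined: angles are uniformly opposed")
    return wrap_deg(np.degrees(np.arctan2(s, c)))


def circular_std_deg(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular std of an empty angle list is undefined")
    r = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
    r = min(max(r, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def ensemble_geometry_table(
    ensemble,
    segment_n: tuple[int, int] = DEFAULT_SEGMENT_N,
    segment_c: tuple[int, int] = DEFAULT_SEGMENT_C,
    hinge: tuple[int, int] = DEFAULT_HINGE,
    cv_sites: tuple[int, int, int] = (708, 709, 710),
    frame: MembraneFrame | None = None,
):
    """Per-model geometry summary as a pandas DataFrame.

    Columns: model, bend_deg, axis_angle_deg, tilt_deg (NaN without a
    membrane frame), cv1_deg, cv2_deg.
    """
    import pandas as pd

    full_range = (segment_n[0], segment_c[1])
    rows = []
    for i, conf in enumerate(ensemble):
        kink = bend_angle(conf, segment_n, segment_c, hinge)
        cv = cv_dihedrals(conf, cv_sites)
        tilt = np.nan
        if frame is not None:
            tilt = tilt_angle(fit_helix_axis(conf, full_range), frame)
        rows.append(
            {
                "model": conf.label or str(i + 1),
                "bend_deg": kink.bend_deg,
                "axis_angle_deg": kink.axis_angle_deg,
                "tilt_deg": tilt,
                "cv1_deg": cv.cv1_deg,
                "cv2_deg": cv.cv2_deg,
            }
        )
    return pd.DataFrame(rows)
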
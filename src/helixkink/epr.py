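"""Pseudo spin labels, DEER-style distance distributions, Boltzmann-weighted
ensembles, and EPR membrane depth-parameter profiles.

The label model is a deliberately simple accessible-volume construction: N-O
midpoint candidates are sampled in a cone about the Calpha->Cbeta direction at
a Gaussian radial distance (mean 7 A, the typical Calpha-to-nitroxide reach of
an MTSL side chain), candidates clashing with protein heavy atoms are
rejected, and — when an implicit membrane is present — surviving candidates
are re-weighted toward the bilayer interior, reflecting the strong burial
preference of the hydrophobic nitroxide tag.  It is a synthetic stand-in
model, not a rotamer library.

Distances are measured between N-O midpoints.  Distribution densities are
reported on a uniform grid (default 0-80 A at 0.25 A, bracketing the
DEER-sensitive 18-60 A range), Gaussian-smoothed and normalized to unit
area; the reported mean/sd are the weighted moments of the raw pair
distances, computed before smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import Conformation, MembraneFrame

__all__ = [
    "LabelEnsemble",
    "DistanceDistribution",
    "DepthProfile",
    "PlacementError",
    "place_pseudo_label",
    "distance_distribution",
    "boltzmann_weights",
    "depth_profile",
    "profile_correlation",
    "membrane_depth",
    "read_distance_table",
    "write_distance_table",
]

KB_KCAL = 0.0019872  # kcal / (mol K)


class PlacementError(RuntimeError):
    """No sterically allowed label position could be found."""


@dataclass(frozen=True)
class LabelEnsemble:
    """Candidate N-O midpoint positions for one labeled site, with weights."""

    site: int
    positions: np.ndarray  # (n, 3) Angstrom
    weights: np.ndarray  # non-negative, sum 1

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.positions, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if p.shape[0] == 0:
            raise ValueError("label ensemble must contain at least one position")
        if w.shape != (p.shape[0],) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per position")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "weights", w)

    @property
    def mean_position(self) -> np.ndarray:
        return self.weights @ self.positions


@dataclass(frozen=True)
class DistanceDistribution:
    grid: np.ndarray  # Angstrom, uniform spacing
    density: np.ndarray  # per Angstrom, trapezoid-integrates to 1
    mean: float
    sd: float

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if np.any(d < -1e-12):
            raise ValueError("density must be non-negative")
        area = np.trapezoid(d, g)
        if abs(area - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 (got {area})")
        if not (g[0] <= self.mean <= g[-1]):
            raise ValueError("mean must lie inside the distance grid")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "density", d)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.density, **kwargs)
        ax.set_xlabel("distance (Å)")
        ax.set_ylabel("P(r) (1/Å)")
        return ax


@dataclass(frozen=True)
class DepthProfile:
    residue_index: np.ndarray
    depth_ang: np.ndarray  # signed distance from nearest phosphate plane, + toward center
    phi: np.ndarray  # dimensionless depth parameter

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"residue": self.residue_index, "depth_ang": self.depth_ang, "phi": self.phi}
        )


# ---------------------------------------------------------------------------
# Label placement
# ---------------------------------------------------------------------------

def _cbeta_direction(conf: Conformation, site: int) -> tuple[np.ndarray, np.ndarray]:
    """Calpha position and unit Calpha->Cbeta direction (ideal reconstruction
    from N, C, CA for glycines or stripped side chains)."""
    ca = conf.atom_coords(site, "CA")
    cb_atom = conf.get(site, "CB")
    if cb_atom is not None:
        d = cb_atom.coords - ca
        return ca, d / np.linalg.norm(d)
    n = conf.atom_coords(site, "N")
    c = conf.atom_coords(site, "C")
    # ideal tetrahedral Cbeta: opposite the bisector of CA->N and CA->C,
    # tilted out of the N-CA-C plane
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    d = bis * np.cos(np.radians(54.0)) + perp * np.sin(np.radians(54.0))
    return ca, d / np.linalg.norm(d)


def membrane_depth(z: float | np.ndarray, frame: MembraneFrame) -> np.ndarray | float:
    """Signed distance from the nearer phosphate plane, positive toward the
    membrane center, negative toward water."""
    z = np.asarray(z, dtype=float)
    d_upper = frame.z_phosphate_upper - z
    d_lower = z - frame.z_phosphate_lower
    depth = np.where(np.abs(d_upper) <= np.abs(d_lower), d_upper, d_lower)
    return float(depth) if depth.ndim == 0 else depth


def place_pseudo_label(
    conf: Conformation,
    site: int,
    n_samples: int = 500,
    radius_mean: float = 7.0,
    radius_sd: float = 1.0,
    clash_cutoff: float = 2.5,
    cone_half_angle_deg: float = 60.0,
    lambda_bury: float = 5.0,
    seed: int = 0,
    frame: MembraneFrame | None = None,
) -> LabelEnsemble:
    """Sample sterically allowed pseudo-label (N-O midpoint) positions.

    Candidates are drawn uniformly in a cone about the Calpha->Cbeta axis at
    Gaussian radial distance from Calpha; any candidate within
    ``clash_cutoff`` of a heavy atom outside the labeled residue is
    rejected.  With a membrane frame, surviving candidates are re-weighted
    by exp(depth / lambda_bury) (depth positive into the membrane), then
    normalized — deeper positions always gain weight.
    """
    ca, axis = _cbeta_direction(conf, site)
    rng = np.random.default_rng(seed)
    cos_min = np.cos(np.radians(cone_half_angle_deg))
    # orthonormal frame around the cone axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    cos_t = rng.uniform(cos_min, 1.0, size=n_samples)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi_az = rng.uniform(0.0, 2.0 * np.pi, size=n_samples)
    radii = rng.normal(radius_mean, radius_sd, size=n_samples)
    dirs = (
        cos_t[:, None] * axis
        + (sin_t * np.cos(phi_az))[:, None] * e1
        + (sin_t * np.sin(phi_az))[:, None] * e2
    )
    candidates = ca + radii[:, None] * dirs

    heavy = np.array(
        [a.coords for a in conf.atoms if a.element != "H" and a.residue_index != site]
    )
    if len(heavy):
        from scipy.spatial import cKDTree

        tree = cKDTree(heavy)
        clash = tree.query_ball_point(candidates, r=clash_cutoff)
        keep = np.array([len(c) == 0 for c in clash])
    else:
        keep = np.ones(n_samples, dtype=bool)
    positions = candidates[keep]
    if len(positions) == 0:
        raise PlacementError(
            f"all {n_samples} label candidates at residue {site} clash within {clash_cutoff} A"
        )

    weights = np.ones(len(positions))
    if frame is not None:
        depth = membrane_depth(positions[:, 2], frame)
        weights = weights * np.exp(np.asarray(depth) / lambda_bury)
    weights = weights / weights.sum()
    return LabelEnsemble(site=site, positions=positions, weights=weights)


# ---------------------------------------------------------------------------
# Distance distributions
# ---------------------------------------------------------------------------

def distance_distribution(
    a: LabelEnsemble,
    b: LabelEnsemble,
    grid_min: float = 0.0,
    grid_max: float = 80.0,
    grid_spacing: float = 0.25,
    bandwidth: float = 1.0,
) -> DistanceDistribution:
    """Weighted distribution of all cross-pair label-label distances.

    Pair weights are the products w_a * w_b.  The histogram on the grid is
    Gaussian-smoothed (sigma = ``bandwidth``) and renormalized to unit
    trapezoid area; mean/sd are the weighted moments of the raw pair
    distances, unaffected by smoothing.
    """
    diff = a.positions[:, None, :] - b.positions[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=-1)).ravel()
    weights = np.outer(a.weights, b.weights).ravel()
    if dists.min() < grid_min or dists.max() > grid_max:
        raise ValueError(
            f"grid [{grid_min}, {grid_max}] does not cover pair distances "
            f"[{dists.min():.2f}, {dists.max():.2f}]"
        )
    mean = float(weights @ dists)
    var = float(weights @ (dists - mean) ** 2)
    sd = float(np.sqrt(max(var, 0.0)))

    grid = np.arange(grid_min, grid_max + 0.5 * grid_spacing, grid_spacing)
    edges = np.concatenate([grid - 0.5 * grid_spacing, [grid[-1] + 0.5 * grid_spacing]])
    hist, _ = np.histogram(dists, bins=edges, weights=weights)
    density = gaussian_filter1d(hist, sigma=bandwidth / grid_spacing, mode="constant")
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("empty distance histogram on the requested grid")
    return DistanceDistribution(grid=grid, density=density / area, mean=mean, sd=sd)


def boltzmann_weights(fes, assignments, temperature_K: float = 300.0) -> np.ndarray:
    """Boltzmann weights w_i ~ exp(-F(bin_i) / kT) for conformers assigned to
    free-energy-surface bins.

    ``assignments`` is a sequence of (i, j) grid indices into ``fes.f``.
    Invariant to any constant shift of the surface.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("empty bin assignment")
    f = np.array([fes.f[i, j] for i, j in assignments], dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("assigned bins include non-finite free energy")
    kt = KB_KCAL * temperature_K
    w = np.exp(-(f - f.min()) / kt)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

def depth_profile(
    labels: list[LabelEnsemble],
    frame: MembraneFrame,
    phi_max: float = 5.0,
    lambda_ang: float = 10.0,
) -> DepthProfile:
    """Membrane depth parameter per labeled residue.

    depth is the signed distance of the weighted-mean label position from
    the nearer phosphate plane (positive toward the bilayer center); the
    dimensionless depth parameter uses the monotone saturating calibration
    proxy phi = phi_max * tanh(depth / lambda_ang).
    """
    residues = np.array([lab.site for lab in labels])
    z = np.array([lab.mean_position[2] for lab in labels])
    depth = np.asarray(membrane_depth(z, frame))
    phi = phi_max * np.tanh(depth / lambda_ang)
    return DepthProfile(residue_index=residues, depth_ang=depth, phi=phi)


def profile_correlation(a: dict[int, float], b: dict[int, float]) -> float:
    """Pearson correlation of two per-residue tracks over shared residues."""
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared residues, have {len(shared)}")
    x = np.array([a[r] for r in shared], dtype=float)
    y = np.array([b[r] for r in shared], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a track has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def read_distance_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an experimental DEER table: TSV ``distance_ang<TAB>density``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return df["distance_ang"].to_numpy(float), df["density"].to_numpy(float)


def write_distance_table(dist: DistanceDistribution, path) -> None:
    import pandas as pd

    pd.DataFrame({"distance_ang": dist.grid, "density": dist.density}).to_csv(
        path, sep="\t", index=False
    )
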
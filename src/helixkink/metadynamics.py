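"""Desk-scale metadynamics on a 2D periodic dihedral collective-variable space.

An overdamped Langevin walker explores an analytic potential U(cv1, cv2) on
the torus (degrees); repulsive Gaussian hills are deposited at the walker
position at a fixed interval, and the free-energy surface is estimated as
the negated accumulated bias (standard non-well-tempered estimator),
averaged over the final fraction of the deposition history to damp the
sawtooth oscillation of the filled surface.

This is a toy sampling engine for method validation against analytic
potentials with known minima and barriers — it replaces the role an
all-atom MD engine plays in production metadynamics, and physical time is
nominal (one walker step per ``dt``).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import wrap_deg

__all__ = [
    "HillRecord",
    "HillHistory",
    "FreeEnergySurface",
    "LangevinParams",
    "StabilityError",
    "bias_potential",
    "run_metadynamics",
    "reconstruct_fes",
    "fes_minima_and_barrier",
    "fes_difference",
    "read_hills",
    "write_hills",
]

DEFAULT_HILL_HEIGHT = 0.01  # kcal/mol per deposition
DEFAULT_HILL_SIGMA = np.degrees(0.3)  # 0.3 rad ~ 17.2 deg
DEFAULT_DEPOSITION_INTERVAL = 150  # walker steps between hills


class StabilityError(RuntimeError):
    """The walker moved implausibly far in one step; reduce dt."""


@dataclass(frozen=True)
class HillRecord:
    time: int  # walker step at deposition
    center: tuple[float, float]  # (cv1, cv2) degrees, wrapped
    width_sigma: float  # degrees
    height: float  # kcal/mol

    def __post_init__(self):
        if self.width_sigma <= 0:
            raise ValueError("hill width must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")
        c = (wrap_deg(self.center[0]), wrap_deg(self.center[1]))
        object.__setattr__(self, "center", c)


class HillHistory:
    """Time-ordered hill depositions plus the sampling-window metadata."""

    def __init__(
        self,
        hills: list[HillRecord],
        deposition_interval: int = DEFAULT_DEPOSITION_INTERVAL,
        cv_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    ):
        times = [h.time for h in hills]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("hill times must be strictly increasing")
        self.hills = list(hills)
        self.deposition_interval = deposition_interval
        self.cv_bounds = cv_bounds

    def __len__(self) -> int:
        return len(self.hills)

    def arrays(self):
        """(centers (n,2), sigmas (n,), heights (n,)) as float arrays."""
        if not self.hills:
            return np.empty((0, 2)), np.empty(0), np.empty(0)
        centers = np.array([h.center for h in self.hills], dtype=float)
        sigmas = np.array([h.width_sigma for h in self.hills], dtype=float)
        heights = np.array([h.height for h in self.hills], dtype=float)
        return centers, sigmas, heights


def _min_image(delta: np.ndarray) -> np.ndarray:
    """Minimum-image angular difference on a 360-degree period."""
    return delta - 360.0 * np.round(delta / 360.0)


def bias_potential(history: HillHistory, point, hill_weights: np.ndarray | None = None) -> float:
    """Accumulated bias V(s) = sum_h h * exp(-(d1^2 + d2^2) / (2 sigma^2)),
    with minimum-image angular differences."""
    centers, sigmas, heights = history.arrays()
    if len(centers) == 0:
        return 0.0
    if hill_weights is not None:
        heights = heights * hill_weights
    d1 = _min_image(point[0] - centers[:, 0])
    d2 = _min_image(point[1] - centers[:, 1])
    return float(np.sum(heights * np.exp(-(d1**2 + d2**2) / (2.0 * sigmas**2))))


# V = h exp(-(d1^2+d2^2)/2s^2)  =>  dV/dcv1 = -h exp(..) d1 / s^2
def _bias_grad(centers, sigmas, heights, point) -> np.ndarray:
    if len(centers) == 0:
        return np.zeros(2)
    d1 = _min_image(point[0] - centers[:, 0])
    d2 = _min_image(point[1] - centers[:, 1])
    common = heights * np.exp(-(d1**2 + d2**2) / (2.0 * sigmas**2)) / sigmas**2
    return np.array([-np.sum(common * d1), -np.sum(common * d2)])


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped-walker parameters: all positive, seed fixed per run."""

    kT: float = 0.5961  # kcal/mol at 300 K
    friction: float = 1.0  # 1/steps
    dt: float = 1.0  # step size
    seed: int = 0

    def __post_init__(self):
        if self.kT <= 0 or self.friction <= 0 or self.dt <= 0:
            raise ValueError("kT, friction and dt must all be positive")


def _numerical_gradient(potential, point, h=1e-4) -> np.ndarray:
    x, y = point
    return np.array(
        [
            (potential(x + h, y) - potential(x - h, y)) / (2 * h),
            (potential(x, y + h) - potential(x, y - h)) / (2 * h),
        ]
    )


def run_metadynamics(
    potential,
    hill_height: float = DEFAULT_HILL_HEIGHT,
    hill_sigma: float = DEFAULT_HILL_SIGMA,
    deposition_interval: int = DEFAULT_DEPOSITION_INTERVAL,
    n_steps: int = 100_000,
    langevin: LangevinParams = LangevinParams(),
    start: tuple[float, float] = (0.0, 0.0),
    cv_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    return_trajectory: bool = False,
):
    """Run a biased overdamped Langevin walker and return its hill history.

    The walker follows s <- s - (grad U + grad V_bias) dt/gamma
    + sqrt(2 kT dt/gamma) xi, wrapping periodically (or reflecting at
    ``cv_bounds`` when a sampling window is set).  A hill is dropped at the
    walker position every ``deposition_interval`` steps.  Setting
    ``hill_height=0`` gives an unbiased equilibrium sampler.
    Bit-reproducible for a fixed seed.
    """
    if hill_sigma <= 0 or deposition_interval <= 0 or n_steps <= 0:
        raise ValueError("hill sigma, deposition interval and n_steps must be positive")
    if hill_height < 0:
        raise ValueError("hill height must be non-negative")
    grad_u = getattr(potential, "gradient", None)
    if grad_u is None:
        grad_u = lambda x, y: _numerical_gradient(potential, (x, y))  # noqa: E731

    rng = np.random.default_rng(langevin.seed)
    mobility = langevin.dt / langevin.friction
    noise_scale = np.sqrt(2.0 * langevin.kT * langevin.dt / langevin.friction)

    s = np.array(start, dtype=float)
    centers: list[tuple[float, float]] = []
    c_arr = np.empty((0, 2))
    sig_arr = np.empty(0)
    h_arr = np.empty(0)
    hills: list[HillRecord] = []
    traj_list: list[np.ndarray] = []

    for step in range(1, n_steps + 1):
        force = -(np.asarray(grad_u(s[0], s[1]), dtype=float) + _bias_grad(c_arr, sig_arr, h_arr, s))
        ds = force * mobility + noise_scale * rng.standard_normal(2)
        if np.any(np.abs(ds) > 90.0):
            raise StabilityError(
                f"walker step of {np.abs(ds).max():.1f} deg at step {step}; reduce dt"
            )
        s = s + ds
        if cv_bounds is not None:
            for i, (lo, hi) in enumerate(cv_bounds):
                # reflect into the sampling window
                width = hi - lo
                val = (s[i] - lo) % (2 * width)
                s[i] = lo + (val if val <= width else 2 * width - val)
        else:
            s = wrap_deg(s)
        if step % deposition_interval == 0 and hill_height > 0:
            hills.append(
                HillRecord(time=step, center=(s[0], s[1]), width_sigma=hill_sigma, height=hill_height)
            )
            centers.append((s[0], s[1]))
            c_arr = np.array(centers)
            sig_arr = np.full(len(centers), hill_sigma)
            h_arr = np.full(len(centers), hill_height)
        if return_trajectory:
            traj_list.append(s.copy())

    history = HillHistory(hills, deposition_interval=deposition_interval, cv_bounds=cv_bounds)
    if return_trajectory:
        return history, np.array(traj_list)
    return history


# ---------------------------------------------------------------------------
# FES reconstruction and analysis
# ---------------------------------------------------------------------------

class FreeEnergySurface:
    """2D free-energy surface on uniform degree grids, min-shifted to zero."""

    def __init__(self, grid1: np.ndarray, grid2: np.ndarray, f: np.ndarray, periodic: bool = True):
        self.grid1 = np.asarray(grid1, dtype=float)
        self.grid2 = np.asarray(grid2, dtype=float)
        f = np.asarray(f, dtype=float)
        if f.shape != (len(self.grid1), len(self.grid2)):
            raise ValueError("f must have shape (len(grid1), len(grid2))")
        if not np.all(np.isfinite(f)):
            raise ValueError("free-energy values must be finite")
        self.f = f - f.min()
        self.periodic = periodic

    def value_at(self, cv1: float, cv2: float) -> float:
        i = int(np.argmin(np.abs(_min_image(self.grid1 - cv1))))
        j = int(np.argmin(np.abs(_min_image(self.grid2 - cv2))))
        return float(self.f[i, j])

    def to_frame(self):
        import pandas as pd

        g1, g2 = np.meshgrid(self.grid1, self.grid2, indexing="ij")
        return pd.DataFrame(
            {"cv1_deg": g1.ravel(), "cv2_deg": g2.ravel(), "free_energy_kcal": self.f.ravel()}
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(self.grid1, self.grid2, self.f.T, shading="nearest", **kwargs)
        ax.set_xlabel("cv1 (deg)")
        ax.set_ylabel("cv2 (deg)")
        plt.colorbar(im, ax=ax, label="F (kcal/mol)")
        return ax


def reconstruct_fes(
    history: HillHistory,
    grid1: np.ndarray | None = None,
    grid2: np.ndarray | None = None,
    average_fraction: float = 0.2,
) -> FreeEnergySurface:
    """F = -V_bias on the grid, min-shifted to zero.

    With ``average_fraction`` > 0 the estimate is the average of -V over the
    bias states at each deposition in the final fraction of the history,
    which damps the hill-by-hill sawtooth; equivalently each hill j
    contributes with weight (#checkpoints >= j) / #checkpoints.
    """
    if grid1 is None:
        grid1 = np.arange(-180.0, 180.0, 4.0)
    if grid2 is None:
        grid2 = np.arange(-180.0, 180.0, 4.0)
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    if grid1.size == 0 or grid2.size == 0:
        raise ValueError("grids must be non-empty")
    centers, sigmas, heights = history.arrays()
    n = len(centers)
    v = np.zeros((len(grid1), len(grid2)))
    if n:
        if average_fraction > 0:
            first_ckpt = int(np.ceil((1.0 - average_fraction) * n))
            first_ckpt = min(first_ckpt, n - 1)
            n_ckpt = n - first_ckpt
            hill_idx = np.arange(n)
            weights = (n - np.maximum(hill_idx, first_ckpt)) / n_ckpt
        else:
            weights = np.ones(n)
        # hills are separable in the two CVs: accumulate outer products
        for c, s_, h in zip(centers, sigmas, heights * weights):
            gx = np.exp(-(_min_image(grid1 - c[0]) ** 2) / (2.0 * s_**2))
            gy = np.exp(-(_min_image(grid2 - c[1]) ** 2) / (2.0 * s_**2))
            v += h * np.outer(gx, gy)
    return FreeEnergySurface(grid1, grid2, -v, periodic=history.cv_bounds is None)


def _descend(fes: FreeEnergySurface, start_idx: tuple[int, int]) -> tuple[int, int]:
    """Steepest-descent walk on the 8-connected grid to the local minimum."""
    n1, n2 = fes.f.shape
    cur = start_idx
    while True:
        best = cur
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                i, j = cur[0] + di, cur[1] + dj
                if fes.periodic:
                    i, j = i % n1, j % n2
                elif not (0 <= i < n1 and 0 <= j < n2):
                    continue
                if fes.f[i, j] < fes.f[best]:
                    best = (i, j)
        if best == cur:
            return cur
        cur = best


def _nearest_index(fes: FreeEnergySurface, point) -> tuple[int, int]:
    i = int(np.argmin(np.abs(_min_image(fes.grid1 - point[0]))))
    j = int(np.argmin(np.abs(_min_image(fes.grid2 - point[1]))))
    return i, j


def fes_minima_and_barrier(fes: FreeEnergySurface, basin_seeds) -> dict:
    """Locate the local minima nearest two basin seeds and the barrier between them.

    The barrier is computed by a monotone flood (widest/minimax path) on the
    8-connected grid: the smallest possible maximum F along any grid path
    from one minimum to the other, minus F at the starting minimum.
    """
    seed_a, seed_b = basin_seeds
    min_a = _descend(fes, _nearest_index(fes, seed_a))
    min_b = _descend(fes, _nearest_index(fes, seed_b))
    f = fes.f
    minima = [
        ((float(fes.grid1[min_a[0]]), float(fes.grid2[min_a[1]])), float(f[min_a])),
        ((float(fes.grid1[min_b[0]]), float(fes.grid2[min_b[1]])), float(f[min_b])),
    ]
    if min_a == min_b:
        warnings.warn("both seeds descend to the same basin; barrier is 0", stacklevel=2)
        return {"minima": minima, "barrier": 0.0}

    n1, n2 = f.shape
    best = np.full((n1, n2), np.inf)
    best[min_a] = f[min_a]
    heap = [(f[min_a], min_a)]
    while heap:
        val, (i, j) = heapq.heappop(heap)
        if val > best[i, j]:
            continue
        if (i, j) == min_b:
            break
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if fes.periodic:
                    ni, nj = ni % n1, nj % n2
                elif not (0 <= ni < n1 and 0 <= nj < n2):
                    continue
                cand = max(val, f[ni, nj])
                if cand < best[ni, nj]:
                    best[ni, nj] = cand
                    heapq.heappush(heap, (cand, (ni, nj)))
    barrier = float(best[min_b] - f[min_a])
    return {"minima": minima, "barrier": barrier}


def fes_difference(a: FreeEnergySurface, b: FreeEnergySurface) -> np.ndarray:
    """Element-wise difference of two min-shifted surfaces on identical grids."""
    if not (np.array_equal(a.grid1, b.grid1) and np.array_equal(a.grid2, b.grid2)):
        raise ValueError("surfaces must share identical grids")
    return a.f - b.f


# ---------------------------------------------------------------------------
# HILLS file I/O (PLUMED-style text)
# ---------------------------------------------------------------------------

HILLS_HEADER = "#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height"


def write_hills(history: HillHistory, path) -> None:
    with open(path, "w") as fh:
        fh.write(HILLS_HEADER + "\n")
        for h in history.hills:
            fh.write(
                f"{h.time} {h.center[0]:.6f} {h.center[1]:.6f} "
                f"{h.width_sigma:.6f} {h.width_sigma:.6f} {h.height:.6f}\n"
            )


def read_hills(path) -> HillHistory:
    hills: list[HillRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t, c1, c2, s1, s2, h = line.split()[:6]
            if abs(float(s1) - float(s2)) > 1e-9:
                raise ValueError("anisotropic hill widths are not supported")
            hills.append(
                HillRecord(
                    time=int(float(t)),
                    center=(float(c1), float(c2)),
                    width_sigma=float(s1),
                    height=float(h),
                )
            )
    times = np.array([h.time for h in hills])
    interval = int(np.min(np.diff(times))) if len(times) > 1 else DEFAULT_DEPOSITION_INTERVAL
    return HillHistory(hills, deposition_interval=interval)
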
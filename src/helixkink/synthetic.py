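"""Synthetic inputs for every pipeline stage.

Builds ideal and hinge-kinked alpha-helices by sequential internal-coordinate
(NeRF) construction, noisy dihedral ensembles, implicit-membrane water boxes,
RDC sets planted from a known alignment tensor, and analytic 2D periodic toy
potentials with closed-form minima and barriers.

The default sequence mirrors the amyloid-precursor-protein fragment 686-728
(695-isoform author numbering), so the hinge glycines 708/709, the GxxxG
motif residues 700/704/708 and the spin-label sites 700/723 all resolve at
their literature indices.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Atom, Conformation, MembraneFrame, StructureEnsemble
from .geometry import bend_angle, dihedral, wrap_deg
from .hydration import WaterSet
from .rdc import AlignmentTensor, RDCRecord, nh_vectors, reconstruct_amide_h

__all__ = [
    "APP_SEQUENCE_686_728",
    "HelixSpec",
    "KinkSpec",
    "KinkError",
    "ToyPotential",
    "build_ideal_helix",
    "build_kinked_helix",
    "build_helix_from_torsions",
    "measure_backbone_torsions",
    "sample_ensemble",
    "make_membrane_and_waters",
    "synth_rdc",
    "random_tensor",
    "toy_potential",
]

# APP 695-isoform numbering, residues 686-728 (juxtamembrane + TM + anchor)
APP_SEQUENCE_686_728 = (
    "GLN LYS LEU VAL PHE PHE ALA GLU ASP VAL GLY SER ASN LYS GLY ALA ILE ILE "
    "GLY LEU MET VAL GLY GLY VAL VAL ILE ALA THR VAL ILE VAL ILE THR LEU VAL "
    "MET LEU LYS LYS LYS GLN TYR"
).split()


class KinkError(RuntimeError):
    """The kink builder could not bracket the requested bend angle."""


@dataclass(frozen=True)
class HelixSpec:
    """Backbone geometry for the internal-coordinate helix builder.

    Default torsions (phi -57, psi -47) are canonical right-handed
    alpha-helix values; bond lengths/angles are standard peptide geometry.
    """

    sequence: tuple[str, ...] = tuple(APP_SEQUENCE_686_728)
    start_index: int = 686
    phi_deg: float = -57.0
    psi_deg: float = -47.0
    omega_deg: float = 180.0
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.5
    include_amide_h: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for v in (self.bond_n_ca, self.bond_ca_c, self.bond_c_n, self.angle_n_ca_c):
            if v <= 0:
                raise ValueError("bond lengths and angles must be positive")


@dataclass(frozen=True)
class KinkSpec:
    """Hinge kink request: bend amplitude and azimuthal swivel direction."""

    hinge_residue: int = 709
    target_bend_deg: float = 30.0
    swivel_deg: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.target_bend_deg <= 90.0):
            raise ValueError("target bend must lie in [0, 90] degrees")


# ---------------------------------------------------------------------------
# NeRF construction
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A-B-C given internal coordinates
    (|C-D|, angle(B,C,D), torsion(A,B,C,D))."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_helix_from_torsions(
    phis: np.ndarray, psis: np.ndarray, spec: HelixSpec = HelixSpec()
) -> Conformation:
    """Build a backbone (N, CA, C, O, optional amide H) from per-residue
    phi/psi arrays with ideal bond geometry and trans peptide bonds."""
    n_res = len(spec.sequence)
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    if phis.shape != (n_res,) or psis.shape != (n_res,):
        raise ValueError("phi/psi arrays must have one entry per residue")

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed the first residue in an arbitrary frame
    N[0] = np.zeros(3)
    CA[0] = np.array([spec.bond_n_ca, 0.0, 0.0])
    ang = np.radians(spec.angle_n_ca_c)
    C[0] = CA[0] + spec.bond_ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], spec.bond_c_n, spec.angle_ca_c_n, psis[i])
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], spec.bond_n_ca, spec.angle_c_n_ca, spec.omega_deg)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], spec.bond_ca_c, spec.angle_n_ca_c, phis[i + 1])

    atoms: list[Atom] = []
    for i, resname in enumerate(spec.sequence):
        idx = spec.start_index + i
        atoms.append(Atom("N", "N", idx, resname, N[i]))
        if spec.include_amide_h and i > 0 and resname != "PRO":
            atoms.append(Atom("H", "H", idx, resname, reconstruct_amide_h(N[i], CA[i], C[i - 1])))
        atoms.append(Atom("CA", "C", idx, resname, CA[i]))
        atoms.append(Atom("C", "C", idx, resname, C[i]))
        # carbonyl O opposite the next amide (psi + 180)
        o = _place_atom(N[i], CA[i], C[i], spec.bond_c_o, spec.angle_ca_c_o, psis[i] + 180.0)
        atoms.append(Atom("O", "O", idx, resname, o))
    return Conformation(atoms, label="built")


def build_ideal_helix(spec: HelixSpec = HelixSpec()) -> Conformation:
    """Straight ideal alpha-helix with uniform backbone torsions."""
    n = len(spec.sequence)
    return build_helix_from_torsions(np.full(n, spec.phi_deg), np.full(n, spec.psi_deg), spec)


def measure_backbone_torsions(conf: Conformation, spec: HelixSpec = HelixSpec()):
    """Per-residue (phi, psi) measured from coordinates; undefined terminal
    torsions fall back to the spec defaults."""
    residues = conf.residue_indices()
    n = len(residues)
    phis = np.full(n, spec.phi_deg)
    psis = np.full(n, spec.psi_deg)
    for i, r in enumerate(residues):
        if i > 0:
            phis[i] = dihedral(
                conf.atom_coords(residues[i - 1], "C"),
                conf.atom_coords(r, "N"),
                conf.atom_coords(r, "CA"),
                conf.atom_coords(r, "C"),
            )
        if i < n - 1:
            psis[i] = dihedral(
                conf.atom_coords(r, "N"),
                conf.atom_coords(r, "CA"),
                conf.atom_coords(r, "C"),
                conf.atom_coords(residues[i + 1], "N"),
            )
    return phis, psis


def build_kinked_helix(
    spec: HelixSpec = HelixSpec(),
    kink: KinkSpec = KinkSpec(),
    segment_n: tuple[int, int] = (700, 708),
    segment_c: tuple[int, int] = (710, 723),
    tolerance_deg: float = 0.5,
) -> Conformation:
    """Hinge-kinked helix whose measured bend matches the request within 1 deg.

    The kink is induced by perturbing the hinge residue's psi (and, for the
    swivel, phi) torsions — chemistry stays ideal — and the perturbation
    amplitude is found by bisection against the measured inter-segment bend.
    """
    n = len(spec.sequence)
    hinge_pos = kink.hinge_residue - spec.start_index
    if not (0 < hinge_pos < n - 1):
        raise ValueError(f"hinge residue {kink.hinge_residue} outside the sequence")
    base_phis = np.full(n, spec.phi_deg)
    base_psis = np.full(n, spec.psi_deg)
    if kink.target_bend_deg == 0.0:
        return build_helix_from_torsions(base_phis, base_psis, spec)

    sw = np.radians(kink.swivel_deg)

    def build(amplitude: float) -> Conformation:
        phis = base_phis.copy()
        psis = base_psis.copy()
        phis[hinge_pos] += amplitude * np.sin(sw)
        psis[hinge_pos] += amplitude * np.cos(sw)
        return build_helix_from_torsions(phis, psis, spec)

    def measured(amplitude: float) -> float:
        return bend_angle(build(amplitude), segment_n, segment_c).bend_deg

    lo, hi = 0.0, 10.0
    f_lo = measured(lo)
    while measured(hi) < kink.target_bend_deg:
        hi += 15.0
        if hi > 170.0:
            raise KinkError(
                f"could not bracket a {kink.target_bend_deg} deg bend at swivel {kink.swivel_deg}"
            )
    if f_lo > kink.target_bend_deg:
        raise KinkError("straight helix already exceeds the requested bend")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if measured(mid) < kink.target_bend_deg:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    amplitude = 0.5 * (lo + hi)
    conf = build(amplitude)
    if abs(bend_angle(conf, segment_n, segment_c).bend_deg - kink.target_bend_deg) > tolerance_deg:
        raise KinkError("bisection converged outside tolerance")
    return conf


def sample_ensemble(
    base: Conformation,
    n: int,
    dihedral_noise_deg: float,
    seed: int = 0,
    spec: HelixSpec = HelixSpec(),
) -> StructureEnsemble:
    """Rebuild the base backbone ``n`` times with independent Gaussian
    perturbations on every phi/psi torsion (seeded, reproducible)."""
    if n < 1 or dihedral_noise_deg < 0:
        raise ValueError("need n >= 1 and non-negative noise")
    phis, psis = measure_backbone_torsions(base, spec)
    rng = np.random.default_rng(seed)
    members = []
    for i in range(n):
        dphi = rng.normal(0.0, dihedral_noise_deg, size=len(phis))
        dpsi = rng.normal(0.0, dihedral_noise_deg, size=len(psis))
        conf = build_helix_from_torsions(phis + dphi, psis + dpsi, spec)
        members.append(Conformation(conf.atoms, label=str(i + 1)))
    return StructureEnsemble(members)


# ---------------------------------------------------------------------------
# Waters
# ---------------------------------------------------------------------------

def make_membrane_and_waters(
    conf: Conformation,
    frame: MembraneFrame,
    density: float = 0.01,
    n_frames: int = 1,
    seed: int = 0,
    padding: float = 15.0,
) -> WaterSet:
    """Scatter water oxygens uniformly outside the membrane slab.

    The box is the protein bounding box plus ``padding`` on every side;
    waters falling between the phosphate planes are rejected, so each
    frame's count is Poisson with mean density x (box volume outside the
    slab).  Frames are independent and seeded.
    """
    if density <= 0:
        raise ValueError("water density must be positive")
    xyz = conf.coords
    lo = xyz.min(axis=0) - padding
    hi = xyz.max(axis=0) + padding
    lo[2] = min(lo[2], frame.z_phosphate_lower - padding)
    hi[2] = max(hi[2], frame.z_phosphate_upper + padding)
    volume = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        count = rng.poisson(density * volume)
        pts = lo + rng.random((count, 3)) * (hi - lo)
        inside_slab = (pts[:, 2] > frame.z_phosphate_lower) & (pts[:, 2] < frame.z_phosphate_upper)
        frames.append(pts[~inside_slab])
    return WaterSet(frames)


# ---------------------------------------------------------------------------
# Synthetic RDCs
# ---------------------------------------------------------------------------

def random_tensor(seed: int = 0, scale: float = 1.0) -> AlignmentTensor:
    """Random symmetric traceless Saupe tensor (5 Gaussian components)."""
    rng = np.random.default_rng(seed)
    return AlignmentTensor.from_s5(rng.normal(0.0, scale, size=5))


def synth_rdc(
    confs: Conformation | list[Conformation],
    tensor: AlignmentTensor | None = None,
    mixture_weights=None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[RDCRecord], dict]:
    """Couplings planted from a known tensor on one or more conformers.

    d_r = sum_c w_c (v_cr^T S v_cr) + Gaussian noise, over residues whose
    N-H vector exists in every conformer.  The ground-truth tensor and
    mixture weights are returned alongside, so recovery tests never rely on
    hidden state.
    """
    if isinstance(confs, Conformation):
        confs = [confs]
    if tensor is None:
        tensor = random_tensor(seed)
    if mixture_weights is None:
        mixture_weights = np.full(len(confs), 1.0 / len(confs))
    w = np.asarray(mixture_weights, dtype=float)
    if w.shape != (len(confs),) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1, one per conformer")
    vec_sets = [nh_vectors(c) for c in confs]
    shared = sorted(set.intersection(*(set(v) for v in vec_sets)))
    rng = np.random.default_rng(seed)
    S = tensor.saupe
    records = []
    for r in shared:
        d = sum(wi * float(v[r] @ S @ v[r]) for wi, v in zip(w, vec_sets))
        if noise_sigma > 0:
            d += rng.normal(0.0, noise_sigma)
        records.append(RDCRecord(r, d))
    truth = {"tensor": tensor, "weights": w, "noise_sigma": noise_sigma, "residues": shared}
    return records, truth


# ---------------------------------------------------------------------------
# Analytic toy potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyPotential:
    """Analytic 2D periodic potential with closed-form minima and barrier.

    ``minima`` is a list of ((cv1, cv2), U) pairs; ``delta_f`` is
    U(shallow) - U(deep); ``barrier`` is the saddle height above the deep
    minimum (None when undefined, e.g. a single well).
    """

    name: str
    params: dict
    minima: tuple
    delta_f: float | None
    barrier: float | None
    saddle_point: tuple[float, float] | None
    _u: callable = field(repr=False)
    _grad: callable = field(repr=False)

    def __call__(self, cv1, cv2):
        return self._u(cv1, cv2)

    def gradient(self, cv1, cv2):
        return self._grad(cv1, cv2)


_DEG = np.pi / 180.0


def toy_potential(name: str, **params) -> ToyPotential:
    """Construct a named analytic potential.

    ``harmonic``: periodic single well ``k (1 - cos(cv - center))`` in each CV.
    ``doublewell``: along cv1, f(theta) = a cos(theta) - b cos(2 theta) with
    theta = cv1 - shallow center: minima 180 deg apart, closed-form
    Delta F = 2a and deep-well barrier a^2/(8b) + a + 2b, with a transverse
    periodic confinement ``k_transverse (1 - cos(cv2 - center2))`` that
    vanishes along the minimum-energy path.  Parameterized directly by
    ``delta_f`` and ``barrier``.
    """
    if name == "harmonic":
        cx, cy = params.get("center", (0.0, 0.0))
        k = params.get("k", 1.0)

        def u(x, y):
            return k * (1 - np.cos((np.asarray(x) - cx) * _DEG)) + k * (
                1 - np.cos((np.asarray(y) - cy) * _DEG)
            )

        def grad(x, y):
            return np.array(
                [k * np.sin((x - cx) * _DEG) * _DEG, k * np.sin((y - cy) * _DEG) * _DEG]
            )

        return ToyPotential(
            name="harmonic",
            params={"center": (cx, cy), "k": k},
            minima=(((cx, cy), 0.0),),
            delta_f=None,
            barrier=None,
            saddle_point=None,
            _u=u,
            _grad=grad,
        )

    if name == "doublewell":
        delta_f = params.get("delta_f", 2.0)
        barrier = params.get("barrier", 5.0)
        deep = params.get("deep_center", (-40.0, -40.0))
        k_t = params.get("k_transverse", 2.0)
        a = delta_f / 2.0
        disc = (barrier - a) ** 2 - a**2
        if barrier <= delta_f or disc < 0:
            raise ValueError("barrier must exceed delta_f")
        b = ((barrier - a) + np.sqrt(disc)) / 4.0
        if a >= 4 * b:
            raise ValueError("degenerate double well: require a < 4b")
        x_deep, y0 = deep
        x_shallow = wrap_deg(x_deep + 180.0)
        # theta measured from the shallow well so the deep well sits at theta = pi
        def u(x, y):
            th = (np.asarray(x) - x_shallow) * _DEG
            ty = (np.asarray(y) - y0) * _DEG
            return a * np.cos(th) - b * np.cos(2 * th) + k_t * (1 - np.cos(ty))

        def grad(x, y):
            th = (x - x_shallow) * _DEG
            ty = (y - y0) * _DEG
            return np.array(
                [(-a * np.sin(th) + 2 * b * np.sin(2 * th)) * _DEG, k_t * np.sin(ty) * _DEG]
            )

        cos_saddle = a / (4.0 * b)
        theta_saddle = np.degrees(np.arccos(cos_saddle))
        u_deep = -a - b
        u_shallow = a - b
        u_saddle = a**2 / (8.0 * b) + b
        return ToyPotential(
            name="doublewell",
            params={
                "delta_f": delta_f,
                "barrier": barrier,
                "deep_center": deep,
                "a": a,
                "b": b,
                "k_transverse": k_t,
            },
            minima=(((x_deep, y0), u_deep), ((x_shallow, y0), u_shallow)),
            delta_f=float(u_shallow - u_deep),
            barrier=float(u_saddle - u_deep),
            saddle_point=(wrap_deg(x_shallow + theta_saddle), y0),
            _u=u,
            _grad=grad,
        )

    raise ValueError(f"unknown toy potential {name!r}; known: harmonic, doublewell")
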
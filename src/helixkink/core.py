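"""Multi-model structure containers, PDB I/O, and rigid-body superposition.

The basic currency of the package is the :class:`StructureEnsemble` — an
ordered set of conformations (NMR models or trajectory-style frames) sharing a
single topology.  Author residue numbering is preserved verbatim throughout;
for the amyloid-precursor-protein transmembrane fragment this means the
695-isoform numbering (hinge glycines 708/709, TM span 700-723).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Conformation",
    "StructureEnsemble",
    "MembraneFrame",
    "Selection",
    "TopologyError",
    "GeometryError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "superpose",
    "ensemble_rmsd_population",
]

_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


class TopologyError(ValueError):
    """Models in a multi-model file do not share one topology."""


class GeometryError(ValueError):
    """A geometric operation received degenerate or insufficient atoms."""


@dataclass(frozen=True)
class Atom:
    """A single atom with author residue numbering.

    ``coords`` are in Angstrom.  ``element`` may be empty when the source
    file omits it; it is then inferred from the first letter of the name.
    """

    name: str
    element: str
    residue_index: int
    residue_name: str
    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}/{self.residue_index}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            object.__setattr__(self, "element", self.name.lstrip("0123456789")[:1].upper())


class Conformation:
    """One model/frame: an ordered list of atoms plus fast lookup tables."""

    def __init__(self, atoms: list[Atom], label: str = ""):
        self.atoms = list(atoms)
        self.label = label
        self._index: dict[tuple[int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.residue_index, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {a.name} in residue {a.residue_index}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def residue_indices(self) -> list[int]:
        """Distinct residue indices in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, None)
        return list(seen)

    def residue_name(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        raise KeyError(residue_index)

    def get(self, residue_index: int, atom_name: str) -> Atom | None:
        i = self._index.get((residue_index, atom_name))
        return None if i is None else self.atoms[i]

    def atom_coords(self, residue_index: int, atom_name: str) -> np.ndarray:
        a = self.get(residue_index, atom_name)
        if a is None:
            raise GeometryError(f"missing atom {atom_name} in residue {residue_index}")
        return a.coords

    def residue_atoms(self, residue_index: int) -> list[Atom]:
        return [a for a in self.atoms if a.residue_index == residue_index]

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of all non-hydrogen atoms."""
        return np.array([a.coords for a in self.atoms if a.element != "H"])

    def topology_key(self) -> tuple:
        return tuple((a.residue_index, a.residue_name, a.name) for a in self.atoms)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Return a copy with coordinates mapped through x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            Atom(a.name, a.element, a.residue_index, a.residue_name, R @ a.coords + t)
            for a in self.atoms
        ]
        return Conformation(atoms, label=self.label)


def _topology_hash(conf: Conformation) -> str:
    h = hashlib.sha256()
    for res_idx, res_name, name in conf.topology_key():
        h.update(f"{res_idx}:{res_name}:{name};".encode())
    return h.hexdigest()


class StructureEnsemble:
    """Ordered conformations sharing one topology."""

    def __init__(self, members: list[Conformation]):
        if not members:
            raise ValueError("ensemble must contain at least one conformation")
        self.members = list(members)
        self.topology_hash = _topology_hash(members[0])
        for i, m in enumerate(self.members[1:], start=2):
            if _topology_hash(m) != self.topology_hash:
                raise TopologyError(f"model {i} (label {m.label!r}) does not match the topology of model 1")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return StructureEnsemble(self.members[i])
        return self.members[i]


@dataclass(frozen=True)
class MembraneFrame:
    """Implicit-bilayer reference frame: two phosphate planes about a center.

    The membrane normal is +z by convention.  Default half-thickness of 19 A
    (phosphate plane to bilayer center) is typical of a POPC bilayer.
    """

    z_phosphate_upper: float = 19.0
    z_phosphate_lower: float = -19.0
    z_center: float = 0.0
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("membrane normal must have unit length")
        object.__setattr__(self, "normal", n)
        if not (self.z_phosphate_lower < self.z_center < self.z_phosphate_upper):
            raise ValueError("require z_phosphate_lower < z_center < z_phosphate_upper")

    @property
    def half_thickness(self) -> float:
        return 0.5 * (self.z_phosphate_upper - self.z_phosphate_lower)


@dataclass(frozen=True)
class Selection:
    """Residue range plus atom-name filter, e.g. ``Selection(700, 723, ("N","CA","C"))``.

    The string form used in configs/CLI is ``"start-end:ATOM1,ATOM2"``; omit the
    atom list to keep every atom of the range.
    """

    start: int
    end: int
    atom_names: tuple[str, ...] | None = ("N", "CA", "C")

    @classmethod
    def parse(cls, text: str) -> "Selection":
        rng, _, names = text.partition(":")
        start_s, _, end_s = rng.partition("-")
        atom_names = tuple(n.strip() for n in names.split(",") if n.strip()) or None
        return cls(int(start_s), int(end_s), atom_names)

    def matches(self, atom: Atom) -> bool:
        if not (self.start <= atom.residue_index <= self.end):
            return False
        return self.atom_names is None or atom.name in self.atom_names

    def coords_from(self, conf: Conformation) -> np.ndarray:
        pts = [a.coords for a in conf.atoms if self.matches(a)]
        if not pts:
            raise GeometryError(f"selection {self.start}-{self.end} matched no atoms")
        return np.array(pts)


# ---------------------------------------------------------------------------
# PDB I/O (biotite does the parsing/formatting)
# ---------------------------------------------------------------------------

def _conformation_from_atom_array(arr: struc.AtomArray, label: str) -> tuple[Conformation, np.ndarray]:
    """Split a biotite AtomArray into a protein Conformation and water-O coordinates."""
    atoms: list[Atom] = []
    waters: list[np.ndarray] = []
    for i in range(arr.array_length()):
        resname = str(arr.res_name[i])
        if resname in _WATER_RESNAMES:
            if str(arr.atom_name[i]).startswith("O"):
                waters.append(np.array(arr.coord[i], dtype=float))
            continue
        if bool(arr.hetero[i]):
            continue  # non-water heteroatoms are out of scope
        atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_index=int(arr.res_id[i]),
                residue_name=resname,
                coords=np.array(arr.coord[i], dtype=float),
            )
        )
    return Conformation(atoms, label=label), (np.array(waters) if waters else np.empty((0, 3)))


def read_pdb_ensemble(path, return_waters: bool = False):
    """Read a (multi-)MODEL PDB file into a :class:`StructureEnsemble`.

    Alternate locations other than blank/'A' are dropped; water oxygens
    (HOH/WAT/TIP3/SOL) are split off and optionally returned per frame, other
    heteroatoms are ignored.  Author residue numbering is preserved.
    """
    try:
        pdb = PDBFile.read(str(path))
    except OSError:
        raise
    except Exception as exc:  # malformed content
        raise OSError(f"could not parse PDB file {path}: {exc}") from exc
    n_models = pdb.get_model_count()
    members: list[Conformation] = []
    water_frames: list[np.ndarray] = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, altloc="first")
        conf, waters = _conformation_from_atom_array(arr, label=str(m))
        members.append(conf)
        water_frames.append(waters)
    ensemble = StructureEnsemble(members)  # raises TopologyError naming the model
    if return_waters:
        from .hydration import WaterSet

        return ensemble, WaterSet(water_frames)
    return ensemble


def _atom_array_from_conformation(conf: Conformation) -> struc.AtomArray:
    n = len(conf)
    arr = struc.AtomArray(n)
    arr.coord = conf.coords
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.array([a.residue_index for a in conf.atoms])
    arr.res_name = np.array([a.residue_name for a in conf.atoms])
    arr.atom_name = np.array([a.name for a in conf.atoms])
    arr.element = np.array([a.element for a in conf.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb_ensemble(ensemble: StructureEnsemble, path) -> None:
    """Write a standard PDB with one MODEL/ENDMDL block per member."""
    if not isinstance(ensemble, StructureEnsemble):
        raise ValueError("write_pdb_ensemble requires a non-empty StructureEnsemble")
    arrays = [_atom_array_from_conformation(c) for c in ensemble]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    with open(path, "w") as fh:
        text = io.StringIO()
        pdb.write(text)
        fh.write(text.getvalue())


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _selection_pairs(mobile: Conformation, reference: Conformation, selection: Selection):
    names = selection.atom_names or None
    mob, ref = [], []
    for a in mobile.atoms:
        if selection.matches(a):
            b = reference.get(a.residue_index, a.name)
            if b is not None and (names is None or b.name in names):
                mob.append(a.coords)
                ref.append(b.coords)
    return np.array(mob), np.array(ref)


def superpose(mobile: Conformation, reference: Conformation, selection: Selection):
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that ``R @ x + t`` maps
    mobile atoms onto the reference frame; the RMSD is the minimum over all
    proper rigid motions for the selected atom pairs.
    """
    mob, ref = _selection_pairs(mobile, reference, selection)
    if len(mob) < 3:
        raise GeometryError(f"selection resolves to {len(mob)} atom pairs; need at least 3")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinear point sets leave a rotation degree of freedom undetermined
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("selected atoms are collinear; superposition is underdetermined")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    rmsd = float(rssd) / np.sqrt(len(mob))
    return R, t, rmsd


def ensemble_rmsd_population(
    ensemble: StructureEnsemble, reference: Conformation, selection: Selection
) -> tuple[float, float]:
    """Mean and population (divide-by-n) standard deviation of per-member RMSD."""
    rmsds = np.array([superpose(m, reference, selection)[2] for m in ensemble])
    return float(rmsds.mean()), float(rmsds.std(ddof=0))
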
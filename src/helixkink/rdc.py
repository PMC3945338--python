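"""Residual dipolar couplings: back-calculation, SVD tensor fit, genetic-algorithm
ensemble selection, and Jarvis-Patrick clustering of the selected conformers.

An RDC for a backbone N-H bond with unit vector v is, up to a global dipolar
prefactor, the bilinear form d = v^T S v with S the symmetric traceless 3x3
Saupe (alignment) order matrix.  The prefactor is folded into S throughout,
so couplings and tensor share whatever units the input table uses.

Fitting S to a set of (v, d_exp) pairs is a linear least-squares problem in
the five independent components of S, solved here by SVD.  Goodness of fit is
the Q factor, rms(d_calc - d_exp) / rms(d_exp).

When a single conformer cannot explain the couplings, a sub-ensemble is
selected from a conformer pool with a genetic algorithm: the fitness of a
candidate subset is the Q of one joint tensor fitted to the subset-averaged
design matrix (one alignment medium implies one tensor — the standard sparse
ensemble-selection formulation).  :class:`EnsembleRDCModel` packages this as
a model fitted to the experimental couplings; its :meth:`~EnsembleRDCModel.fit`
returns an :class:`EnsembleRDCResults` with the selection, tensor, Q and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import Conformation, GeometryError, Selection, StructureEnsemble, superpose

__all__ = [
    "RDCRecord",
    "AlignmentTensor",
    "FitError",
    "nh_vectors",
    "svd_fit_tensor",
    "backcalc_rdc",
    "q_factor",
    "EnsembleRDCModel",
    "EnsembleRDCResults",
    "ga_select_ensemble",
    "ClusterResult",
    "jarvis_patrick",
    "read_rdc_table",
    "write_rdc_table",
]

NH_BOND_LENGTH = 1.02  # Angstrom, amide N-H


class FitError(ValueError):
    """Alignment-tensor fit is underdetermined or otherwise impossible."""


@dataclass(frozen=True)
class RDCRecord:
    residue_index: int
    d_exp: float

    def __post_init__(self):
        if not np.isfinite(self.d_exp):
            raise ValueError(f"non-finite coupling for residue {self.residue_index}")


def read_rdc_table(path) -> list[RDCRecord]:
    """Read a TSV table with header ``residue<TAB>rdc``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [RDCRecord(int(r), float(d)) for r, d in zip(df["residue"], df["rdc"])]


def write_rdc_table(records: list[RDCRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"residue": [r.residue_index for r in records], "rdc": [r.d_exp for r in records]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment tensor
# ---------------------------------------------------------------------------

def _s5_to_matrix(s: np.ndarray) -> np.ndarray:
    """Expand the 5-vector (Syy, Szz, Sxy, Sxz, Syz) into the traceless matrix."""
    syy, szz, sxy, sxz, syz = s
    sxx = -syy - szz
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])


@dataclass(frozen=True)
class AlignmentTensor:
    """Symmetric traceless Saupe order matrix with derived axial/rhombic terms.

    ``da`` is half the principal value of largest magnitude; ``rhombicity``
    is (Sxx' - Syy') / (3 Da) with primes denoting the principal frame
    ordered |Sxx'| <= |Syy'| <= |Szz'|.
    """

    saupe: np.ndarray
    da: float = field(init=False)
    rhombicity: float = field(init=False)

    def __post_init__(self):
        m = np.asarray(self.saupe, dtype=float)
        if m.shape != (3, 3) or not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("Saupe matrix must be symmetric 3x3")
        if abs(np.trace(m)) > 1e-9 * max(1.0, np.abs(m).max()):
            raise ValueError("Saupe matrix must be traceless")
        object.__setattr__(self, "saupe", m)
        vals = np.linalg.eigvalsh(m)
        order = np.argsort(np.abs(vals))
        sxx, syy, szz = vals[order]
        da = szz / 2.0
        rh = (sxx - syy) / (3.0 * da) if da != 0 else 0.0
        object.__setattr__(self, "da", float(da))
        object.__setattr__(self, "rhombicity", float(rh))

    @classmethod
    def from_s5(cls, s: np.ndarray) -> "AlignmentTensor":
        return cls(_s5_to_matrix(np.asarray(s, dtype=float)))

    @property
    def s5(self) -> np.ndarray:
        m = self.saupe
        return np.array([m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])

    def principal_values(self) -> np.ndarray:
        vals = np.linalg.eigvalsh(self.saupe)
        return vals[np.argsort(np.abs(vals))]


def design_row(v: np.ndarray) -> np.ndarray:
    """Design-matrix row for one unit bond vector: d = row . s5."""
    vx, vy, vz = v
    return np.array([vy * vy - vx * vx, vz * vz - vx * vx, 2 * vx * vy, 2 * vx * vz, 2 * vy * vz])


# ---------------------------------------------------------------------------
# N-H vectors
# ---------------------------------------------------------------------------

def reconstruct_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Place the amide H in the peptide plane, opposite the bisector of
    N->C(prev) and N->CA, at 1.02 A from N."""
    u1 = (c_prev - n) / np.linalg.norm(c_prev - n)
    u2 = (ca - n) / np.linalg.norm(ca - n)
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    return n - NH_BOND_LENGTH * bis


def nh_vectors(conf: Conformation, strict: bool = False) -> dict[int, np.ndarray]:
    """Unit N-H bond vectors per residue.

    Uses the explicit amide H when present, otherwise reconstructs it from
    N, CA and the preceding carbonyl C.  The first residue (no preceding C)
    and prolines are skipped.  With ``strict=True`` any other residue that
    cannot yield a vector raises a :class:`~helixkink.core.GeometryError`
    listing it.
    """
    residues = conf.residue_indices()
    vectors: dict[int, np.ndarray] = {}
    failed: list[int] = []
    for pos, r in enumerate(residues):
        if pos == 0:
            continue  # no preceding carbonyl to define the peptide plane
        if conf.residue_name(r) == "PRO":
            continue
        n_atom = conf.get(r, "N")
        if n_atom is None:
            failed.append(r)
            continue
        h_atom = conf.get(r, "H") or conf.get(r, "HN")
        if h_atom is not None:
            v = h_atom.coords - n_atom.coords
        else:
            ca = conf.get(r, "CA")
            c_prev = conf.get(residues[pos - 1], "C")
            if ca is None or c_prev is None:
                failed.append(r)
                continue
            v = reconstruct_amide_h(n_atom.coords, ca.coords, c_prev.coords) - n_atom.coords
        vectors[r] = v / np.linalg.norm(v)
    if failed:
        if strict:
            raise GeometryError(f"could not build N-H vectors for residues {failed}")
        warnings.warn(f"skipped residues without N-H geometry: {failed}", stacklevel=2)
    return vectors


# ---------------------------------------------------------------------------
# Tensor fit / back-calculation / Q
# ---------------------------------------------------------------------------

def _design_matrix(vectors: dict[int, np.ndarray], records: list[RDCRecord]):
    usable = [r for r in records if r.residue_index in vectors]
    if len(usable) < 5:
        raise FitError(f"need >=5 usable (vector, coupling) pairs, have {len(usable)}")
    M = np.array([design_row(vectors[r.residue_index]) for r in usable])
    d = np.array([r.d_exp for r in usable])
    return M, d, usable


def svd_fit_tensor(vectors: dict[int, np.ndarray], records: list[RDCRecord]) -> AlignmentTensor:
    """Least-squares Saupe tensor mapping the bond vectors onto the couplings."""
    M, d, _ = _design_matrix(vectors, records)
    s, _, rank, _ = np.linalg.lstsq(M, d, rcond=None)
    if rank < 5:
        raise FitError(f"design matrix is rank-deficient (rank {rank} < 5)")
    return AlignmentTensor.from_s5(s)


def backcalc_rdc(tensor: AlignmentTensor, vectors: dict[int, np.ndarray]) -> dict[int, float]:
    """d_i = v_i^T S v_i for each residue's unit bond vector."""
    S = tensor.saupe
    return {r: float(v @ S @ v) for r, v in vectors.items()}


def q_factor(d_calc, d_exp) -> float:
    """Normalized rms misfit: sqrt(sum (d_calc - d_exp)^2) / sqrt(sum d_exp^2)."""
    a = np.asarray(d_calc, dtype=float)
    b = np.asarray(d_exp, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("d_calc and d_exp must be equally sized and non-empty")
    denom = np.sqrt(np.sum(b * b))
    if denom == 0:
        raise ValueError("Q factor undefined: experimental couplings are all zero")
    return float(np.sqrt(np.sum((a - b) ** 2)) / denom)


# ---------------------------------------------------------------------------
# GA ensemble selection (Model / Results)
# ---------------------------------------------------------------------------

@dataclass
class _GAParams:
    ensemble_size: int = 10
    population: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/pool per bit
    elitism: int = 1
    seed: int = 0

    def validate(self, pool_size: int):
        if not (1 <= self.ensemble_size <= pool_size):
            raise ValueError("require pool size >= ensemble_size >= 1")
        if self.population < 2 or self.generations < 1:
            raise ValueError("population must be >=2 and generations >=1")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must lie in [0, population)")


class EnsembleRDCModel:
    """Sparse ensemble selection against experimental RDCs.

    Parameters
    ----------
    pool
        Conformer pool (e.g. frames pulled from simulations).
    records
        Experimental couplings, one per residue.
    """

    def __init__(self, pool: StructureEnsemble, records: list[RDCRecord]):
        self.pool = pool
        self.records = list(records)
        # Residues usable in every pool member define the shared design space.
        vec0 = nh_vectors(pool[0])
        common = [r for r in self.records if r.residue_index in vec0]
        if len(common) < 5:
            raise FitError(f"need >=5 couplings with N-H geometry, have {len(common)}")
        self._records_used = common
        self.d_exp = np.array([r.d_exp for r in common])
        # per-member design matrices, shape (pool, n_res, 5)
        rows = []
        for conf in pool:
            vecs = nh_vectors(conf)
            missing = [r.residue_index for r in common if r.residue_index not in vecs]
            if missing:
                raise FitError(f"pool member {conf.label!r} lacks N-H vectors for residues {missing}")
            rows.append([design_row(vecs[r.residue_index]) for r in common])
        self._design = np.array(rows)

    # -- fitness ------------------------------------------------------------
    def subset_q(self, indices) -> tuple[float, AlignmentTensor, np.ndarray]:
        """Q of one joint tensor fitted to the subset-averaged design matrix."""
        M = self._design[np.asarray(indices)].mean(axis=0)
        s, _, rank, _ = np.linalg.lstsq(M, self.d_exp, rcond=None)
        if rank < 5:
            raise FitError(f"averaged design matrix is rank-deficient (rank {rank})")
        d_calc = M @ s
        return q_factor(d_calc, self.d_exp), AlignmentTensor.from_s5(s), d_calc

    def _q_only(self, indices) -> float:
        M = self._design[indices].mean(axis=0)
        s, *_ = np.linalg.lstsq(M, self.d_exp, rcond=None)
        return q_factor(M @ s, self.d_exp)

    # -- GA machinery --------------------------------------------------------
    @staticmethod
    def _repair(mask: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        on = np.flatnonzero(mask)
        off = np.flatnonzero(~mask)
        if len(on) > k:
            drop = rng.choice(on, size=len(on) - k, replace=False)
            mask[drop] = False
        elif len(on) < k:
            add = rng.choice(off, size=k - len(on), replace=False)
            mask[add] = True
        return mask

    def fit(
        self,
        ensemble_size: int = 10,
        population: int = 100,
        generations: int = 200,
        crossover_rate: float = 0.8,
        mutation_rate: float | None = None,
        elitism: int = 1,
        seed: int = 0,
    ) -> "EnsembleRDCResults":
        """Run the genetic algorithm and return the best subset ever seen.

        Binary-mask chromosomes constrained to a fixed subset size via
        repair; tournament selection (size 3), uniform crossover, per-bit
        mutation (default rate 1/pool), elitism.  Bit-reproducible for a
        fixed seed.
        """
        params = _GAParams(
            ensemble_size, population, generations, crossover_rate, mutation_rate, elitism, seed
        )
        n_pool = len(self.pool)
        params.validate(n_pool)
        k = params.ensemble_size
        p_mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / n_pool
        rng = np.random.default_rng(seed)

        pop = np.zeros((params.population, n_pool), dtype=bool)
        for i in range(params.population):
            pop[i, rng.choice(n_pool, size=k, replace=False)] = True

        def fitnesses(p):
            return np.array([self._q_only(np.flatnonzero(row)) for row in p])

        fit = fitnesses(pop)
        best_i = int(np.argmin(fit))
        best_mask, best_q = pop[best_i].copy(), float(fit[best_i])
        history = [best_q]

        for _ in range(params.generations):
            order = np.argsort(fit, kind="stable")
            new_pop = [pop[order[i]].copy() for i in range(params.elitism)]
            while len(new_pop) < params.population:
                # tournament selection, size 3
                parents = []
                for _ in range(2):
                    contenders = rng.integers(0, params.population, size=3)
                    parents.append(pop[contenders[np.argmin(fit[contenders])]].copy())
                a, b = parents
                if rng.random() < params.crossover_rate:
                    swap = rng.random(n_pool) < 0.5
                    a[swap], b[swap] = b[swap].copy(), a[swap].copy()
                for child in (a, b):
                    flip = rng.random(n_pool) < p_mut
                    child ^= flip
                    self._repair(child, k, rng)
                    if len(new_pop) < params.population:
                        new_pop.append(child)
            pop = np.array(new_pop)
            fit = fitnesses(pop)
            gen_best = int(np.argmin(fit))
            if fit[gen_best] < best_q:
                best_q = float(fit[gen_best])
                best_mask = pop[gen_best].copy()
            history.append(best_q)

        selected = np.flatnonzero(best_mask)
        q, tensor, d_calc = self.subset_q(selected)
        return EnsembleRDCResults(
            model=self,
            selected=selected,
            tensor=tensor,
            d_calc=d_calc,
            q=q,
            history=np.array(history),
            params=params,
        )


@dataclass
class EnsembleRDCResults:
    """Selection, joint alignment tensor and fit quality from the GA."""

    model: EnsembleRDCModel
    selected: np.ndarray
    tensor: AlignmentTensor
    d_calc: np.ndarray
    q: float
    history: np.ndarray
    params: _GAParams

    @property
    def q_factor(self) -> float:
        return self.q

    @property
    def residue_index(self) -> np.ndarray:
        return np.array([r.residue_index for r in self.model._records_used])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"residue": self.residue_index, "d_exp": self.model.d_exp, "d_calc": self.d_calc}
        )

    def summary(self) -> str:
        lines = [
            "Ensemble RDC selection (genetic algorithm)",
            "=" * 44,
            f"pool size:            {len(self.model.pool)}",
            f"ensemble size:        {len(self.selected)}",
            f"couplings used:       {len(self.d_calc)}",
            f"Q factor:             {self.q:.4f}",
            f"Da (coupling units):  {self.tensor.da:.4g}",
            f"rhombicity:           {self.tensor.rhombicity:.4f}",
            f"selected indices:     {list(map(int, self.selected))}",
            f"generations/pop/seed: {self.params.generations}/{self.params.population}/{self.params.seed}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Back-calculated vs experimental couplings."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.d_exp, self.d_calc, s=18)
        lo = min(self.model.d_exp.min(), self.d_calc.min())
        hi = max(self.model.d_exp.max(), self.d_calc.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_xlabel("experimental RDC")
        ax.set_ylabel("back-calculated RDC")
        ax.set_title(f"Q = {self.q:.3f}")
        return ax


def ga_select_ensemble(pool: StructureEnsemble, records: list[RDCRecord], params: dict | None = None):
    """Functional wrapper around :class:`EnsembleRDCModel` + :meth:`fit`."""
    return EnsembleRDCModel(pool, records).fit(**(params or {}))


# ---------------------------------------------------------------------------
# Jarvis-Patrick clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # -1 = singleton/noise
    k_neighbors: int
    k_min_shared: int

    def clusters(self) -> dict[int, np.ndarray]:
        return {
            int(c): np.flatnonzero(self.labels == c)
            for c in sorted(set(self.labels.tolist()))
            if c >= 0
        }


def _rmsd_matrix(conformers: StructureEnsemble, selection: Selection) -> np.ndarray:
    n = len(conformers)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = superpose(conformers[j], conformers[i], selection)[2]
    return D


def jarvis_patrick(
    conformers: StructureEnsemble | None,
    k_neighbors: int = 6,
    k_min_shared: int = 3,
    selection: Selection = Selection(700, 723, ("N", "CA", "C", "O")),
    distance_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Jarvis-Patrick clustering on superposed-backbone RMSD (or a given matrix).

    Two items join iff each lies in the other's k-nearest list and they share
    at least ``k_min_shared`` of their k nearest neighbors; clusters are the
    connected components of the join graph, with unjoined items labeled -1.
    Neighbor lists are tie-inclusive: every item at or below the k-th nearest
    distance is a neighbor, which makes the partition invariant to input
    order (and groups exactly coincident conformers together).
    """
    if k_min_shared > k_neighbors:
        raise ValueError("k_min_shared must not exceed k_neighbors")
    if distance_matrix is None:
        if conformers is None or len(conformers) < 2:
            raise ValueError("need at least 2 conformers")
        D = _rmsd_matrix(conformers, selection)
    else:
        D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors ({k_neighbors}) must be smaller than the pool size ({n})")

    neighbor_sets = []
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        dists = D[i, others]
        kth = np.sort(dists)[k_neighbors - 1]
        neighbor_sets.append(set(others[dists <= kth].tolist()))

    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            mutual = j in neighbor_sets[i] and i in neighbor_sets[j]
            if mutual and len(neighbor_sets[i] & neighbor_sets[j]) >= k_min_shared:
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)

    labels = np.full(n, -1, dtype=int)
    next_id = 0
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) >= 2:
            labels[members] = next_id
            next_id += 1
    return ClusterResult(labels=labels, k_neighbors=k_neighbors, k_min_shared=k_min_shared)
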
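# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package, stage by stage.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structures and superposition

Multi-model PDB files are read through biotite into an ordered
`StructureEnsemble` whose members must share one topology (a digest of the
`(residue_index, residue_name, atom_name)` sequence); the first model that
deviates is named in the error.  Author residue numbering is kept verbatim —
for the APP fragment this is the 695-isoform numbering (TM span 700–723,
hinge 708/709) — and no renumbering ever happens.  Alternate locations other
than blank/'A' are dropped; water oxygens (HOH/WAT/TIP3/SOL) are split into
a per-frame `WaterSet` for the hydration stage; other heteroatoms are
ignored.  Hydrogens are optional everywhere: stages that need the amide H
reconstruct it (below).

Superposition is the Kabsch least-squares rigid fit (via
`scipy.spatial.transform.Rotation.align_vectors`), guaranteed proper
(det = +1).  Selections of fewer than three atom pairs, or pairs whose
centered coordinates are rank-deficient (collinear), are rejected because
the rotation is then underdetermined.  Ensemble RMSD statistics use the
population (divide-by-n) standard deviation; this is a deliberate,
documented convention so that printed mean ± sd values are unambiguous.

## Helix geometry

A helix axis is the first principal component of sliding 4-residue means of
CA positions.  The window averages out the ~3.6-residue helical wobble that
would contaminate a raw-CA PCA; the sign is fixed so the axis points
N→C.  At least 5 CA atoms are required.

The hinge bend is the angle between the axes of the flanking segments,
defaulting to 700–708 and 710–723 (the TM span minus the hinge).  Both
printed conventions circulate in the literature, so `KinkGeometry` carries
both: `bend_deg` (0° = straight) and `axis_angle_deg = 180° − bend_deg`
(180° = straight), with the identity enforced exactly.

The two collective-variable dihedrals are the four-point torsions
N(708)–CA(708)–C(708)–N(709) and N(709)–CA(709)–C(709)–N(710) — the ψ
torsions of the two hinge glycines, which connect the three backbone
nitrogens across the hinge.  Torsions use the IUPAC sign convention (checked
against biotite during development; an α-helical ψ is ≈ −47°), wrapped to
(−180°, 180°].  Site indices are parameters.

Ensemble dihedral averages use circular means (atan2 of mean sine/cosine);
a resultant length below 1e-9 (uniformly opposed angles) is an error rather
than a silent garbage value.  Averages are computed over **all** models of
an ensemble.

## Hydration

A residue's hydration in a frame is the number of distinct water oxygens
within a cutoff of any of its heavy atoms (KD-tree accelerated; a water may
count toward several residues).  The default cutoff of 3.5 Å is the
conventional first-hydration-shell heavy-atom distance.  The "relative"
track divides by the profile maximum, giving a unitless 0–1 track that peaks
at the membrane-interface residues; it is a contact count, not an occupancy
or radial density.

## RDC ensemble selection

Couplings are modeled in reduced units: the dipolar prefactor is folded
into the Saupe tensor, so tensor components and the derived axial magnitude
`Da` share the units of the input couplings.  For a unit N–H vector
v = (vx, vy, vz) the coupling is the bilinear form `d = vᵀSv`, linear in the
five independent components `(Syy, Szz, Sxy, Sxz, Syz)` with design row
`[vy²−vx², vz²−vx², 2vxvy, 2vxvz, 2vyvz]`; the least-squares solution is
obtained by SVD and requires ≥5 usable couplings and a rank-5 design.
`Da` is half the principal value of largest magnitude and the rhombicity is
`(Sxx′ − Syy′)/(3Da)` in the ordered principal frame.

Missing amide hydrogens are rebuilt in the peptide plane, opposite the
bisector of N→C(prev) and N→CA at 1.02 Å — the standard planar-amide
construction; on ideal helix geometry the rebuilt vector deviates from an
explicit H by well under 5°.  The first residue (no preceding carbonyl) and
prolines are skipped.

Ensemble fitness for the genetic algorithm is the Q factor of **one joint
tensor** fitted to the subset-averaged design matrix (rows averaged over
members before solving).  One alignment medium implies one tensor; averaging
per-member tensors instead would let each conformer invent its own
alignment, which is the wrong model for a single sample.  GA defaults:
binary-mask chromosome repaired to a fixed subset size, tournament selection
of size 3, uniform crossover at rate 0.8, per-bit mutation 1/pool, elitism
1, population 100, generations 200.  All are parameters; runs are
bit-reproducible per seed, and the best individual ever seen is returned.

Jarvis–Patrick clustering joins two conformers iff each is in the other's
k-nearest list and they share at least `k_min_shared` of their k nearest
neighbors; clusters are connected components of the join graph and items
that join nothing are labeled −1.  Neighbor lists are **tie-inclusive**
(every item at or below the k-th nearest distance belongs to the list).
This makes the partition invariant to input order and gives the sensible
degenerate behavior that exactly coincident conformers cluster together —
an index-based tie-break would make the mutual-kNN relation asymmetric for
identical points.  Defaults k = 6, shared = 3, metric = backbone RMSD after
superposition on the TM range.

## Spin labels, DEER and depth profiles

The label model is a deliberately simple accessible-volume construction and
is labeled synthetic: N–O midpoint candidates are sampled in a 60° half-angle
cone about the CA→CB direction (CB rebuilt tetrahedrally for glycines) at a
Gaussian radial distance of 7 ± 1 Å — the typical CA-to-nitroxide reach of
an MTSL side chain — and candidates within 2.5 Å of any foreign heavy atom
are rejected.  With a membrane frame, surviving candidates are re-weighted
by `exp(depth/λ_bury)` with λ_bury = 5 Å, where depth is the signed distance
from the nearer phosphate plane, positive toward the bilayer center.  The
weight is monotone in depth, so the weighted ensemble is never shallower
than the unweighted one — encoding the burial preference of the hydrophobic
nitroxide, which is the qualitative mechanism that shortens apparent
inter-label distances in membranes.  This stand-in does not reproduce
rotamer-library predictions and is not intended to.

Distance distributions are weighted histograms of all cross pairs
(weight = w_a·w_b) on a 0–80 Å grid at 0.25 Å spacing (bracketing the
DEER-sensitive 18–60 Å window), Gaussian-smoothed with a 1.0 Å bandwidth and
renormalized to unit trapezoid area.  The reported mean/sd are weighted
moments of the **raw** pair distances, computed before smoothing, so the
kernel bandwidth never shifts them.

Boltzmann weights for conformers assigned to free-energy bins are
`w ∝ exp(−F/kT)` with k_B = 0.0019872 kcal mol⁻¹ K⁻¹, invariant to constant
surface shifts.

The depth parameter uses the calibration proxy `Φ = Φ_max·tanh(depth/λ)`
(defaults Φ_max = 5, λ = 10 Å): a monotone saturating map of distance from
the phosphate plane, which is the functional shape of power-saturation
calibrations; the true instrument calibration is sample-specific, so Φ
values here are comparable within a run, not against a spectrometer.

## Metadynamics engine

The walker is overdamped Langevin in the 2D periodic dihedral space
(degrees): `s ← s − (∇U + ∇V_bias)·dt/γ + sqrt(2·kT·dt/γ)·ξ`, wrapping on
the torus, or reflecting at the CV window when one is set.  Defaults
kT = 0.5961 kcal/mol (300 K), γ = 1 step⁻¹, dt = 20 — chosen so the per-step
thermal displacement (~5°) resolves 15°-scale features while diffusing
across the torus in a few thousand steps.  A per-step displacement above 90°
aborts with a stability error.  The engine replaces the all-atom MD walker
of production metadynamics; its "time" is nominal walker steps.

Hills are isotropic periodic Gaussians; the bias and its gradient use
minimum-image angular differences, so the bias is exactly 360°-periodic.
The literature hill settings for this CV pair are ambiguous about units
("width 0.3" with scaled colvars): the HILLS defaults interpret width 0.3
as radians (≈17.2°) and weight 0.01 as kcal/mol, and both are fully
configurable.  For desk-scale validation runs on the analytic double well
the package uses height 0.1 kcal/mol, σ = 15°, deposition every 50 steps and
2×10⁵ steps per seed: at 0.01 kcal/mol per hill, filling a 5 kcal/mol well
would need ~10⁷ steps, which serves no validation purpose.

The surface estimate is the standard non-well-tempered `F = −V_bias`,
averaged over the bias states at each deposition in the final 20% of the
history (equivalently, hill j is weighted by the fraction of checkpoints it
precedes), which damps the sawtooth of the filled surface; surfaces are
min-shifted to zero.  Minima are located by steepest descent on the
8-connected grid from user seeds; the barrier between two minima is the
minimax path value (monotone flood / widest path) minus the starting
minimum, which on a grid equals the saddle height up to one grid cell's
worth of F variation.

The analytic double well is built from `f(θ) = a·cosθ − b·cos2θ` along cv1
(θ measured from the shallow minimum) plus a transverse `k(1 − cos)`
confinement that vanishes along the minimum-energy path.  Minima sit 180°
apart with ΔF = 2a exactly, and the saddle height above the deep well is
`a²/8b + a + 2b`; the constructor inverts these relations so the potential
is parameterized directly by the planted ΔF and barrier.

## Synthetic generators

Helices are built by sequential internal-coordinate (NeRF) placement with
ideal peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles
111.2°, 116.2°, 121.7°; ω = 180°) and uniform φ = −57°, ψ = −47°.  The
default sequence is the APP 686–728 fragment with author numbering so every
literature site index resolves.  Kinks are induced by perturbing the hinge
residue's φ/ψ (the swivel angle distributes the perturbation between them)
with the amplitude found by bisection against the measured bend — chemistry
stays ideal, and the builder-measure loop closes within 1° for bends up to
65° at any swivel.  Ensembles rebuild the backbone with independent Gaussian
φ/ψ noise; waters are scattered uniformly outside the membrane slab
(half-thickness 19 Å, typical of a POPC bilayer) in the padded bounding box;
synthetic RDC sets always return their generating tensor and mixture
weights so recovery tests have no hidden state.  Every generator is a pure
function of (parameters, seed).

For the mixture-recovery validation (60:40 straight/bent couplings, 50+50
conformer pool, subset size 10) the within-class dihedral noise is σ = 2°
per torsion: accumulated over the ~20-residue C-terminal segment this
spreads member axes by roughly 10–15°, safely below the 30° bend separating
the classes, so class membership remains identifiable — with noise
comparable to the class separation the selection question itself becomes
ill-posed.

What the synthetic data does **not** emulate: side chains and rotamers,
real lipid packing, water structure and hydrogen-bond geometry,
force-field energetics, and correlated backbone motions.  Passing tests
therefore demonstrate correctness of the estimators and selection machinery
under planted truth, not that any particular real membrane system behaves
accordingly.

## Numerical choices and degenerate inputs

- Angle wrap is the half-open interval (−180°, 180°]; ±180° maps to +180°.
- Kink bisection tolerance 0.5° (reported closure tolerance 1°); bracket
  expansion capped at a 170° hinge perturbation.
- Q factor is undefined (error) for all-zero experimental couplings;
  circular means are undefined for uniformly opposed angles.
- All-zero hydration profiles return an all-zero relative track rather than
  dividing by zero.
- Distance grids that do not cover the pair-distance range are an error,
  not a silent truncation.
- The per-stage pipeline seeds derive from the global seed through
  `SeedSequence(global, spawn_key=(stage_index,))`, recorded in the run
  manifest; every derived seed is below 2³¹.

## Limitations

- The two published-ensemble geometry checks need the deposited PDB files
  (2LLM, 2LP1), which are not redistributable inside the repository; place
  them under `data/pdb/` to run those checks.
- The pseudo-label and depth calibration are proxies; absolute DEER
  distances and Φ values are not comparable to rotamer-library or
  instrument outputs.
- The metadynamics engine is non-well-tempered and single-walker; no
  reweighting estimators are provided.
- RDCs are N–H only; multi-medium joint fits and maximum-entropy ensemble
  weighting are out of scope.
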
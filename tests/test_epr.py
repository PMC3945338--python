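"""Pseudo-label placement, distance distributions, Boltzmann weights, depth."""

import numpy as np
import pytest

from helixkink.core import Atom, Conformation
from helixkink.epr import (
    DistanceDistribution,
    LabelEnsemble,
    PlacementError,
    boltzmann_weights,
    depth_profile,
    distance_distribution,
    membrane_depth,
    place_pseudo_label,
    profile_correlation,
    read_distance_table,
    write_distance_table,
)
from helixkink.metadynamics import FreeEnergySurface

KT300 = 0.0019872 * 300.0


def _bare_site(origin=(0.0, 0.0, 0.0)):
    """A single glycine-like residue with no neighbors."""
    o = np.asarray(origin, float)
    return Conformation(
        [
            Atom("N", "N", 1, "GLY", o + [-1.2, 0.8, 0.0]),
            Atom("CA", "C", 1, "GLY", o),
            Atom("C", "C", 1, "GLY", o + [1.3, 0.7, 0.0]),
        ]
    )


class TestLabelPlacement:
    def test_isolated_site_mean_radius(self):
        conf = _bare_site()
        lab = place_pseudo_label(conf, 1, n_samples=2000, seed=1)
        radii = np.linalg.norm(lab.positions - conf.atom_coords(1, "CA"), axis=1)
        assert np.average(radii, weights=lab.weights) == pytest.approx(7.0, abs=0.5)

    def test_total_clash_raises(self):
        conf = _bare_site()
        # enclose the site in a 2.0 A-spaced lattice of dummy heavy atoms:
        # every candidate position is within sqrt(3) A of a lattice point
        shell = []
        idx = 0
        ticks = np.arange(-18.0, 18.1, 2.0)
        for x in ticks:
            for y in ticks:
                for z in ticks:
                    r = np.linalg.norm([x, y, z])
                    if 2.5 < r < 17.0:
                        shell.append(Atom("O", "O", 100 + idx, "DUM", np.array([x, y, z])))
                        idx += 1
        walled = Conformation(conf.atoms + shell)
        with pytest.raises(PlacementError):
            place_pseudo_label(walled, 1, n_samples=300, clash_cutoff=2.5, seed=2)

    def test_burial_weighting_deepens_mean(self, membrane_frame):
        # site just above the upper phosphate plane, cone pointing down into the slab
        conf = _bare_site(origin=(0.0, 0.0, membrane_frame.z_phosphate_upper + 2.0))
        lab_w = place_pseudo_label(conf, 1, n_samples=1500, seed=3, frame=membrane_frame)
        lab_u = place_pseudo_label(conf, 1, n_samples=1500, seed=3, frame=None)
        depth_w = np.average(membrane_depth(lab_w.positions[:, 2], membrane_frame), weights=lab_w.weights)
        depth_u = np.average(membrane_depth(lab_u.positions[:, 2], membrane_frame), weights=lab_u.weights)
        assert depth_w > depth_u

    def test_weights_sum_to_one(self, ideal_helix, membrane_frame):
        lab = place_pseudo_label(ideal_helix, 700, seed=4, frame=membrane_frame)
        assert lab.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestDistanceDistribution:
    def test_two_point_delta(self):
        a = LabelEnsemble(1, np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
        b = LabelEnsemble(2, np.array([[20.0, 0.0, 0.0]]), np.array([1.0]))
        dist = distance_distribution(a, b)
        assert dist.mean == pytest.approx(20.000, abs=1e-9)
        assert dist.sd == pytest.approx(0.0, abs=1e-9)
        assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_clouds_match_monte_carlo(self, rng):
        """Moments agree with a 10^6-pair Monte-Carlo estimate within 1%."""
        pa = rng.normal([0, 0, 0], 2.0, size=(1000, 3))
        pb = rng.normal([30, 0, 0], 2.0, size=(1000, 3))
        a = LabelEnsemble(1, pa, np.full(1000, 1e-3))
        b = LabelEnsemble(2, pb, np.full(1000, 1e-3))
        dist = distance_distribution(a, b)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1).ravel()
        assert dist.mean == pytest.approx(d.mean(), rel=0.01)
        assert dist.sd == pytest.approx(d.std(), rel=0.01)

    def test_symmetry_under_swap(self, rng):
        a = LabelEnsemble(1, rng.normal(0, 2, (50, 3)), np.full(50, 1 / 50))
        b = LabelEnsemble(2, rng.normal(25, 2, (40, 3)), np.full(40, 1 / 40))
        d1 = distance_distribution(a, b)
        d2 = distance_distribution(b, a)
        assert np.allclose(d1.density, d2.density)
        assert d1.mean == pytest.approx(d2.mean, abs=1e-9)

    def test_narrow_grid_rejected(self):
        a = LabelEnsemble(1, np.array([[0.0, 0, 0]]), np.array([1.0]))
        b = LabelEnsemble(2, np.array([[50.0, 0, 0]]), np.array([1.0]))
        with pytest.raises(ValueError, match="cover"):
            distance_distribution(a, b, grid_max=40.0)

    def test_smoothing_does_not_shift_moments(self, rng):
        a = LabelEnsemble(1, rng.normal(0, 1.5, (80, 3)), np.full(80, 1 / 80))
        b = LabelEnsemble(2, rng.normal(30, 1.5, (80, 3)), np.full(80, 1 / 80))
        wide = distance_distribution(a, b, bandwidth=3.0)
        narrow = distance_distribution(a, b, bandwidth=0.5)
        assert wide.mean == narrow.mean
        assert wide.sd == narrow.sd

    def test_invalid_density_rejected(self):
        grid = np.linspace(0, 10, 11)
        bad = np.full(11, 0.5)  # integrates to 5
        with pytest.raises(ValueError):
            DistanceDistribution(grid, bad, mean=5.0, sd=1.0)


class TestBoltzmannWeights:
    def _fes(self, values):
        values = np.asarray(values, float)
        g1 = np.arange(len(values), dtype=float)
        return FreeEnergySurface(g1, np.array([0.0]), values[:, None])

    def test_flat_surface_uniform(self):
        fes = self._fes([3.0, 3.0, 3.0])
        w = boltzmann_weights(fes, [(0, 0), (1, 0), (2, 0)], 300.0)
        assert np.allclose(w, 1 / 3)

    def test_kt_ln2_gap_gives_two_to_one(self):
        fes = self._fes([0.0, KT300 * np.log(2.0)])
        w = boltzmann_weights(fes, [(0, 0), (1, 0)], 300.0)
        assert w[0] == pytest.approx(2 / 3, abs=1e-9)
        assert w[1] == pytest.approx(1 / 3, abs=1e-9)

    def test_matches_direct_exponentials(self):
        f = np.array([0.0, 1.0, 2.0])
        fes = self._fes(f)
        w = boltzmann_weights(fes, [(0, 0), (1, 0), (2, 0)], 300.0)
        direct = np.exp(-f / KT300)
        direct /= direct.sum()
        assert np.abs(w - direct).max() <= 1e-12

    def test_shift_invariance(self):
        w1 = boltzmann_weights(self._fes([0.0, 1.0, 2.5]), [(0, 0), (1, 0), (2, 0)])
        w2 = boltzmann_weights(self._fes([10.0, 11.0, 12.5]), [(0, 0), (1, 0), (2, 0)])
        assert np.allclose(w1, w2)

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_weights(self._fes([0.0]), [])


class TestDepthProfile:
    def test_on_plane_zero(self, membrane_frame):
        lab = LabelEnsemble(
            700, np.array([[0.0, 0.0, membrane_frame.z_phosphate_upper]]), np.array([1.0])
        )
        prof = depth_profile([lab], membrane_frame)
        assert prof.depth_ang[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.phi[0] == pytest.approx(0.0, abs=1e-12)

    def test_center_saturates(self, membrane_frame):
        lab = LabelEnsemble(700, np.array([[0.0, 0.0, membrane_frame.z_center]]), np.array([1.0]))
        prof = depth_profile([lab], membrane_frame, phi_max=5.0, lambda_ang=10.0)
        expected = 5.0 * np.tanh(membrane_frame.half_thickness / 10.0)
        assert prof.phi[0] == pytest.approx(expected, abs=1e-12)

    def test_translation_equivariance(self, membrane_frame):
        z0 = membrane_frame.z_phosphate_upper - 1.0
        labs = [
            LabelEnsemble(r, np.array([[0.0, 0.0, z0 - i]]), np.array([1.0]))
            for i, r in enumerate((700, 701, 702))
        ]
        moved = [
            LabelEnsemble(l.site, l.positions - [0, 0, 3.0], l.weights) for l in labs
        ]
        p0 = depth_profile(labs, membrane_frame)
        p1 = depth_profile(moved, membrane_frame)
        assert np.allclose(p1.depth_ang - p0.depth_ang, 3.0)

    def test_phi_monotone_in_depth(self, membrane_frame):
        zs = np.linspace(membrane_frame.z_phosphate_upper + 5, membrane_frame.z_center, 20)
        labs = [
            LabelEnsemble(700 + i, np.array([[0.0, 0.0, z]]), np.array([1.0]))
            for i, z in enumerate(zs)
        ]
        prof = depth_profile(labs, membrane_frame)
        assert np.all(np.diff(prof.phi) > 0)


class TestProfileCorrelation:
    def test_affine_perfect(self):
        a = {r: float(r) for r in range(700, 710)}
        b = {r: 2.0 * r + 1.0 for r in range(700, 710)}
        assert profile_correlation(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_negated_is_minus_one(self):
        a = {r: float(r % 7) for r in range(700, 710)}
        b = {r: -v for r, v in a.items()}
        assert profile_correlation(a, b) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_independent_covariance_formula(self):
        xs = {1: 0.5, 2: 1.7, 3: -0.3, 4: 2.2, 5: 0.9}
        ys = {1: 1.1, 2: 0.4, 3: 0.0, 4: 1.9, 5: -0.7}
        x = np.array([xs[i] for i in range(1, 6)])
        y = np.array([ys[i] for i in range(1, 6)])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert profile_correlation(xs, ys) == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match=">=3"):
            profile_correlation({1: 1.0, 2: 2.0}, {1: 1.0, 2: 2.0})
        flat = {1: 1.0, 2: 1.0, 3: 1.0}
        with pytest.raises(ValueError, match="variance"):
            profile_correlation(flat, {1: 1.0, 2: 2.0, 3: 3.0})


def test_distance_table_round_trip(tmp_path):
    a = LabelEnsemble(1, np.array([[0.0, 0, 0]]), np.array([1.0]))
    b = LabelEnsemble(2, np.array([[20.0, 0, 0]]), np.array([1.0]))
    dist = distance_distribution(a, b)
    p = tmp_path / "deer.tsv"
    write_distance_table(dist, p)
    grid, dens = read_distance_table(p)
    assert np.allclose(grid, dist.grid)
    assert np.allclose(dens, dist.density)
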
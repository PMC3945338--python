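"""RDC back-calculation, tensor fitting, GA ensemble selection, clustering."""

import itertools

import numpy as np
import pytest

from helixkink.core import Conformation, StructureEnsemble
from helixkink.rdc import (
    AlignmentTensor,
    EnsembleRDCModel,
    FitError,
    RDCRecord,
    backcalc_rdc,
    ga_select_ensemble,
    jarvis_patrick,
    nh_vectors,
    q_factor,
    read_rdc_table,
    svd_fit_tensor,
    write_rdc_table,
)
from helixkink.synthetic import (
    KinkSpec,
    build_kinked_helix,
    random_tensor,
    sample_ensemble,
    synth_rdc,
)


class TestNHVectors:
    def test_explicit_h_used_exactly(self, ideal_helix):
        vecs = nh_vectors(ideal_helix)
        for r in (700, 708, 715):
            n = ideal_helix.atom_coords(r, "N")
            h = ideal_helix.atom_coords(r, "H")
            expected = (h - n) / np.linalg.norm(h - n)
            assert np.allclose(vecs[r], expected, atol=1e-12)

    def test_first_residue_skipped(self, ideal_helix):
        vecs = nh_vectors(ideal_helix)
        assert 686 not in vecs
        assert 687 in vecs

    def test_reconstruction_close_to_explicit(self, ideal_helix):
        stripped = Conformation([a for a in ideal_helix.atoms if a.name != "H"])
        rebuilt = nh_vectors(stripped)
        explicit = nh_vectors(ideal_helix)
        for r, v in rebuilt.items():
            ang = np.degrees(np.arccos(np.clip(np.dot(v, explicit[r]), -1, 1)))
            assert ang <= 5.0

    def test_missing_n_skipped_or_strict(self, ideal_helix):
        broken = Conformation(
            [a for a in ideal_helix.atoms if not (a.residue_index == 710 and a.name in ("N", "H"))]
        )
        with pytest.warns(UserWarning, match="710"):
            vecs = nh_vectors(broken)
        assert 710 not in vecs
        from helixkink.core import GeometryError

        with pytest.raises(GeometryError, match="710"):
            nh_vectors(broken, strict=True)


class TestTensorFit:
    def test_exact_recovery_noise_free(self, ideal_helix):
        planted = random_tensor(3)
        records, _ = synth_rdc(ideal_helix, tensor=planted)
        vecs = nh_vectors(ideal_helix)
        fitted = svd_fit_tensor(vecs, records[:20])
        assert np.abs(fitted.saupe - planted.saupe).max() <= 1e-8
        d_calc = backcalc_rdc(fitted, vecs)
        shared = [r for r in records if r.residue_index in d_calc]
        q = q_factor([d_calc[r.residue_index] for r in shared], [r.d_exp for r in shared])
        assert q <= 1e-8

    def test_noisy_recovery_within_tolerance(self, ideal_helix):
        planted = random_tensor(5)
        clean, _ = synth_rdc(ideal_helix, tensor=planted)
        rms = np.sqrt(np.mean([r.d_exp**2 for r in clean]))
        records, _ = synth_rdc(ideal_helix, tensor=planted, noise_sigma=0.1 * rms, seed=42)
        vecs = nh_vectors(ideal_helix)
        fitted = svd_fit_tensor(vecs, records)
        d_calc = backcalc_rdc(fitted, vecs)
        shared = [r for r in records if r.residue_index in d_calc]
        q = q_factor([d_calc[r.residue_index] for r in shared], [r.d_exp for r in shared])
        assert 0.05 <= q <= 0.2
        rel = np.abs(fitted.saupe - planted.saupe).max() / np.abs(planted.saupe).max()
        assert rel <= 0.15

    def test_too_few_records(self, ideal_helix):
        planted = random_tensor(1)
        records, _ = synth_rdc(ideal_helix, tensor=planted)
        with pytest.raises(FitError, match=">=5"):
            svd_fit_tensor(nh_vectors(ideal_helix), records[:4])

    def test_traceless_invariant(self, ideal_helix):
        records, _ = synth_rdc(ideal_helix, tensor=random_tensor(8))
        t = svd_fit_tensor(nh_vectors(ideal_helix), records)
        assert abs(np.trace(t.saupe)) <= 1e-12

    def test_refit_projection(self, ideal_helix):
        """Refitting a tensor to its own back-calculated couplings reproduces it."""
        vecs = nh_vectors(ideal_helix)
        t = random_tensor(13)
        d = backcalc_rdc(t, vecs)
        refit = svd_fit_tensor(vecs, [RDCRecord(r, v) for r, v in d.items()])
        assert np.abs(refit.saupe - t.saupe).max() <= 1e-10


class TestBackcalc:
    def test_zero_tensor(self, ideal_helix):
        zero = AlignmentTensor(np.zeros((3, 3)))
        d = backcalc_rdc(zero, nh_vectors(ideal_helix))
        assert all(v == 0.0 for v in d.values())

    def test_principal_axis_gives_eigenvalue(self):
        t = random_tensor(2)
        vals, vecs = np.linalg.eigh(t.saupe)
        d = backcalc_rdc(t, {1: vecs[:, 0], 2: vecs[:, 2]})
        assert d[1] == pytest.approx(vals[0], abs=1e-12)
        assert d[2] == pytest.approx(vals[2], abs=1e-12)

    def test_matches_explicit_double_sum(self, rng):
        t = random_tensor(4)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        expected = sum(t.saupe[k, l] * v[k] * v[l] for k in range(3) for l in range(3))
        assert backcalc_rdc(t, {7: v})[7] == pytest.approx(expected, abs=1e-12)


class TestQFactor:
    def test_perfect_fit(self):
        d = np.array([1.0, -2.0, 3.0])
        assert q_factor(d, d) == 0.0

    def test_zero_prediction_is_one(self):
        d = np.array([1.0, -2.0, 3.0])
        assert q_factor(np.zeros(3), d) == pytest.approx(1.0)

    def test_double_prediction_is_one(self):
        d = np.array([1.0, -2.0, 3.0])
        assert q_factor(2 * d, d) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert q_factor(3.7 * a, 3.7 * b) == pytest.approx(q_factor(a, b), abs=1e-12)

    def test_all_zero_exp_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            q_factor(np.ones(3), np.zeros(3))


class TestRDCTableIO:
    def test_round_trip(self, tmp_path):
        recs = [RDCRecord(700, 1.25), RDCRecord(701, -0.5)]
        p = tmp_path / "rdc.tsv"
        write_rdc_table(recs, p)
        assert p.read_text().splitlines()[0] == "residue\trdc"
        back = read_rdc_table(p)
        assert [(r.residue_index, r.d_exp) for r in back] == [(700, 1.25), (701, -0.5)]


@pytest.fixture(scope="module")
def mixture_setup(ideal_helix):
    bent = build_kinked_helix(kink=KinkSpec(target_bend_deg=30.0))
    pool = StructureEnsemble(
        list(sample_ensemble(ideal_helix, 50, 2.0, seed=100))
        + list(sample_ensemble(bent, 50, 2.0, seed=200))
    )
    records, truth = synth_rdc(
        [ideal_helix, bent], tensor=random_tensor(7), mixture_weights=[0.6, 0.4]
    )
    return pool, records, truth


class TestGASelection:
    def test_planted_solution_recovered(self, ideal_helix):
        decoys = sample_ensemble(
            build_kinked_helix(kink=KinkSpec(target_bend_deg=30.0)), 20, 6.0, seed=300
        )
        pool = StructureEnsemble([ideal_helix] + list(decoys))
        records, _ = synth_rdc(ideal_helix, tensor=random_tensor(9))
        res = ga_select_ensemble(pool, records, {"ensemble_size": 1, "generations": 50, "seed": 1})
        assert list(res.selected) == [0]
        assert res.q <= 1e-8

    def test_mixture_recovery_over_seeds(self, mixture_setup):
        pool, records, _ = mixture_setup
        model = EnsembleRDCModel(pool, records)
        fracs = [
            np.mean(model.fit(ensemble_size=10, seed=s).selected < 50) for s in range(2)
        ]
        assert np.mean(fracs) == pytest.approx(0.6, abs=0.1)

    def test_beats_random_search_baseline(self, mixture_setup):
        pool, records, _ = mixture_setup
        model = EnsembleRDCModel(pool, records)
        res = model.fit(ensemble_size=10, population=40, generations=40, seed=3)
        rng = np.random.default_rng(3)
        n_random = 40 * 41 * 10  # 10x the GA evaluation budget
        best_random = min(
            model._q_only(rng.choice(len(pool), size=10, replace=False))
            for _ in range(n_random)
        )
        assert res.q <= best_random

    def test_deterministic_given_seed(self, mixture_setup):
        pool, records, _ = mixture_setup
        model = EnsembleRDCModel(pool, records)
        a = model.fit(ensemble_size=5, population=20, generations=10, seed=11)
        b = model.fit(ensemble_size=5, population=20, generations=10, seed=11)
        assert np.array_equal(a.selected, b.selected)
        assert a.q == b.q
        assert np.array_equal(a.history, b.history)

    def test_invalid_params(self, mixture_setup):
        pool, records, _ = mixture_setup
        model = EnsembleRDCModel(pool, records)
        with pytest.raises(ValueError):
            model.fit(ensemble_size=0)
        with pytest.raises(ValueError):
            model.fit(ensemble_size=10, population=1)

    def test_results_q_recomputable(self, mixture_setup):
        pool, records, _ = mixture_setup
        res = EnsembleRDCModel(pool, records).fit(
            ensemble_size=5, population=20, generations=10, seed=2
        )
        assert res.q == pytest.approx(q_factor(res.d_calc, res.model.d_exp), abs=1e-12)
        assert "Q factor" in res.summary()


def _brute_force_jp(D, k, kmin):
    """Independent implementation of the Jarvis-Patrick join rule."""
    n = D.shape[0]
    neigh = []
    for i in range(n):
        others = sorted(j for j in range(n) if j != i)
        ds = sorted(D[i, j] for j in others)
        kth = ds[k - 1]
        neigh.append({j for j in others if D[i, j] <= kth})
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        if j in neigh[i] and i in neigh[j] and len(neigh[i] & neigh[j]) >= kmin:
            adj[i].add(j)
            adj[j].add(i)
    labels = [-1] * n
    cid = 0
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(adj[u] - seen)
        if len(comp) >= 2:
            for u in comp:
                labels[u] = cid
            cid += 1
    return labels


def _canonical_partition(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab if lab >= 0 else f"s{i}", set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


class TestJarvisPatrick:
    def test_two_tight_groups(self, ideal_helix, kinked_helix_30):
        pool = StructureEnsemble(
            list(sample_ensemble(ideal_helix, 5, 1.0, seed=1))
            + list(sample_ensemble(kinked_helix_30, 5, 1.0, seed=2))
        )
        result = jarvis_patrick(pool, k_neighbors=4, k_min_shared=2)
        assert set(result.labels[:5]) == {result.labels[0]}
        assert set(result.labels[5:]) == {result.labels[5]}
        assert result.labels[0] != result.labels[5]
        assert -1 not in result.labels

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_on_small_instances(self, trial, rng):
        n = 6 + trial % 3
        pts = rng.normal(size=(n, 2)) * (2 + trial)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        k, kmin = 3, 2
        mine = jarvis_patrick(None, k, kmin, distance_matrix=D)
        ref = _brute_force_jp(D, k, kmin)
        assert _canonical_partition(mine.labels) == _canonical_partition(ref)

    def test_all_identical_single_cluster(self, ideal_helix):
        pool = StructureEnsemble([ideal_helix] * 6)
        result = jarvis_patrick(pool, k_neighbors=3, k_min_shared=3)
        assert len(set(result.labels)) == 1
        assert result.labels[0] >= 0

    def test_order_invariance(self, rng):
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        base = jarvis_patrick(None, 3, 2, distance_matrix=D)
        perm = rng.permutation(8)
        Dp = D[np.ix_(perm, perm)]
        permuted = jarvis_patrick(None, 3, 2, distance_matrix=Dp)
        mapped = [permuted.labels[list(perm).index(i)] for i in range(8)]
        assert _canonical_partition(base.labels) == _canonical_partition(mapped)

    def test_k_too_large_rejected(self, rng):
        D = np.abs(rng.normal(size=(4, 4)))
        with pytest.raises(ValueError, match="pool size"):
            jarvis_patrick(None, 4, 2, distance_matrix=D)
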
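"""Restraint building, annealing, clustering and ensemble geometry."""

import numpy as np
import pytest

import nucleoid3d as n3
from nucleoid3d.model3d import (
    KIND_ADJACENT,
    KIND_ATTRACT,
    KIND_LOWER_BOUND,
    restraint_energy,
    superposed_rmsd,
)


def toy_restraints(n_particles, entries, radius=1.0):
    i, j, kind, d0, k = (np.array(x) for x in zip(*entries))
    return n3.RestraintSet(n_particles=n_particles, radii=np.full(n_particles, radius),
                           i=i, j=j, kind=kind, d0=d0, k=k, require_adjacency=False)


class TestParticleRadius:
    @pytest.mark.parametrize("bin_size,scale,expected",
                             [(10_000, 0.0201, 100.5), (1, 2.0, 1.0), (3000, 0.0201, 30.15)])
    def test_radius_formula(self, bin_size, scale, expected):
        assert n3.particle_radius(bin_size, scale) == pytest.approx(expected)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            n3.particle_radius(0, 0.02)


class TestBuildRestraints:
    def normalized_map(self, seed=0, n=20):
        truth = n3.PlantedTruth(n_bins=n, decay_exponent=-1.0, antidiagonal_eps=0.0)
        raw = n3.simulate_contact_map(truth, n, 100.0, seed=seed, bin_size=10_000)
        return n3.ice_normalize(raw)

    def test_adjacency_present_for_every_circular_pair(self):
        cfg = n3.ModelingConfig()
        rs = n3.build_restraints(self.normalized_map(), cfg)
        adj = {(min(a, b), max(a, b)) for a, b, kd in zip(rs.i, rs.j, rs.kind)
               if kd == KIND_ADJACENT}
        n = 20
        assert {(p, p + 1) for p in range(n - 1)} | {(0, n - 1)} <= adj
        sum_radii = 2 * n3.particle_radius(10_000, cfg.scale)
        for a, b, kd, d0 in zip(rs.i, rs.j, rs.kind, rs.d0):
            if kd == KIND_ADJACENT:
                assert d0 == pytest.approx(sum_radii)

    def test_attract_distance_decreases_with_frequency(self):
        cfg = n3.ModelingConfig()
        rs = n3.build_restraints(self.normalized_map(), cfg)
        attract = rs.kind == KIND_ATTRACT
        assert attract.sum() > 0
        sum_radii = 2 * n3.particle_radius(10_000, cfg.scale)
        assert np.all(rs.d0[attract] <= cfg.maxdist + 1e-9)
        assert np.all(rs.d0[attract] >= sum_radii - 1e-9)

    def test_low_frequency_pairs_get_lower_bound_at_maxdist(self):
        cfg = n3.ModelingConfig()
        rs = n3.build_restraints(self.normalized_map(), cfg)
        lower = rs.kind == KIND_LOWER_BOUND
        assert lower.sum() > 0
        assert np.all(rs.d0[lower] == cfg.maxdist)

    def test_all_zero_matrix_rejected(self):
        m = n3.ContactMatrix(values=np.zeros((10, 10)), bin_size=10_000, state="normalized")
        with pytest.raises(ValueError):
            n3.build_restraints(m, n3.ModelingConfig())

    def test_conflicting_kinds_rejected(self):
        with pytest.raises(ValueError):
            toy_restraints(3, [(0, 1, KIND_ATTRACT, 5.0, 1.0),
                               (1, 0, KIND_LOWER_BOUND, 5.0, 1.0)])


class TestOptimizeEnsemble:
    def test_single_attract_pair_reaches_equilibrium(self):
        rs = toy_restraints(2, [(0, 1, KIND_ATTRACT, 5.0, 1.0)])
        cfg = n3.ModelingConfig(n_models=3, n_keep=3, maxdist=10.0, step0=1.0,
                                t0=10.0, tmin=0.01, seed=1)
        ens = n3.optimize_ensemble(rs, cfg)
        for m in range(3):
            d = np.linalg.norm(ens.coords[m, 0] - ens.coords[m, 1])
            assert d == pytest.approx(5.0, rel=0.01)

    def test_adjacency_chain_reaches_sum_of_radii(self):
        entries = [(0, 1, KIND_ADJACENT, 2.0, 1.0), (1, 2, KIND_ADJACENT, 2.0, 1.0)]
        rs = toy_restraints(3, entries)
        cfg = n3.ModelingConfig(n_models=2, n_keep=2, maxdist=10.0, step0=1.0,
                                t0=10.0, tmin=0.01, seed=2)
        ens = n3.optimize_ensemble(rs, cfg)
        for m in range(2):
            for a, b in [(0, 1), (1, 2)]:
                d = np.linalg.norm(ens.coords[m, a] - ens.coords[m, b])
                assert d == pytest.approx(2.0, rel=0.01)

    def test_deterministic_under_seed_and_penalties_finite(self):
        rs = toy_restraints(4, [(0, 1, KIND_ADJACENT, 2.0, 1.0),
                                (1, 2, KIND_ADJACENT, 2.0, 1.0),
                                (2, 3, KIND_ADJACENT, 2.0, 1.0),
                                (0, 3, KIND_ATTRACT, 3.0, 1.0)])
        cfg = n3.ModelingConfig(n_models=4, n_keep=4, seed=5, t0=10.0, step0=1.0)
        a = n3.optimize_ensemble(rs, cfg)
        b = n3.optimize_ensemble(rs, cfg)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert np.all(np.isfinite(a.penalties))

    def test_annealing_energy_decreases_in_expectation(self):
        truth = n3.generate_true_structure(20, 50.0, seed=0)
        cmap = n3.contact_map_from_structure(truth, 100.0, seed=0)
        norm = n3.ice_normalize(cmap)
        cfg = n3.ModelingConfig(n_models=8, n_keep=8, seed=0)
        ens = n3.optimize_ensemble(n3.build_restraints(norm, cfg), cfg)
        mean_trace = ens.energy_trace.mean(axis=0)
        # monotone in expectation: allow small noise, require a strong net drop
        assert mean_trace[-1] < 0.2 * mean_trace[0]
        diffs = np.diff(mean_trace)
        assert (diffs <= np.abs(mean_trace[:-1]) * 0.05).mean() > 0.9
        # final penalty never exceeds the first recorded annealing energy
        assert np.all(ens.penalties <= ens.energy_trace[:, 0])


class TestSelectModels:
    def make(self, penalties):
        n = len(penalties)
        return n3.ModelEnsemble(coords=np.zeros((n, 2, 3)),
                                penalties=np.array(penalties, float),
                                run_index=np.arange(n))

    def test_lowest_penalties_kept_with_tie_break(self):
        ens = self.make([3.0, 1.0, 2.0, 1.0])
        kept = n3.select_models(ens, 2)
        assert sorted(kept.run_index.tolist()) == [1, 3]

    def test_identity_and_idempotence(self):
        ens = self.make([5.0, 4.0, 3.0])
        assert n3.select_models(ens, 3).n_models == 3
        once = n3.select_models(ens, 2)
        twice = n3.select_models(once, 2)
        np.testing.assert_array_equal(once.run_index, twice.run_index)

    def test_overlarge_keep_rejected(self):
        with pytest.raises(ValueError):
            n3.select_models(self.make([1.0]), 2)


class TestClusterModels:
    def test_mirror_ensemble_splits_into_two_clusters(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(12, 3)) * 50.0
        mirror = base.copy()
        mirror[:, 2] *= -1
        coords = np.stack([base + rng.normal(scale=0.5, size=base.shape) for _ in range(4)]
                          + [mirror + rng.normal(scale=0.5, size=base.shape) for _ in range(4)])
        ens = n3.ModelEnsemble(coords=coords, penalties=np.zeros(8), run_index=np.arange(8))
        out = n3.cluster_models(ens)
        assert out.cluster_labels.max() + 1 == 2
        assert len(set(out.cluster_labels[:4])) == 1
        assert out.cluster_labels[0] != out.cluster_labels[4]

    def test_achiral_planar_structure_merges_with_its_mirror(self):
        theta = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        planar = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(10)]) * 30.0
        mirror = planar.copy()
        mirror[:, 2] *= -1
        ens = n3.ModelEnsemble(coords=np.stack([planar, mirror, planar]),
                               penalties=np.zeros(3), run_index=np.arange(3))
        assert superposed_rmsd(planar, mirror) < 1e-6
        out = n3.cluster_models(ens)
        assert out.cluster_labels.max() + 1 == 1

    def test_reflection_flag_merges_mirror_clusters(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(12, 3)) * 50.0
        mirror = base.copy()
        mirror[:, 2] *= -1
        ens = n3.ModelEnsemble(coords=np.stack([base, mirror, base, mirror]),
                               penalties=np.zeros(4), run_index=np.arange(4))
        out = n3.cluster_models(ens, allow_reflection=True)
        assert out.cluster_labels.max() + 1 == 1

    def test_single_model_rejected(self):
        ens = n3.ModelEnsemble(coords=np.zeros((1, 3, 3)), penalties=np.zeros(1),
                               run_index=np.arange(1))
        with pytest.raises(ValueError):
            n3.cluster_models(ens)


class TestEnsembleGeometry:
    def test_two_point_formulas(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 10.0
        geo = n3.ensemble_geometry(n3.ModelEnsemble(coords=coords, penalties=np.zeros(1),
                                                    run_index=np.arange(1)))
        assert geo["median_length_nm"] == pytest.approx(10.0)
        assert geo["median_width_nm"] == pytest.approx(10.0)  # 2 x Rg, Rg = 5

    def test_prolate_ellipsoid_volume_value(self):
        # length 1000 nm, width 500 nm -> (4/3) pi 500 * 250^2 nm^3 ~ 0.1309 um^3
        length, width = 1000.0, 500.0
        vol = (4 / 3) * np.pi * (length / 2) * (width / 2) ** 2 * 1e-9
        assert vol == pytest.approx(0.1309, rel=1e-3)
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 1000.0
        geo = n3.ensemble_geometry(n3.ModelEnsemble(coords=coords, penalties=np.zeros(1),
                                                    run_index=np.arange(1)))
        expected = (4 / 3) * np.pi * 500.0 * 500.0 ** 2 * 1e-9
        assert geo["median_volume_um3"] == pytest.approx(expected)

    def test_sphere_cloud_length_close_to_diameter(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(500, 3))
        pts = 100.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        geo = n3.ensemble_geometry(n3.ModelEnsemble(coords=pts[None], penalties=np.zeros(1),
                                                    run_index=np.arange(1)))
        assert geo["median_length_nm"] == pytest.approx(200.0, rel=0.05)

    def test_rigid_motion_and_reflection_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(15, 3)) * 40.0
        # random proper rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = base @ q + np.array([100.0, -50.0, 20.0])
        reflected = base * np.array([1.0, 1.0, -1.0])
        geos = [n3.ensemble_geometry(n3.ModelEnsemble(coords=c[None], penalties=np.zeros(1),
                                                      run_index=np.arange(1)))
                for c in (base, moved, reflected)]
        for key in ("median_length_nm", "median_width_nm", "median_volume_um3"):
            assert geos[1][key] == pytest.approx(geos[0][key])
            assert geos[2][key] == pytest.approx(geos[0][key])

    def test_single_particle_rejected(self):
        ens = n3.ModelEnsemble(coords=np.zeros((1, 1, 3)), penalties=np.zeros(1),
                               run_index=np.arange(1))
        with pytest.raises(ValueError):
            n3.ensemble_geometry(ens)


class TestModelContactMap:
    def identical_ensemble(self):
        coords = np.zeros((5, 3, 3))
        coords[:, 1, 0] = 100.0
        coords[:, 2, 0] = 500.0
        return n3.ModelEnsemble(coords=coords, penalties=np.zeros(5), run_index=np.arange(5))

    def test_identical_conformations_give_binary_map(self):
        frac, _ = n3.model_contact_map(self.identical_ensemble(), contact_cutoff=225.0)
        assert set(np.unique(frac)) <= {0.0, 1.0}

    def test_infinite_cutoff_gives_all_ones(self):
        frac, _ = n3.model_contact_map(self.identical_ensemble(), contact_cutoff=1e12)
        np.testing.assert_array_equal(frac, np.ones((3, 3)))

    def test_degenerate_reference_rejected(self):
        ref = n3.ContactMatrix(values=np.ones((3, 3)), bin_size=1, state="normalized")
        with pytest.raises(ValueError):
            n3.model_contact_map(self.identical_ensemble(), contact_cutoff=1e12,
                                 reference=ref)


class TestLocusAndProfile:
    def test_locus_distance_identities(self):
        coords = np.zeros((3, 4, 3))
        coords[:, 1, 0] = 7.0
        ens = n3.ModelEnsemble(coords=coords, penalties=np.zeros(3), run_index=np.arange(3))
        out = n3.locus_distances(ens, [0, 1, 0])
        assert out["median"][0, 2] == 0.0
        assert out["median"][0, 1] == pytest.approx(7.0)
        with pytest.raises(IndexError):
            n3.locus_distances(ens, [99])

    def test_center_of_mass_profile_on_symmetric_ring(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(12)]) * 50.0
        ens = n3.ModelEnsemble(coords=ring[None], penalties=np.zeros(1),
                               run_index=np.arange(1))
        prof = n3.center_of_mass_profile(ens)
        np.testing.assert_allclose(prof["median"], 50.0, rtol=1e-9)

    def test_poles_have_maximal_profile_on_true_structure(self):
        coords = n3.generate_true_structure(40, 10.0, seed=2)
        ens = n3.ModelEnsemble(coords=coords[None], penalties=np.zeros(1),
                               run_index=np.arange(1))
        prof = n3.center_of_mass_profile(ens)["median"]
        # a near-circular ring: all bins nearly equidistant from the centre,
        # poles (0, n/2) among the top by construction of the wobble-free circle
        flat = n3.generate_true_structure(40, 10.0, seed=2, wobble=0.0)
        ens0 = n3.ModelEnsemble(coords=flat[None], penalties=np.zeros(1),
                                run_index=np.arange(1))
        prof0 = n3.center_of_mass_profile(ens0)["median"]
        np.testing.assert_allclose(prof0, prof0[0], rtol=1e-9)
        assert prof.std() / prof.mean() < 0.1


def test_restraint_energy_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    rs = toy_restraints(5, [(0, 1, KIND_ADJACENT, 2.0, 1.5),
                            (1, 2, KIND_ATTRACT, 3.0, 2.0),
                            (2, 3, KIND_LOWER_BOUND, 4.0, 1.0),
                            (0, 4, KIND_LOWER_BOUND, 4.0, 1.0)])
    x = rng.normal(size=15)
    e0, g = restraint_energy(x, rs)
    eps = 1e-6
    for idx in range(15):
        xp = x.copy()
        xp[idx] += eps
        ep, _ = restraint_energy(xp, rs)
        assert (ep - e0) / eps == pytest.approx(g[idx], rel=1e-3, abs=1e-5)
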
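"""Reduced potentials, MBAR leg, assembly, poses, MM/GBSA, metrics."""

import numpy as np
import pytest

from dbfe.constants import KB
from dbfe.errors import AssemblyError, ParameterError
from dbfe.free_energy import (DecoupledSample, ReducedPotentialMatrix,
                              assemble_total, bootstrap_metrics,
                              combine_poses, evaluate_reduced_potentials,
                              mbar_delta_g, mmgbsa_baseline)
from dbfe.mbar import bar_delta_f, solve_mbar
from dbfe.restraint_model import RestraintParameters
from dbfe.rigid_geometry import RigidTransform
from dbfe.toy_systems import ToyBackend, direct_boltzmann_sample, preset
from dbfe.trajectory_io import TrajectoryEnsemble

T = 300.0
KT = KB * T


def make_matrix(u0, u1, origin):
    return ReducedPotentialMatrix(u=np.vstack([u0, u1]), origin=np.array(origin))


class TestMBARLeg:
    def test_identical_states_give_exact_zero_and_full_overlap(self, rng):
        u = rng.standard_normal(2000)
        m = make_matrix(u, u, ["filtered_decoupled"] * 1000 + ["complex_traj"] * 1000)
        dg, se, overlap = mbar_delta_g(m, T)
        assert dg == 0.0
        assert overlap > 0.99

    def test_two_harmonic_wells_match_closed_form(self):
        # stiffness ratio 4: dG = (kT/2) ln 4
        r = np.random.default_rng(10)
        k0, k1 = 1.0, 4.0
        n = 5000
        x0 = r.normal(0, np.sqrt(KT / k0), n)
        x1 = r.normal(0, np.sqrt(KT / k1), n)
        x = np.concatenate([x0, x1])
        beta = 1.0 / KT
        m = make_matrix(beta * k0 * x**2 / 2, beta * k1 * x**2 / 2,
                        ["filtered_decoupled"] * n + ["complex_traj"] * n)
        dg, se, overlap = mbar_delta_g(m, T)
        exact = 0.5 * KT * np.log(k1 / k0)
        assert abs(dg - exact) < 3 * se
        assert overlap > 0.5

    def test_mbar_agrees_with_independent_bar_root(self, rng):
        n = 3000
        x0 = rng.normal(0, 1, n)
        x1 = rng.normal(0.5, 0.8, n)
        x = np.concatenate([x0, x1])
        u0 = x**2 / 2
        u1 = (x - 0.5) ** 2 / (2 * 0.64)
        res = solve_mbar(np.vstack([u0, u1]), [n, n])
        bar = bar_delta_f(u1[:n] - u0[:n], u0[n:] - u1[n:])
        assert abs(res.delta_f - bar) < 1e-6

    def test_poor_overlap_detected(self, rng):
        # two unit Gaussians offset by 6 sigma
        n = 1000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(6, 1, n)])
        m = make_matrix(x**2 / 2, (x - 6) ** 2 / 2,
                        ["filtered_decoupled"] * n + ["complex_traj"] * n)
        _, _, overlap = mbar_delta_g(m, T)
        assert overlap < 0.01

    def test_infinite_potentials_are_hard_walls(self, rng):
        # a sample outside the conditional support carries zero weight
        n = 500
        u0 = np.abs(rng.standard_normal(2 * n))
        u1 = np.abs(rng.standard_normal(2 * n))
        u0_inf = u0.copy()
        u0_inf[n] = np.inf  # one complex sample clashes
        m = make_matrix(u0_inf, u1,
                        ["filtered_decoupled"] * n + ["complex_traj"] * n)
        dg, _, _ = mbar_delta_g(m, T)
        assert np.isfinite(dg)


@pytest.fixture(scope="module")
def reduced_potential_setup():
    spec = preset("pure_harmonic", seed=3)
    backend = ToyBackend(spec)
    cpx = direct_boltzmann_sample(spec, "complex", 50, seed=1)
    restraint = RestraintParameters(
        mu=spec.site_center, sigma=0.3 * np.eye(3), M=np.eye(4),
        Z=np.zeros((4, 4)), rotational=False)
    zetas = [RigidTransform(f.coordinates[6:].mean(axis=0)
                            - f.coordinates[:6].mean(axis=0),
                            [1, 0, 0, 0])
             for f in cpx.frames]
    dec = [DecoupledSample(receptor_coords=f.coordinates[:6],
                           ligand_coords=f.coordinates[6:], zeta=z)
           for f, z in zip(cpx.frames, zetas)]
    return spec, backend, cpx, restraint, zetas, dec


class TestReducedPotentials:
    def test_subsampling_contract(self, reduced_potential_setup):
        spec, backend, cpx, restraint, zetas, dec = reduced_potential_setup
        m1 = evaluate_reduced_potentials(cpx, dec, backend, restraint, T,
                                         complex_zetas=zetas, n_s=5, seed=9)
        m2 = evaluate_reduced_potentials(cpx, dec, backend, restraint, T,
                                         complex_zetas=zetas, n_s=5, seed=9)
        assert m1.u.shape == (2, 10)
        np.testing.assert_array_equal(m1.u, m2.u)
        assert list(m1.n_k) == [5, 5]

    def test_noninteracting_backend_difference_is_restraint_only(self, reduced_potential_setup):
        spec, backend, cpx, restraint, zetas, dec = reduced_potential_setup

        class NonInteracting:
            def evaluate_many(self, topology, coords):
                # U_PL == U_P + U_L == 0 for every subsystem
                return np.zeros(np.asarray(coords, float).shape[0])

        m = evaluate_reduced_potentials(cpx, dec, NonInteracting(), restraint,
                                        T, complex_zetas=zetas, n_s=20, seed=0)
        # u_rc - u_1 reduces to the (nonnegative, Gaussian) restraint term
        diff = m.u[0] - m.u[1]
        assert np.all(diff >= 0)
        assert np.any(diff > 0)

    def test_matrix_matches_hand_evaluation(self, reduced_potential_setup):
        spec, backend, cpx, restraint, zetas, dec = reduced_potential_setup
        m = evaluate_reduced_potentials(cpx, dec, backend, restraint, T,
                                        complex_zetas=zetas, n_s=3, seed=2)
        beta = 1.0 / KT
        rng = np.random.default_rng(2)
        # reproduce the subsample selection, then check columns by hand
        rng.choice(len(cpx), size=3, replace=False)  # complex draw (first)
        sel_dec = np.sort(rng.choice(len(dec), size=3, replace=False))
        for col in range(3):
            d = dec[sel_dec[col]]
            u_rc = beta * (float(spec.receptor_energy(d.receptor_coords))
                           + float(spec.ligand_energy(d.ligand_coords)))
            u_rc += 0.5 * float(
                (d.zeta.t - restraint.mu)
                @ np.linalg.solve(restraint.sigma, d.zeta.t - restraint.mu))
            assert m.u[0, col] == pytest.approx(u_rc, rel=1e-10)
            u_1 = beta * float(spec.complex_energy(
                np.concatenate([d.receptor_coords, d.ligand_coords])))
            assert m.u[1, col] == pytest.approx(u_1, rel=1e-10)


class TestAssembly:
    def test_legs_add(self):
        res = assemble_total(-2.0, 1.0, -4.0)
        assert res.dg_total == pytest.approx(-5.0, abs=1e-12)

    def test_zero_legs_quadrature_error(self):
        res = assemble_total(0.0, 0.0, 0.0, se_filter=0.3, se_mbar=0.4)
        assert res.dg_total == 0.0
        assert res.se_total == pytest.approx(0.5)

    def test_se_quadrature_contract(self):
        res = assemble_total(1.0, 1.0, 1.0, se_filter=0.06, se_mbar=0.08)
        assert res.se_total**2 == pytest.approx(0.06**2 + 0.08**2)

    def test_nan_leg_rejected(self):
        with pytest.raises(AssemblyError):
            assemble_total(np.nan, 0.0, 0.0)


class TestCombinePoses:
    def test_single_pose_identity(self):
        assert combine_poses([-5.0], T) == pytest.approx(-5.0, abs=1e-12)

    def test_two_equal_poses(self):
        expected = -5.0 - KT * np.log(2.0)
        assert combine_poses([-5.0, -5.0], T) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_dominant_pose_limit(self):
        assert combine_poses([-5.0, 50.0], T) == pytest.approx(-5.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            combine_poses([], T)


class TestMMGBSA:
    def test_noninteracting_decomposition_is_zero(self):
        spec = preset("pure_harmonic", seed=3)
        spec.well_depth = 0.0
        spec.site_stiffness = 0.0
        backend = ToyBackend(spec)
        cpx = direct_boltzmann_sample(preset("pure_harmonic", seed=3),
                                      "complex", 30, seed=5)
        cpx = TrajectoryEnsemble(spec.complex_topology(), cpx.frames)
        assert mmgbsa_baseline(cpx, backend) == pytest.approx(0.0, abs=1e-10)

    def test_constant_interaction_recovered(self):
        spec = preset("pure_harmonic", seed=3)
        spec.well_depth = 3.0
        spec.site_stiffness = 0.0
        backend = ToyBackend(spec)
        cpx = direct_boltzmann_sample(preset("pure_harmonic", seed=3),
                                      "complex", 30, seed=5)
        cpx = TrajectoryEnsemble(spec.complex_topology(), cpx.frames)
        assert mmgbsa_baseline(cpx, backend) == pytest.approx(-3.0, abs=1e-10)

    def test_harmonic_complex_matches_hand_evaluation(self):
        spec = preset("pure_harmonic", seed=3)
        backend = ToyBackend(spec)
        cpx = direct_boltzmann_sample(spec, "complex", 10, seed=5)
        coords = cpx.coordinates()
        by_hand = np.mean([
            float(spec.complex_energy(c))
            - float(spec.receptor_energy(c[:6]))
            - float(spec.ligand_energy(c[6:]))
            for c in coords])
        assert mmgbsa_baseline(cpx, backend) == pytest.approx(by_hand,
                                                              rel=1e-10)


class TestBootstrapMetrics:
    def test_perfect_agreement(self, rng):
        x = rng.standard_normal(10)
        m = bootstrap_metrics(x, x, n_resamples=200, seed=1)
        assert m["rmse"]["value"] == pytest.approx(0.0, abs=1e-12)
        assert m["pearson_r"]["value"] == pytest.approx(1.0)
        assert m["spearman_rho"]["value"] == pytest.approx(1.0)

    def test_anti_sorted_pairs(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = bootstrap_metrics(pred, pred[::-1], n_resamples=100, seed=1)
        assert m["spearman_rho"]["value"] == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        pred = rng.standard_normal(5)
        expt = rng.standard_normal(5)
        m = bootstrap_metrics(pred, expt, n_resamples=50, seed=2)
        cov = np.mean((pred - pred.mean()) * (expt - expt.mean()))
        r = cov / (pred.std() * expt.std())
        assert m["pearson_r"]["value"] == pytest.approx(r, rel=1e-10)

    def test_constant_predictions_reported_not_crashed(self):
        m = bootstrap_metrics([1.0, 1.0, 1.0], [0.0, 1.0, 2.0],
                              n_resamples=50, seed=3)
        assert m["pearson_r"]["value"] is None

    def test_seed_reproducible(self, rng):
        pred = rng.standard_normal(8)
        expt = pred + rng.standard_normal(8) * 0.3
        a = bootstrap_metrics(pred, expt, n_resamples=300, seed=7)
        b = bootstrap_metrics(pred, expt, n_resamples=300, seed=7)
        assert a == b
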
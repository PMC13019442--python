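"""Restraint fitting, Bingham machinery, analytic release free energy."""

import numpy as np
import pytest
from scipy.stats import chi2, ortho_group

from dbfe import bingham
from dbfe.constants import KB, S3_VOLUME, V_STANDARD
from dbfe.errors import ClusteringError
from dbfe.restraint_model import (RestraintParameters, delta_g_release,
                                  fit_restraint, reduced_restraint_energy,
                                  restraint_energy, restraint_log_partition,
                                  sample_restraint, sample_restraint_arrays,
                                  select_largest_mode)
from dbfe.rigid_geometry import RigidTransform, canonical_quaternion

T = 300.0
KT = KB * T


def make_params(mu=(0.0, 0.0, 0.0), sigma=None, z=(0.0, 0.0, 0.0, 0.0),
                M=None, rotational=True):
    sigma = np.eye(3) if sigma is None else np.asarray(sigma, float)
    M = np.eye(4) if M is None else M
    z = np.sort(np.asarray(z, float))  # ascending, gauge max = 0
    return RestraintParameters(mu=np.asarray(mu, float), sigma=sigma,
                               M=M, Z=np.diag(z), rotational=rotational)


def random_orthogonal_4(rng):
    return ortho_group.rvs(4, random_state=rng)


class TestModeSelection:
    def test_all_identical_collapse_to_one_cluster(self):
        zetas = [RigidTransform(np.array([1.0, 2, 3]), [1, 0, 0, 0])
                 for _ in range(30)]
        members, _ = select_largest_mode(zetas, bandwidth=0.5)
        assert len(members) == 30

    def test_two_separated_clusters_returns_majority(self, rng):
        big = [RigidTransform(rng.normal([0, 0, 0], 0.1), [1, 0, 0, 0])
               for _ in range(80)]
        small = [RigidTransform(rng.normal([8, 0, 0], 0.1), [1, 0, 0, 0])
                 for _ in range(20)]
        zetas = big + small
        members, center = select_largest_mode(zetas)
        # oracle: nearest-center assignment on the generating centers
        truth = {i for i in range(100)
                 if np.linalg.norm(zetas[i].t) < np.linalg.norm(zetas[i].t - [8, 0, 0])}
        assert set(members.tolist()) == truth

    def test_center_inside_member_translation_box(self, rng):
        zetas = [RigidTransform(rng.normal(0, 1, 3), [1, 0, 0, 0])
                 for _ in range(200)]
        members, center = select_largest_mode(zetas)
        trans = np.array([zetas[i].t for i in members])
        assert np.all(center[:3] >= trans.min(axis=0) - 1e-9)
        assert np.all(center[:3] <= trans.max(axis=0) + 1e-9)

    def test_singleton_clusters_raise(self, rng):
        zetas = [RigidTransform(np.array([10.0 * i, 0, 0]), [1, 0, 0, 0])
                 for i in range(12)]
        with pytest.raises(ClusteringError):
            select_largest_mode(zetas, bandwidth=0.01)


class TestFitRestraint:
    def test_degenerate_translations_hit_covariance_floor(self):
        zetas = [RigidTransform(np.array([1.0, 1, 1]), [1, 0, 0, 0])
                 for _ in range(20)]
        params = fit_restraint(zetas, range(20), rotational=False)
        np.testing.assert_allclose(params.mu, [1, 1, 1], atol=1e-12)
        np.testing.assert_allclose(params.sigma, 1e-4 * np.eye(3), atol=1e-12)

    def test_parameter_recovery_from_known_density(self, rng):
        mu = np.array([1.0, -2.0, 0.5])
        sigma = np.diag([0.09, 0.16, 0.25])
        z = np.array([-10.0, -4.0, -1.5, 0.0])
        M = random_orthogonal_4(rng)
        truth = RestraintParameters(mu=mu, sigma=sigma, M=M, Z=np.diag(z))
        zetas = sample_restraint(truth, 100_000, seed=5)
        fit = fit_restraint(zetas, range(100_000))
        assert np.linalg.norm(fit.mu - mu) < 0.05
        assert np.all(np.abs(np.linalg.eigvalsh(fit.sigma)
                             - np.diag(sigma)) < 0.1 * np.diag(sigma))
        z_fit = np.sort(fit.z_diag)
        mask = z < 0
        assert np.all(np.abs(z_fit[mask] - z[mask]) < 0.15 * np.abs(z[mask]))

    def test_antipodal_duplication_invariance(self, rng):
        truth = make_params(z=(-6.0, -3.0, -1.0, 0.0))
        zetas = sample_restraint(truth, 2000, seed=9)
        doubled = zetas + [RigidTransform(z.t, -z.q) for z in zetas]
        a = fit_restraint(zetas, range(len(zetas)))
        b = fit_restraint(doubled, range(len(doubled)))
        np.testing.assert_allclose(np.sort(a.z_diag), np.sort(b.z_diag),
                                   atol=1e-6)


class TestRestraintEnergy:
    def test_energy_zero_at_mode_under_gauge(self):
        params = make_params(mu=(1, 2, 3), z=(-5.0, -2.0, -1.0, 0.0))
        # mode: t = mu, q on the principal axis (last eigencolumn, M = I)
        zeta = RigidTransform(np.array([1.0, 2, 3]), [0, 0, 0, 1.0])
        assert restraint_energy(zeta, params, T) == pytest.approx(0.0, abs=1e-12)

    def test_one_mahalanobis_unit_is_half_kt(self):
        params = make_params(sigma=np.diag([4.0, 1.0, 1.0]), rotational=False)
        zeta = RigidTransform(np.array([2.0, 0, 0]), [1, 0, 0, 0])
        assert restraint_energy(zeta, params, T) == pytest.approx(0.5 * KT)

    def test_double_cover_invariance(self, rng):
        params = make_params(z=(-7.0, -3.0, -2.0, 0.0),
                             M=random_orthogonal_4(rng))
        for _ in range(100):
            t = rng.standard_normal(3)
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            e1 = reduced_restraint_energy(RigidTransform(t, canonical_quaternion(q)), params)
            e2 = reduced_restraint_energy(RigidTransform(t, canonical_quaternion(-q)), params)
            assert e1 == pytest.approx(e2, abs=1e-10)


class TestSampling:
    def test_moments_match_parameters(self):
        params = make_params(mu=(0.5, -0.5, 1.0),
                             sigma=np.diag([0.25, 0.5, 1.0]),
                             rotational=False)
        T_arr, _ = sample_restraint_arrays(params, 100_000, seed=3)
        assert np.linalg.norm(T_arr.mean(axis=0) - params.mu) < 0.02
        emp = np.cov(T_arr.T)
        assert np.all(np.abs(np.diag(emp) - np.diag(params.sigma))
                      < 0.05 * np.diag(params.sigma))

    def test_quaternions_unit_and_canonical(self):
        params = make_params(z=(-4.0, -2.0, -1.0, 0.0))
        zetas = sample_restraint(params, 2000, seed=1)
        Q = np.array([z.q for z in zetas])
        np.testing.assert_allclose(np.linalg.norm(Q, axis=1), 1.0, atol=1e-9)
        assert np.all(Q[:, 0] >= 0)

    def test_flat_bingham_scatter_is_isotropic(self):
        # Z = 0: uniform on S^3, scatter matrix = I/4
        params = make_params(z=(0.0, 0.0, 0.0, 0.0))
        _, Q = sample_restraint_arrays(params, 100_000, seed=2)
        scatter = (Q[:, :, None] * Q[:, None, :]).mean(axis=0)
        np.testing.assert_allclose(scatter, np.eye(4) / 4, atol=0.01)

    def test_sampler_density_histogram(self, rng):
        # chi^2 GOF: binned Bingham statistic s = q^T M Z M^T q of samples
        # against bin probabilities from an independent importance-weighted
        # uniform-S^3 oracle (weights e^s)
        z = np.array([-8.0, -4.0, -1.0, 0.0])
        params = make_params(z=z, M=random_orthogonal_4(rng))
        n = 50_000
        _, Q = sample_restraint_arrays(params, n, seed=4)
        s_obs = np.einsum("ni,ij,nj->n", Q @ params.M, np.diag(z),
                          Q @ params.M)
        U = rng.standard_normal((4_000_000, 4))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        s_mc = (U**2) @ z
        w_mc = np.exp(s_mc)
        edges = np.quantile(s_obs, np.linspace(0, 1, 51))
        edges[0], edges[-1] = -np.inf, np.inf
        obs, _ = np.histogram(s_obs, bins=edges)
        probs = np.array([w_mc[(s_mc >= edges[i]) & (s_mc < edges[i + 1])].sum()
                          for i in range(50)])
        probs /= probs.sum()
        expected = probs * n
        stat = np.sum((obs - expected) ** 2 / expected)
        p = 1.0 - chi2.cdf(stat, df=49)
        assert p > 0.01

    def test_translation_histogram_matches_energy(self):
        # radial Mahalanobis^2 of translation draws follows chi^2(3)
        params = make_params(sigma=np.diag([0.3, 0.5, 0.9]), rotational=False)
        T_arr, _ = sample_restraint_arrays(params, 50_000, seed=8)
        d = T_arr - params.mu
        m2 = np.einsum("ni,ij,nj->n", d, np.linalg.inv(params.sigma), d)
        edges = chi2.ppf(np.linspace(0, 1, 51), df=3)
        edges[-1] = np.inf
        obs, _ = np.histogram(m2, bins=edges)
        expected = np.full(50, len(m2) / 50)
        stat = np.sum((obs - expected) ** 2 / expected)
        assert 1.0 - chi2.cdf(stat, df=49) > 0.01


class TestPartitionFunction:
    def test_uniform_rotation_unit_gaussian_closed_form(self):
        params = make_params()
        expected = 1.5 * np.log(2 * np.pi) + np.log(2 * np.pi**2)
        assert restraint_log_partition(params) == pytest.approx(expected, rel=1e-9)

    def test_matches_monte_carlo_on_random_parameters(self, rng):
        # 5 random (Sigma, Z, M) sets against 10^6-point MC over S^3
        for _ in range(5):
            z = np.sort(np.append(-20 * rng.random(3), 0.0))
            M = random_orthogonal_4(rng)
            A = rng.standard_normal((3, 3))
            sigma = A @ A.T + 0.05 * np.eye(3)
            params = make_params(sigma=sigma, z=z, M=M)
            n = 1_000_000
            V = rng.standard_normal((n, 4))
            V /= np.linalg.norm(V, axis=1, keepdims=True)
            f = np.exp(np.einsum("ni,ij,nj->n", V @ M, np.diag(z), V @ M))
            mc_rot = S3_VOLUME * f.mean()
            mc_se = S3_VOLUME * f.std() / np.sqrt(n)
            quad_rot = np.exp(restraint_log_partition(params)
                              - 1.5 * np.log(2 * np.pi)
                              - 0.5 * np.linalg.slogdet(sigma)[1])
            assert abs(quad_rot - mc_rot) < 3 * mc_se

    def test_gauge_shift_scales_normalizer_exactly(self):
        z = np.array([-9.0, -3.0, -1.0, 0.0])
        for c in (-2.0, 1.5, 7.0):
            assert bingham.log_normalizer(z + c) == pytest.approx(
                bingham.log_normalizer(z) + c, rel=1e-8)

    def test_gauge_invariant_sampling(self):
        z = np.array([-5.0, -2.0, -1.0, 0.0])
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        a = bingham.sample_bingham(z, 500, rng1)
        b = bingham.sample_bingham(z - 3.0, 500, rng2)
        np.testing.assert_array_equal(a, b)


class TestReleaseFreeEnergy:
    def test_zero_when_restraint_volume_is_standard_volume(self):
        s2 = (V_STANDARD / (2 * np.pi) ** 1.5) ** (2.0 / 3.0)
        params = make_params(sigma=s2 * np.eye(3), rotational=False)
        assert delta_g_release(params, T) == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_closed_form(self):
        s2 = 0.49
        params = make_params(sigma=s2 * np.eye(3), rotational=False)
        expected = -KT * np.log((2 * np.pi * s2) ** 1.5 / V_STANDARD)
        assert delta_g_release(params, T) == pytest.approx(expected, rel=1e-10)

    def test_tightening_monotonically_raises_release_cost(self):
        values = [delta_g_release(make_params(sigma=s2 * np.eye(3),
                                              rotational=False), T)
                  for s2 in (4.0, 2.0, 1.0, 0.5, 0.25, 0.1)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_json_round_trip(self, rng):
        params = make_params(mu=(1, 2, 3), sigma=np.diag([0.2, 0.3, 0.4]),
                             z=(-5.0, -2.0, -1.0, 0.0),
                             M=random_orthogonal_4(rng))
        clone = RestraintParameters.from_json(params.to_json())
        np.testing.assert_allclose(clone.mu, params.mu)
        np.testing.assert_allclose(clone.sigma, params.sigma)
        np.testing.assert_allclose(clone.M, params.M)
        np.testing.assert_allclose(clone.Z, params.Z)
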
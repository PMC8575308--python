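import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaglv.dynamics import (
    SingularEquilibriumError,
    Trajectory,
    default_initial_state,
    discrete_laplacian,
    glv_rhs_nonspatial,
    glv_rhs_spatial,
    integrate,
    is_linearly_stable,
    jacobian_at,
    solve_feasible_fixed_point,
)
from metaglv.ensemble import Community, DispersalProfile, build_system
from metaglv.grids import GridGeometry


class TestGridGeometry:
    def test_ring_point_count(self):
        assert GridGeometry.ring(50).n_points == 50

    def test_torus_point_count(self):
        assert GridGeometry.torus(4, 6).n_points == 24

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ndim": 3, "extent": (2, 2, 2)},
            {"ndim": 1, "extent": (2, 2)},
            {"ndim": 1, "extent": (0,)},
            {"ndim": 1, "extent": (5,), "h": 0.0},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            GridGeometry(**kwargs)

    def test_dict_roundtrip(self):
        g = GridGeometry.torus(3, 5)
        assert GridGeometry.from_dict(g.to_dict()) == g


class TestNonspatialRhs:
    def test_zero_state_is_absorbing(self, small_community):
        rhs = glv_rhs_nonspatial(np.zeros(6), small_community)
        np.testing.assert_array_equal(rhs, np.zeros(6))

    def test_single_species_logistic(self, logistic_community):
        rhs = glv_rhs_nonspatial(np.array([0.5]), logistic_community)
        assert rhs[0] == pytest.approx(0.25, abs=1e-15)

    def test_rhs_vanishes_at_feasible_fixed_point(self):
        community, _, _ = build_system(N=20, sigma=0.05, seed=12)
        phi_star, feasible = solve_feasible_fixed_point(community)
        assert feasible
        rhs = glv_rhs_nonspatial(phi_star, community)
        assert np.max(np.abs(rhs)) < 1e-10

    def test_rejects_dimension_mismatch(self, small_community):
        with pytest.raises(ValueError):
            glv_rhs_nonspatial(np.ones(4), small_community)


class TestDiscreteLaplacian:
    def test_constant_field_maps_to_zero(self, ring5):
        out = discrete_laplacian(np.full(5, 3.7), ring5)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_ring_delta_stencil(self, ring5):
        out = discrete_laplacian(np.array([1.0, 0, 0, 0, 0]), ring5)
        np.testing.assert_array_equal(out, [-2.0, 1.0, 0.0, 0.0, 1.0])

    def test_torus_delta_stencil(self):
        geometry = GridGeometry.torus(4, 4)
        field = np.zeros((4, 4))
        field[1, 2] = 1.0
        out = discrete_laplacian(field, geometry)
        assert out[1, 2] == -4.0
        assert out[0, 2] == out[2, 2] == out[1, 1] == out[1, 3] == 1.0
        assert out.sum() == pytest.approx(0.0, abs=1e-14)

    def test_random_field_conserves_total(self, rng):
        geometry = GridGeometry.torus(6, 7)
        field = rng.normal(size=(42, 3))  # flattened points x species
        out = discrete_laplacian(field, geometry)
        total = np.abs(out.sum(axis=0))
        assert np.all(total < 1e-12 * max(1.0, np.abs(field).sum()))

    def test_shape_mismatch_rejected(self, ring5):
        with pytest.raises(ValueError):
            discrete_laplacian(np.zeros(7), ring5)

    def test_spacing_scales_inverse_square(self):
        g1 = GridGeometry.ring(5, h=1.0)
        g2 = GridGeometry.ring(5, h=2.0)
        field = np.array([1.0, 0, 0, 0, 0])
        np.testing.assert_allclose(
            discrete_laplacian(field, g1), 4.0 * discrete_laplacian(field, g2)
        )


class TestSpatialRhs:
    def test_zero_dispersal_equals_per_point_nonspatial(
        self, small_community, ring5, zero_dispersal, rng
    ):
        phi = rng.random((5, 6))
        out = glv_rhs_spatial(phi, small_community, zero_dispersal(6), ring5)
        expected = glv_rhs_nonspatial(phi, small_community)
        np.testing.assert_array_equal(out, expected)

    def test_uniform_state_kills_dispersal_term(self, small_community, ring5):
        dispersal = DispersalProfile(D=np.full(6, 0.5), mu_D=0.5)
        phi = np.tile(np.linspace(0.2, 1.0, 6), (5, 1))
        out = glv_rhs_spatial(phi, small_community, dispersal, ring5)
        expected = glv_rhs_nonspatial(phi, small_community)
        np.testing.assert_allclose(out, expected, atol=1e-13)

    def test_dispersal_contribution_conserves_totals(
        self, small_community, ring5, rng
    ):
        dispersal = DispersalProfile(D=rng.random(6), mu_D=0.5)
        phi = rng.random((5, 6))
        full = glv_rhs_spatial(phi, small_community, dispersal, ring5)
        local = glv_rhs_nonspatial(phi, small_community)
        transport = (full - local).sum(axis=0)
        assert np.max(np.abs(transport)) < 1e-12

    def test_shape_mismatch_rejected(self, small_community, ring5, zero_dispersal):
        with pytest.raises(ValueError):
            glv_rhs_spatial(
                np.ones((4, 6)), small_community, zero_dispersal(6), ring5
            )


class TestFeasibleFixedPoint:
    def test_sigma_zero_gives_carrying_capacity(self):
        community, _, _ = build_system(N=7, sigma=0.0, seed=1)
        phi_star, feasible = solve_feasible_fixed_point(community)
        np.testing.assert_allclose(phi_star, np.ones(7), atol=1e-12)
        assert feasible

    def test_small_sigma_simulation_converges_to_solution(self):
        community, _, _ = build_system(N=20, sigma=0.03, seed=4)
        phi_star, feasible = solve_feasible_fixed_point(community)
        assert feasible
        geometry = GridGeometry.single_point()
        phi0 = phi_star[None, :] * 1.1
        traj = integrate(community, None, geometry, phi0, t_end=120.0,
                         output_dt=1.0)
        assert np.max(np.abs(traj.phi[-1, 0] - phi_star)) < 1e-6

    def test_residual_of_linear_system(self):
        community, _, _ = build_system(N=15, sigma=0.1, seed=6)
        phi_star, _ = solve_feasible_fixed_point(community)
        residual = community.r * (1 - phi_star / community.K) + (
            community.sigma * community.A @ phi_star
        )
        assert np.max(np.abs(residual)) < 1e-10

    def test_singular_system_raises_dedicated_error(self):
        # sigma A with unit eigenvalue: A = I is forbidden (diagonal), use a
        # 2-cycle: (I - sigma A) singular at sigma = 1 with A = [[0,1],[1,0]]
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        community = Community(N=2, A=A, sigma=1.0)
        with pytest.raises(SingularEquilibriumError):
            solve_feasible_fixed_point(community)


class TestJacobian:
    def test_logistic_stable_at_K(self, logistic_community):
        J = jacobian_at(np.array([1.0]), logistic_community)
        assert J[0, 0] == pytest.approx(-1.0)
        assert is_linearly_stable(np.array([1.0]), logistic_community)

    def test_logistic_unstable_at_zero(self, logistic_community):
        J = jacobian_at(np.array([0.0]), logistic_community)
        assert J[0, 0] == pytest.approx(1.0)
        assert not is_linearly_stable(np.array([0.0]), logistic_community)

    def test_matches_finite_differences(self):
        community, _, _ = build_system(N=10, sigma=0.08, seed=2)
        phi_star, _ = solve_feasible_fixed_point(community)
        J = jacobian_at(phi_star, community)
        eps = 1e-7
        J_fd = np.empty_like(J)
        for j in range(10):
            dphi = np.zeros(10)
            dphi[j] = eps
            J_fd[:, j] = (
                glv_rhs_nonspatial(phi_star + dphi, community)
                - glv_rhs_nonspatial(phi_star - dphi, community)
            ) / (2 * eps)
        np.testing.assert_allclose(J, J_fd, atol=1e-6)


class TestIntegrate:
    def test_matches_analytic_logistic(self, logistic_community, single_point):
        phi0 = np.array([[0.01]])
        traj = integrate(logistic_community, None, single_point, phi0,
                         t_end=20.0, output_dt=0.25)
        t = traj.times
        analytic = 0.01 * np.exp(t) / (1 + 0.01 * (np.exp(t) - 1))
        np.testing.assert_allclose(traj.phi[:, 0, 0], analytic, atol=1e-6)

    def test_zero_dispersal_matches_decoupled_copies(self, zero_dispersal):
        community, _, _ = build_system(N=5, sigma=0.1, seed=8)
        geometry = GridGeometry.ring(4)
        rng = np.random.default_rng(0)
        phi0 = rng.random((4, 5)) + 0.1
        spatial = integrate(community, zero_dispersal(5), geometry, phi0,
                            t_end=40.0, output_dt=0.5)
        for m in range(4):
            solo = integrate(community, None, GridGeometry.single_point(),
                             phi0[m][None, :], t_end=40.0, output_dt=0.5)
            np.testing.assert_allclose(
                spatial.phi[:, m, :], solo.phi[:, 0, :], atol=5e-6
            )

    def test_uniform_initial_state_stays_uniform(self):
        community, dispersal, _ = build_system(
            N=5, sigma=0.15, mu_D=1.0, b=0.35, seed=9
        )
        geometry = GridGeometry.ring(6)
        phi0 = np.tile(np.linspace(0.3, 0.9, 5), (6, 1))
        traj = integrate(community, dispersal, geometry, phi0, t_end=50.0,
                         output_dt=0.5)
        spread = traj.phi.max(axis=1) - traj.phi.min(axis=1)
        assert spread.max() < 1e-8

    def test_pure_dispersal_conserves_species_totals(self):
        # r = 0, sigma = 0: only transport remains
        community = Community(
            N=3, A=np.zeros((3, 3)), r=np.zeros(3), K=np.ones(3), sigma=0.0
        )
        dispersal = DispersalProfile(D=np.array([0.1, 0.5, 1.0]), mu_D=0.5)
        geometry = GridGeometry.ring(8)
        rng = np.random.default_rng(3)
        phi0 = rng.random((8, 3))
        traj = integrate(community, dispersal, geometry, phi0, t_end=30.0,
                         output_dt=0.5)
        totals = traj.phi.sum(axis=1)
        rel = np.abs(totals - totals[0]) / totals[0]
        assert rel.max() < 1e-8

    def test_large_diffusion_synchronises_grid(self):
        community, dispersal, _ = build_system(
            N=10, sigma=0.2, mu_D=1.0, b=0.35, seed=21
        )
        geometry = GridGeometry.ring(10)
        phi0 = default_initial_state(community, geometry, seed=21)
        traj = integrate(community, dispersal, geometry, phi0, t_end=100.0,
                         output_dt=1.0)
        var0 = traj.phi[0].var(axis=0).mean()
        varT = traj.phi[-1].var(axis=0).mean()
        assert varT < 1e-6 * max(var0, 1e-30) or varT < 1e-12

    def test_halving_tolerances_changes_little(self):
        community, dispersal, _ = build_system(
            N=6, sigma=0.2, mu_D=1e-2, b=0.35, seed=13
        )
        geometry = GridGeometry.ring(5)
        phi0 = default_initial_state(community, geometry, seed=13)
        kw = dict(t_end=50.0, output_dt=0.5)
        t1 = integrate(community, dispersal, geometry, phi0,
                       rtol=1e-8, atol=1e-10, **kw)
        t2 = integrate(community, dispersal, geometry, phi0,
                       rtol=5e-9, atol=5e-11, **kw)
        diff = np.max(np.abs(t1.phi - t2.phi) / np.maximum(t2.phi, 1e-3))
        assert diff < 1e-5

    def test_divergence_is_flagged_not_raised(self, single_point):
        # positive feedback pair blows up in finite time
        A = np.array([[0.0, 5.0], [5.0, 0.0]])
        community = Community(N=2, A=A, sigma=2.0, c=1.0, mu=5.0)
        traj = integrate(community, None, single_point,
                         np.array([[2.0, 2.0]]), t_end=50.0, output_dt=0.1)
        assert traj.diverged
        assert np.all(np.isfinite(traj.phi))

    def test_nonnegative_output(self):
        community, _, _ = build_system(N=10, sigma=0.4, seed=30)
        geometry = GridGeometry.single_point()
        phi0 = default_initial_state(community, geometry, seed=30)
        traj = integrate(community, None, geometry, phi0, t_end=100.0,
                         output_dt=0.5)
        assert np.all(traj.phi >= 0)

    def test_rejects_negative_initial_state(self, logistic_community, single_point):
        with pytest.raises(ValueError):
            integrate(logistic_community, None, single_point,
                      np.array([[-0.1]]), t_end=1.0, output_dt=0.1)


class TestTrajectory:
    def test_rejects_nonuniform_times(self, ring5):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 1.0, 3.0]),
                       phi=np.zeros((3, 5, 2)), geometry=ring5)

    def test_rejects_negative_abundance(self, ring5):
        phi = np.zeros((3, 5, 2))
        phi[1, 2, 0] = -1e-3
        with pytest.raises(ValueError):
            Trajectory(times=np.arange(3.0), phi=phi, geometry=ring5)

    def test_after_slices_transient(self, ring5):
        traj = Trajectory(times=np.arange(10.0), phi=np.ones((10, 5, 2)),
                          geometry=ring5)
        tail = traj.after(5.0)
        assert tail.times[0] == 5.0
        assert tail.phi.shape == (5, 5, 2)

    def test_npz_roundtrip(self, tmp_path, ring5):
        from metaglv.io import load_trajectory, save_trajectory

        rng = np.random.default_rng(0)
        traj = Trajectory(times=np.arange(4.0), phi=rng.random((4, 5, 3)),
                          geometry=ring5, meta={"rtol": 1e-8})
        path = tmp_path / "traj.npz"
        save_trajectory(path, traj)
        back = load_trajectory(path)
        np.testing.assert_array_equal(back.phi, traj.phi)
        np.testing.assert_array_equal(back.times, traj.times)
        assert back.geometry == traj.geometry
        assert back.meta["rtol"] == 1e-8


class TestDefaultInitialState:
    def test_seeded_determinism(self):
        community, _, geometry = build_system(N=8, sigma=0.1, seed=3)
        a = default_initial_state(community, geometry, seed=3)
        b = default_initial_state(community, geometry, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_perturbation_varies_across_grid(self):
        community, _, geometry = build_system(N=8, sigma=0.1, seed=3)
        phi0 = default_initial_state(community, geometry, seed=3)
        assert phi0.std(axis=0).min() > 0

    def test_uniform_kind_in_unit_interval(self):
        community, _, geometry = build_system(N=8, seed=3)
        phi0 = default_initial_state(community, geometry, seed=3,
                                     kind="uniform")
        assert np.all(phi0 > 0) and np.all(phi0 <= 1)

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_strictly_positive_for_any_seed(self, seed):
        community, _, _ = build_system(N=5, sigma=0.1, seed=1)
        geometry = GridGeometry.ring(4)
        phi0 = default_initial_state(community, geometry, seed=seed)
        assert np.all(phi0 > 0)
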
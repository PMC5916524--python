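import numpy as np
import pytest

from spportrait import (
    FieldModel,
    boundary_maxima,
    classify,
    compute_portrait,
    detect_limit_cycle,
    find_fixed_points,
    integrate_trajectory,
    nullclines,
)
from spportrait.models import RM_LIMIT_CYCLE_OVERRIDES, fixture_network
from spportrait.phase_portrait import jacobian

UNIT_BOX = [(0.0, 1.0), (0.0, 1.0)]


def rotational_field(p):
    """Rotation plus radial attraction to the unit circle."""
    x, y = p
    r = np.hypot(x, y)
    pull = (1.0 - r) if r > 0 else 0.0
    return np.array([-y + x * pull, x + y * pull])


class TestJacobian:
    def test_linear_field(self):
        J = jacobian(lambda x: -np.asarray(x), np.array([0.3, -0.4]))
        assert J == pytest.approx(-np.eye(2), abs=1e-7)

    def test_ant_stochastic_jacobian(self, ant_model):
        # J_s = (eps - r/N) [[-1, 1], [1, -1]], eigenvalues {0, -2(eps - r/N)}
        r, eps, N = 7.5, 0.01, 1000.0
        pref = eps - r / N
        J = ant_model.jacobian_alpha([0.5, 0.5])
        assert J == pytest.approx(pref * np.array([[-1, 1], [1, -1]]))
        eig = np.sort(np.linalg.eigvals(J).real)
        assert eig == pytest.approx(sorted([0.0, -2 * pref]))

    def test_ant_deterministic_jacobian(self, ant_model):
        eps = 0.01
        J = ant_model.jacobian_f([0.5, 0.5])
        assert J == pytest.approx(eps * np.array([[-1, 1], [1, -1]]))
        eig = np.sort(np.linalg.eigvals(J).real)
        assert eig == pytest.approx([-2 * eps, 0.0])


class TestClassify:
    @pytest.mark.parametrize(
        "eigs, expected",
        [
            ([-1.0, -2.0], "stable-node"),
            ([-1.0 + 2.0j, -1.0 - 2.0j], "stable-spiral"),
            ([1.0, 2.0], "unstable-node"),
            ([0.5 + 1.0j, 0.5 - 1.0j], "unstable-spiral"),
            ([-1.0, 1.0], "saddle"),
            ([0.0, -2.0], "marginal/manifold"),
        ],
    )
    def test_sign_patterns(self, eigs, expected):
        assert classify(np.array(eigs)) == expected

    def test_ant_stability_flip(self, ant_net):
        # stable for r/N < eps, unstable (minimum) for r/N > eps
        for r, expected in [(5.0, -1), (15.0, +1)]:
            model = FieldModel.from_network(ant_net, params={"r": r}, N=1000)
            eig = np.linalg.eigvals(model.jacobian_alpha([0.5, 0.5]))
            nonzero = eig[np.argmax(np.abs(eig))]
            assert np.sign(nonzero.real) == expected


class TestFindFixedPoints:
    def test_ant_constrained_root_is_half(self, ant_model):
        # restricted to the conservation line the unique root is x1 = 1/2
        from spportrait import reduce_by_conservation
        from scipy.optimize import brentq

        red = reduce_by_conservation(ant_model, [1, 1], total=1.0)
        root = brentq(red.alpha, 0.01, 0.99)
        assert root == pytest.approx(0.5, abs=1e-12)

    def test_ant_unconstrained_manifold(self, ant_model):
        fps = find_fixed_points(
            ant_model.alpha, UNIT_BOX, n_starts=32, seed=4, jac=ant_model.jacobian_alpha
        )
        assert fps  # representatives of the fixed-point line x1 = x2
        for fp in fps:
            assert fp.location[0] == pytest.approx(fp.location[1], abs=1e-6)
            assert fp.classification == "marginal/manifold"

    def test_rm_interior_root(self, rm_model, rm_domain):
        fps = find_fixed_points(
            rm_model.alpha, rm_domain, n_starts=64, seed=1, jac=rm_model.jacobian_alpha
        )
        interior = [fp for fp in fps if np.all(fp.location > 0.05)]
        assert len(interior) == 1
        assert interior[0].location[0] == pytest.approx(3.0, rel=0.05)
        assert interior[0].is_stable
        assert interior[0].favorable_candidate

    def test_residuals_below_tolerance(self, rm_model, rm_domain):
        fps = find_fixed_points(rm_model.alpha, rm_domain, seed=0, jac=rm_model.jacobian_alpha)
        for fp in fps:
            assert np.linalg.norm(rm_model.alpha(fp.location)) < 1e-9

    def test_invariant_under_multistart_and_seed(self, rm_model, rm_domain):
        def locations(n_starts, seed):
            fps = find_fixed_points(
                rm_model.alpha, rm_domain, n_starts=n_starts, seed=seed,
                jac=rm_model.jacobian_alpha,
            )
            return sorted(tuple(np.round(fp.location, 6)) for fp in fps)

        base = locations(64, 0)
        assert locations(128, 0) == base
        assert locations(64, 123) == base

    def test_no_roots_returns_empty(self):
        fps = find_fixed_points(lambda x: np.array([1.0, 1.0]), UNIT_BOX, n_starts=8, seed=0)
        assert fps == []


class TestNullclines:
    def test_separable_field(self):
        lines = nullclines(lambda p: np.array([p[0] - 1.0, p[1] - 2.0]), [(0, 3), (0, 3)])
        (vert,) = lines[0]
        (horiz,) = lines[1]
        assert np.allclose(vert[:, 0], 1.0, atol=1e-9)
        assert np.allclose(horiz[:, 1], 2.0, atol=1e-9)

    def test_component_without_sign_change_is_empty(self):
        lines = nullclines(lambda p: np.array([1.0, p[1] - 1.0]), [(0, 2), (0, 2)])
        assert lines[0] == []
        assert len(lines[1]) == 1

    def test_resolution_floor(self, rm_model, rm_domain):
        with pytest.raises(ValueError, match="resolution"):
            nullclines(rm_model.alpha, rm_domain, resolution=8)

    def test_rm_families_intersect_at_large_N(self, rm_builder, rm_domain):
        model = rm_builder(1000)
        fps = find_fixed_points(model.alpha, rm_domain, seed=2, jac=model.jacobian_alpha)
        interior = [fp for fp in fps if np.all(fp.location > 0.05)]
        assert len(interior) == 1

    def test_rm_families_detach_at_small_N(self, rm_builder, rm_domain):
        # at N=10 the nullclines cease to intersect in the interior
        model = rm_builder(10)
        fps = find_fixed_points(model.alpha, rm_domain, n_starts=128, seed=2,
                                jac=model.jacobian_alpha)
        interior = [fp for fp in fps if np.all(fp.location > 0.05)]
        assert interior == []


class TestTrajectories:
    def test_stationary_at_fixed_point(self, rm_model, rm_domain):
        fps = find_fixed_points(rm_model.alpha, rm_domain, seed=1, jac=rm_model.jacobian_alpha)
        fp = next(f for f in fps if f.is_stable)
        path = integrate_trajectory(rm_model.alpha, fp.location, t_max=50.0)
        assert np.allclose(path.y, fp.location, atol=1e-6)

    def test_slides_to_boundary_maximum(self, rm_builder):
        # N=10: flow reaches the x-axis and slides to the boundary maximum
        model = rm_builder(10)
        path = integrate_trajectory(model.alpha, (2.0, 1.0), t_max=300.0)
        end = path.y[-1]
        assert end[1] == pytest.approx(0.0, abs=1e-6)
        assert end[0] == pytest.approx(4.0, rel=0.05)

    def test_converges_to_closed_orbit(self, rm_lc_net):
        model = FieldModel.from_network(rm_lc_net, N=2000)
        t_eval = np.linspace(0.0, 400.0, 8000)
        path = integrate_trajectory(model.alpha, (2.0, 1.0), 400.0, t_eval=t_eval)
        cycle = detect_limit_cycle(path, model.alpha, domain_diag=np.hypot(12, 3))
        assert cycle is not None
        assert cycle.period > 0
        # slow-transient mechanism: speed along the orbit is non-constant
        assert cycle.speed_ratio > 1.5


class TestLimitCycle:
    def test_rotational_field_radius(self):
        t_eval = np.linspace(0.0, 60.0, 4000)
        path = integrate_trajectory(rotational_field, (0.2, 0.0), 60.0,
                                    t_eval=t_eval, clip=False)
        cycle = detect_limit_cycle(path, rotational_field, domain_diag=np.sqrt(8.0))
        assert cycle is not None
        radii = np.linalg.norm(cycle.points, axis=1)
        assert np.abs(radii - 1.0).max() < 1e-3
        assert cycle.period == pytest.approx(2 * np.pi, rel=1e-3)
        # rotational symmetry: constant speed
        assert cycle.speeds.std() / cycle.speeds.mean() < 1e-3

    def test_converging_spiral_returns_none(self):
        field = lambda p: np.array([-0.2 * p[0] - p[1], p[0] - 0.2 * p[1]])
        t_eval = np.linspace(0.0, 80.0, 4000)
        path = integrate_trajectory(field, (1.0, 0.0), 80.0, t_eval=t_eval, clip=False)
        assert detect_limit_cycle(path, field, domain_diag=2.0) is None


class TestBoundaryMaxima:
    def test_rm_small_N_inflow(self, rm_builder, rm_domain):
        bms = [bm for bm in boundary_maxima(rm_builder(10).alpha, rm_domain) if bm.axis == 0]
        largest = max(bms, key=lambda bm: bm.location[0])
        assert largest.location[0] == pytest.approx(4.0, rel=0.05)
        assert largest.inflow

    def test_rm_limit_cycle_parameters(self, rm_lc_net):
        model = FieldModel.from_network(rm_lc_net, N=50)
        bms = [bm for bm in boundary_maxima(model.alpha, [(0, 15), (0, 3)]) if bm.axis == 0]
        largest = max(bms, key=lambda bm: bm.location[0])
        assert largest.location[0] == pytest.approx(9.0, rel=0.05)
        assert largest.inflow

    def test_rm_large_N_no_inflow(self, rm_builder, rm_domain):
        bms = [bm for bm in boundary_maxima(rm_builder(1000).alpha, rm_domain) if bm.axis == 0]
        largest = max(bms, key=lambda bm: bm.location[0])
        assert not largest.inflow

    def test_locations_lie_on_boundary(self, rm_builder, rm_domain):
        for bm in boundary_maxima(rm_builder(25).alpha, rm_domain):
            assert bm.location[1 - bm.axis] == 0.0


class TestPortraitAssembly:
    def test_compute_portrait(self, rm_model, rm_domain):
        pp = compute_portrait(
            rm_model.alpha, rm_domain, jac=rm_model.jacobian_alpha,
            resolution=12, nullcline_resolution=64, n_starts=32, seed=0,
            trajectories_from=[(2.0, 1.0)], t_max=30.0,
        )
        assert pp.grid.shape == (144, 2)
        assert pp.vectors.shape == (144, 2)
        assert pp.fixed_points
        assert len(pp.trajectories) == 1
        # every fixed point is near an intersection of the nullcline families
        for fp in pp.fixed_points:
            for comp in (0, 1):
                dmin = min(
                    np.linalg.norm(line - fp.location, axis=1).min()
                    for line in pp.nullclines[comp]
                )
                assert dmin < 0.15
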
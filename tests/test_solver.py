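import math

import numpy as np
import pytest
from scipy.special import gamma

from levyswitch import (
    Domain1D,
    ExteriorCondition,
    Grid,
    NoiseSpec,
    assemble_generator,
    brownian_fep_closed_form,
    brownian_mfet_closed_form,
    refine_until,
    solve_fep,
    solve_mfet,
)

from conftest import X_MINUS, X_U, zero_drift


def getoor_exit_time(x, alpha):
    """Closed-form mean exit time of the standard alpha-stable motion
    from (-1, 1) (no drift, unit intensity)."""
    x = np.asarray(x, dtype=float)
    return (
        (1 - x**2) ** (alpha / 2)
        * math.sqrt(math.pi)
        / (2**alpha * gamma(1 + alpha / 2) * gamma((1 + alpha) / 2))
    )


class TestAssembly:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    @pytest.mark.parametrize("mix", [(0.3, 0.7), (0.5, 0.5), (1.0, 0.0)])
    def test_generator_annihilates_constants(self, params, low_region, alpha, mix):
        sigma, eps = mix
        gm = assemble_generator(
            Grid(low_region, 64),
            params,
            NoiseSpec(sigma, eps, alpha),
            ExteriorCondition("constant", value=1.0),
        )
        resid = gm.apply(np.ones(gm.matrix.shape[0]))
        assert np.max(np.abs(resid)) < 1e-8

    def test_pure_diffusion_matrix_is_tridiagonal(self, params, low_region):
        gm = assemble_generator(
            Grid(low_region, 64), params, NoiseSpec(0.5, 0.0), ExteriorCondition("zero")
        )
        assert gm.is_tridiagonal
        off = gm.matrix - np.triu(np.tril(gm.matrix, 1), -1)
        assert np.max(np.abs(off)) == 0.0

    def test_exterior_tail_mass_positive_for_jumps(self, params, low_region):
        gm = assemble_generator(
            Grid(low_region, 64),
            params,
            NoiseSpec(0.0, 0.5, 1.5),
            ExteriorCondition("zero"),
        )
        assert np.all(gm.tail_mass > 0)

    def test_coarse_grid_rejected(self, low_region):
        with pytest.raises(ValueError, match="16 interior"):
            Grid(low_region, 16)

    def test_unbounded_solve_domain_rejected(self):
        with pytest.raises(ValueError, match="bounded"):
            Grid(Domain1D.interval(0.0, np.inf), 100)


class TestMFETSolver:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_pure_jump_ball_exit_time(self, alpha):
        # independent closed form for the driftless stable motion
        sol = solve_mfet(
            Domain1D.interval(-1.0, 1.0), zero_drift, NoiseSpec(0.0, 1.0, alpha), J=400
        )
        xs = np.array([-0.5, 0.0, 0.3, 0.8])
        rel = np.abs(sol(xs) - getoor_exit_time(xs, alpha)) / getoor_exit_time(xs, alpha)
        assert np.max(rel) < 0.01

    def test_brownian_matches_quadrature_oracle(self, params, low_region):
        sol = solve_mfet(low_region, params, NoiseSpec(0.5, 0.0), J=400)
        xs = np.linspace(0.05, X_U - 0.05, 40)
        exact = brownian_mfet_closed_form(params, 0.5, (0.0, X_U), xs)
        assert np.max(np.abs(sol(xs) - exact) / exact) < 5e-3

    def test_nonnegative_and_zero_at_boundary(self, params, low_region):
        sol = solve_mfet(low_region, params, NoiseSpec(0.2, 0.8, 1.5), J=200)
        assert np.all(sol.values >= 0)
        xs, vs = sol.interval_arrays(0)
        assert vs[0] == 0.0 and vs[-1] == 0.0
        assert vs[1] < vs[len(vs) // 2]  # decays toward the exterior

    @pytest.mark.parametrize("alpha", [0.5, 1.5])
    def test_monotone_in_levy_intensity(self, params, low_region, alpha):
        u_weak = solve_mfet(low_region, params, NoiseSpec(0.0, 0.25, alpha), J=200)
        u_strong = solve_mfet(low_region, params, NoiseSpec(0.0, 1.0, alpha), J=200)
        assert np.all(u_strong.values < u_weak.values)


class TestFEPSolver:
    def test_full_complement_target_certain(self, params, low_region):
        full = Domain1D([(-np.inf, 0.0), (X_U, np.inf)])
        sol = solve_fep(low_region, full, params, NoiseSpec(0.2, 0.8, 1.5), J=100)
        assert np.max(np.abs(sol.values - 1.0)) < 1e-6

    def test_brownian_matches_scale_function(self, params, low_region):
        sol = solve_fep(
            low_region, Domain1D.interval(X_U, np.inf), params, NoiseSpec(0.5, 0.0), J=400
        )
        xs = np.linspace(0.05, X_U - 0.05, 40)
        exact = brownian_fep_closed_form(params, 0.5, (0.0, X_U), xs)
        assert np.max(np.abs(sol(xs) - exact)) < 1e-3

    def test_brownian_cannot_reach_detached_target(self, params, low_region):
        sol = solve_fep(
            low_region, Domain1D.interval(3.0, 5.0), params, NoiseSpec(0.5, 0.0), J=200
        )
        assert np.max(np.abs(sol.values)) < 1e-8

    @pytest.mark.parametrize(
        "noise", [NoiseSpec(0.3, 0.7, 1.5), NoiseSpec(0.5, 0.5, 0.5)]
    )
    def test_complementary_targets_sum_to_one(self, params, low_region, noise):
        left = solve_fep(low_region, Domain1D.interval(-np.inf, 0.0), params, noise, J=100)
        right = solve_fep(low_region, Domain1D.interval(X_U, np.inf), params, noise, J=100)
        assert np.max(np.abs(left.values + right.values - 1.0)) < 1e-6

    def test_probability_bounds(self, params, low_region):
        sol = solve_fep(
            low_region, Domain1D.interval(3.0, 5.0), params, NoiseSpec(0.5, 0.5, 0.5), J=200
        )
        assert sol.values.min() >= -1e-8
        assert sol.values.max() <= 1 + 1e-8

    def test_target_overlapping_domain_rejected(self, params, low_region):
        with pytest.raises(ValueError, match="overlap"):
            solve_fep(
                low_region, Domain1D.interval(1.0, 2.0), params, NoiseSpec(0.5, 0.0), J=100
            )


class TestRefinement:
    def test_brownian_convergence_order(self, params, low_region):
        # Richardson estimate of the order against the closed form
        xs = np.linspace(0.1, X_U - 0.1, 20)
        exact = brownian_mfet_closed_form(params, 0.5, (0.0, X_U), xs)
        errs = []
        for J in (50, 100, 200):
            sol = solve_mfet(low_region, params, NoiseSpec(0.5, 0.0), J=J)
            errs.append(np.max(np.abs(sol(xs) - exact)))
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) >= 1.8

    def test_jump_self_convergence(self, params, low_region):
        sol = refine_until(
            low_region, params, NoiseSpec(0.0, 0.5, 1.5), kind="mfet", tol=5e-3, J0=50
        )
        changes = [c for _, c in sol.convergence[1:]]
        assert changes[-1] < 5e-3
        assert all(b < a for a, b in zip(changes, changes[1:]))  # contracting

    def test_infinite_tolerance_returns_first_solve(self, params, low_region):
        sol = refine_until(
            low_region, params, NoiseSpec(0.5, 0.0), kind="mfet", tol=math.inf, J0=64
        )
        assert sol.grid.J == 64
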
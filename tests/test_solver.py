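"""Moving-domain solver: tip laws, RHS arithmetic, boundary conditions,
closed-form oracles, and convergence behavior."""

import dataclasses

import numpy as np
import pytest

from mtends import (
    FullFieldState,
    ScenarioConfig,
    SolverConfig,
    TipParams,
    apply_boundary_conditions,
    full_rhs,
    refinement_error,
    robin_steady_profile,
    simulate_full,
    simulate_reduced_pde,
    steady_profile_plus,
    tip_velocities_full,
)
from mtends.errors import InvalidParameterError, InvalidStateError


def make_state(n=33, L0=10.0, p=None, c=None, m=None, f=None):
    xi = np.linspace(0.0, 1.0, n)
    one = np.ones(n)
    return FullFieldState(
        xi=xi,
        p=one.copy() if p is None else p,
        c=one.copy() if c is None else c,
        m=one.copy() if m is None else m,
        f=one.copy() if f is None else f,
        L_minus=0.0,
        L_plus=L0,
        t=0.0,
    )


ZERO_TIPS = TipParams(0, 0, 0, 0, 0, 0)


class TestTipVelocities:
    def test_all_rates_zero(self):
        assert tip_velocities_full(5.0, 1.0, 1.0, ZERO_TIPS) == (0.0, 0.0)

    def test_baseline_arithmetic(self, base_params):
        dLp, dLm = tip_velocities_full(10.0, 1.0, 1.0, base_params.tips)
        assert dLp == pytest.approx(0.15 - 0.5 - 0.01, rel=1e-12)

    def test_balancing_density_stalls_plus_end(self, base_params):
        tips = dataclasses.replace(base_params.tips, beta_plus=0.0116)
        p_balance = (0.15 - 0.116) / 0.01
        dLp, _ = tip_velocities_full(10.0, p_balance, 1.0, tips)
        assert dLp == pytest.approx(0.0, abs=1e-14)

    def test_negative_length_rejected(self, base_params):
        with pytest.raises(InvalidStateError):
            tip_velocities_full(-1.0, 1.0, 1.0, base_params.tips)


class TestFullRHS:
    def test_pure_reaction_on_uniform_fields(self, base_params):
        """Uniform fields kill transport; the interior rates are the binding
        reaction terms: dp = k_on*c - k_off*p = 0.75 and dc = -0.75."""
        params = dataclasses.replace(base_params, tips=ZERO_TIPS)
        dp, dc, dm, df, dLp, dLm = full_rhs(make_state(), params)
        assert (dLp, dLm) == (0.0, 0.0)
        assert dp[1:-1] == pytest.approx(0.75, rel=1e-12)
        assert dc[1:-1] == pytest.approx(-0.75, rel=1e-12)

    def test_binding_equilibrium_ratio(self, base_params):
        params = dataclasses.replace(base_params, tips=ZERO_TIPS)
        ratio = params.plus_motor.k_on / params.plus_motor.k_off
        st = make_state(p=np.full(33, ratio))
        dp = full_rhs(st, params)[0]
        assert np.max(np.abs(dp[1:-1])) < 1e-13

    def test_freezing_tips_matches_static_tip_parameters(self, base_params):
        """ALE consistency: with stationary tips the mesh-motion term
        vanishes and the RHS equals the fixed-domain discretization."""
        params = dataclasses.replace(base_params, tips=ZERO_TIPS)
        rng = np.random.default_rng(3)
        st = make_state(p=rng.uniform(0.5, 2, 33), c=rng.uniform(0.5, 2, 33),
                        m=rng.uniform(0.5, 2, 33), f=rng.uniform(0.5, 2, 33))
        static = full_rhs(st, params, freeze_tips=False)
        frozen = full_rhs(st, params, freeze_tips=True)
        for a, b in zip(static[:4], frozen[:4]):
            assert np.max(np.abs(a - b)) < 1e-12


class TestBoundaryConditions:
    def test_dirichlet_and_neumann_values(self):
        rng = np.random.default_rng(11)
        st = make_state(p=rng.uniform(0, 3, 33), c=rng.uniform(0, 3, 33),
                        m=rng.uniform(0, 3, 33), f=rng.uniform(0, 3, 33))
        out = apply_boundary_conditions(st)
        assert out.p[0] == 1.0 and out.c[0] == 1.0 and out.f[0] == 1.0
        assert out.c[-1] == 1.0 and out.m[-1] == 1.0 and out.f[-1] == 1.0
        assert out.m[0] == out.m[1]          # zero one-sided gradient
        assert out.p[-1] == out.p[-2]

    def test_idempotent(self):
        st = apply_boundary_conditions(make_state())
        again = apply_boundary_conditions(st)
        for name in ("p", "c", "m", "f"):
            assert np.array_equal(getattr(st, name), getattr(again, name))

    def test_linear_profile_flattened_at_plus_end(self):
        n = 33
        st = make_state(p=np.linspace(1.0, 4.0, n))
        out = apply_boundary_conditions(st)
        dxi = 1.0 / (n - 1)
        one_sided = (out.p[-1] - out.p[-2]) / dxi
        assert one_sided == 0.0


class TestSimulateFull:
    def test_motor_decoupled_linear_growth(self, base_params, fast_solver):
        tips = TipParams(0.05, 0.01, 0.0, 0.0, 0.0, 0.0)
        sc = ScenarioConfig(
            name="grow", params=dataclasses.replace(base_params, tips=tips),
            L0=5.0, t_end=60.0,
        )
        tr = simulate_full(sc, fast_solver)
        assert tr.length_series[-1] == pytest.approx(5.0 + 0.06 * 60.0, abs=1e-6)

    def test_motor_decoupled_exponential_relaxation(self, base_params, fast_solver, rng):
        """With gamma = 0 the length obeys dL/dt = (a++a-) - (b++b-)L
        exactly; two random draws against the closed form."""
        for _ in range(2):
            a_p, a_m = rng.uniform(0.01, 0.2, 2)
            b_p, b_m = rng.uniform(0.002, 0.05, 2)
            tips = TipParams(a_p, a_m, b_p, b_m, 0.0, 0.0)
            sc = ScenarioConfig(
                name="dec", params=dataclasses.replace(base_params, tips=tips),
                L0=10.0, t_end=100.0,
            )
            solver = dataclasses.replace(fast_solver, L_max=400.0)
            tr = simulate_full(sc, solver)
            L_star = (a_p + a_m) / (b_p + b_m)
            exact = L_star + (10.0 - L_star) * np.exp(-(b_p + b_m) * tr.times)
            assert np.max(np.abs(tr.length_series - exact)) < 1e-3

    def test_dirichlet_exact_and_densities_positive(self, base_params):
        sc = ScenarioConfig(
            name="tread", params=base_params.replace_tips(beta_plus=0.0116),
            L0=10.0, t_end=120.0,
        )
        tr = simulate_full(sc, SolverConfig(n_cells=48, store_snapshots=True))
        assert tr.snapshots
        for snap in tr.snapshots:
            assert snap.p[0] == 1.0 and snap.c[0] == 1.0 and snap.f[0] == 1.0
            assert snap.c[-1] == 1.0 and snap.m[-1] == 1.0 and snap.f[-1] == 1.0
            for arr in (snap.p, snap.c, snap.m, snap.f):
                assert arr.min() >= -1e-8

    def test_length_identity_and_termination_flags(self, base_params, fast_solver):
        # pure shrink: no growth, only intrinsic disassembly
        tips = TipParams(0.0, 0.0, 0.05, 0.0006, 0.0, 0.0)
        sc = ScenarioConfig(
            name="shrink", params=dataclasses.replace(base_params, tips=tips),
            L0=5.0, t_end=500.0,
        )
        tr = simulate_full(sc, fast_solver)
        assert tr.termination == "disassembled"
        assert tr.final_length <= fast_solver.L_min + 1e-6
        assert tr.length_series == pytest.approx(
            tr.L_plus_series - tr.L_minus_series, abs=0
        )

    def test_runaway_cap(self, base_params, fast_solver):
        tips = TipParams(0.1, 0.1, 0.0, 0.0, 0.0, 0.0)
        sc = ScenarioConfig(
            name="run", params=dataclasses.replace(base_params, tips=tips),
            L0=5.0, t_end=1000.0,
        )
        solver = dataclasses.replace(fast_solver, L_max=20.0)
        tr = simulate_full(sc, solver)
        assert tr.termination == "runaway"
        assert tr.final_length == pytest.approx(20.0, abs=1e-6)

    def test_deterministic_repeat(self, base_params, fast_solver):
        sc = ScenarioConfig(name="det", params=base_params, L0=10.0, t_end=30.0)
        a = simulate_full(sc, fast_solver)
        b = simulate_full(sc, fast_solver)
        assert np.array_equal(a.length_series, b.length_series)

    def test_config_validation(self, base_params):
        sc = ScenarioConfig(name="bad", params=base_params, L0=10.0, t_end=10.0)
        with pytest.raises(InvalidParameterError):
            simulate_full(sc, SolverConfig(n_cells=8))
        with pytest.raises(InvalidParameterError):
            simulate_full(sc, SolverConfig(L_min=11.0, L_max=50.0))


class TestSimulateReduced:
    def test_frozen_tips_minus_profile_relaxes_to_one(self, base_params, eff):
        sc = ScenarioConfig(name="relax", params=base_params, L0=10.0, t_end=400.0)
        solver = SolverConfig(n_cells=64, freeze_tips=True,
                              ic_mode="zero-interior", store_snapshots=True)
        tr = simulate_reduced_pde(eff, base_params.tips, sc, solver)
        h = tr.snapshots[-1].h
        assert np.max(np.abs(h - 1.0)) < 1e-6
        assert tr.snapshots[-1].q[0] == 1.0  # Dirichlet held exactly

    def test_frozen_tips_plus_profile_matches_closed_form(self, base_params, eff):
        """With the flux RHS paired consistently (-1), the discrete steady
        state reproduces the closed-form exponential profile."""
        sc = ScenarioConfig(name="steady", params=base_params, L0=10.0, t_end=3000.0)
        solver = SolverConfig(n_cells=200, freeze_tips=True,
                              advection_scheme="central", store_snapshots=True)
        tr = simulate_reduced_pde(eff, base_params.tips, sc, solver, q_robin_rhs=-1.0)
        snap = tr.snapshots[-1]
        expected = steady_profile_plus(snap.x, snap.x[0], eff)
        assert np.max(np.abs(snap.q - expected)) < 1e-4

    def test_decoupled_linear_growth(self, base_params, eff):
        tips = TipParams(0.05, 0.01, 0.0, 0.0, 0.0, 0.0)
        sc = ScenarioConfig(name="grow", params=base_params, L0=5.0, t_end=60.0)
        solver = SolverConfig(n_cells=32, store_snapshots=False)
        tr = simulate_reduced_pde(eff, tips, sc, solver)
        assert tr.length_series[-1] == pytest.approx(5.0 + 0.06 * 60.0, abs=1e-6)

    def test_robin_rhs_controls_steady_tip_value(self, base_params, eff):
        """The discrete steady q at the plus end follows the general Robin
        solution for either sign of the flux datum."""
        sc = ScenarioConfig(name="rhs", params=base_params, L0=10.0, t_end=3000.0)
        solver = SolverConfig(n_cells=100, freeze_tips=True,
                              advection_scheme="central", store_snapshots=True)
        for rhs in (1.0, -1.0):
            tr = simulate_reduced_pde(eff, base_params.tips, sc, solver,
                                      q_robin_rhs=rhs)
            snap = tr.snapshots[-1]
            expected = robin_steady_profile(snap.x, snap.x[0], eff, rhs=rhs)
            assert np.max(np.abs(snap.q - expected)) < 5e-3 * max(
                1.0, np.max(np.abs(expected))
            )


class TestRefinement:
    def test_decoupled_scenario_is_grid_independent(self, base_params):
        tips = TipParams(0.05, 0.01, 0.005, 0.001, 0.0, 0.0)
        sc = ScenarioConfig(
            name="dec", params=dataclasses.replace(base_params, tips=tips),
            L0=10.0, t_end=60.0,
        )
        err = refinement_error(sc, SolverConfig(n_cells=24, store_snapshots=False), 2)
        assert err <= 1e-6

    def test_doubling_cells_reduces_error(self, base_params):
        sc = ScenarioConfig(
            name="tread", params=base_params.replace_tips(beta_plus=0.0116),
            L0=10.0, t_end=120.0,
        )
        coarse = refinement_error(sc, SolverConfig(n_cells=24, store_snapshots=False), 2)
        fine = refinement_error(sc, SolverConfig(n_cells=48, store_snapshots=False), 2)
        assert fine < coarse

    def test_invalid_factor(self, base_params, fast_solver):
        sc = ScenarioConfig(name="x", params=base_params, L0=10.0, t_end=10.0)
        with pytest.raises(InvalidParameterError):
            refinement_error(sc, fast_solver, 1)
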
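"""Moving-domain solver for the motor-density PDEs coupled to tip dynamics.

The physical domain [L₋(t), L₊(t)] is mapped to the fixed reference interval
ξ ∈ [0, 1] via x = L₋ + ξ·L (an arbitrary Lagrangian–Eulerian transform).
In reference coordinates each density u gains a mesh-motion advection term:

    ∂u/∂t|_ξ = −(v − ẋ(ξ)) ∂u/∂x + D ∂²u/∂x² + reactions,
    ẋ(ξ) = dL₋/dt + ξ (dL₊/dt − dL₋/dt),   ∂/∂x = (1/L) ∂/∂ξ.

Spatial discretization is second-order central for diffusion and first-order
upwind on the *total* advection velocity (physical minus mesh), which keeps
densities non-negative.  The concatenated state (all field nodes plus both
tip positions) is integrated with a stiff adaptive method (BDF) using an
explicit Jacobian sparsity pattern.

Boundary conditions are enforced exactly at every accepted step by evolving
boundary nodes consistently: Dirichlet nodes carry zero time derivative,
zero-gradient (vanishing Fickian flux) nodes copy their neighbour's
derivative, and Robin nodes of the reduced model evolve by the exact time
derivative of the discrete constraint.

Full model fields: p (bound plus-motors), c (free plus-motors), m (bound
minus-motors), f (free minus-motors).  Reduced model fields: q = p + c and
h = m + f with kinetically averaged coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .errors import (
    InvalidParameterError,
    InvalidStateError,
    NumericalFailureError,
)
from .params import ModelParams, ScenarioConfig, TipParams
from .reduced import EffectiveParams

__all__ = [
    "SolverConfig",
    "FullFieldState",
    "ReducedFieldState",
    "Trajectory",
    "tip_velocities_full",
    "full_rhs",
    "apply_boundary_conditions",
    "simulate_full",
    "simulate_reduced_pde",
    "refinement_error",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for the moving-domain integrator.

    ``n_cells`` is the number of reference-grid cells (``n_cells + 1``
    nodes).  ``L_min``/``L_max`` are termination cutoffs: the transformed
    equations are singular as L → 0, so a run is declared *disassembled*
    when the length reaches ``L_min`` and *runaway* at ``L_max``.
    ``freeze_tips`` pins both tips (used to study relaxation of the motor
    fields on a static domain).  ``ic_mode`` selects the initial densities:
    ``uniform-one`` (reservoir value everywhere), ``zero-interior``
    (boundary data only), or ``custom`` with ``custom_ic(xi) -> array``
    applied to every field.
    """

    n_cells: int = 100
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    L_min: float = 0.1
    L_max: float = 100.0
    save_every: float = 1.0
    ic_mode: str = "uniform-one"
    freeze_tips: bool = False
    method: str = "BDF"
    advection_scheme: str = "upwind"
    store_snapshots: bool = True
    custom_ic: Callable[[np.ndarray], np.ndarray] | None = None

    def validate(self, L0: float | None = None) -> None:
        if self.n_cells < 16:
            raise InvalidParameterError("n_cells must be >= 16")
        if not (0 < self.L_min < self.L_max):
            raise InvalidParameterError("need 0 < L_min < L_max")
        if L0 is not None and not (self.L_min < L0 < self.L_max):
            raise InvalidParameterError(
                f"L0 = {L0} must lie in (L_min, L_max) = "
                f"({self.L_min}, {self.L_max})"
            )
        if self.ic_mode not in ("uniform-one", "zero-interior", "custom"):
            raise InvalidParameterError(f"unknown ic_mode {self.ic_mode!r}")
        if self.ic_mode == "custom" and self.custom_ic is None:
            raise InvalidParameterError("ic_mode 'custom' requires custom_ic")
        if self.advection_scheme not in ("upwind", "central"):
            raise InvalidParameterError(
                f"unknown advection_scheme {self.advection_scheme!r}"
            )


@dataclass(frozen=True)
class FullFieldState:
    """Snapshot of the full model on the reference grid."""

    xi: np.ndarray
    p: np.ndarray
    c: np.ndarray
    m: np.ndarray
    f: np.ndarray
    L_minus: float
    L_plus: float
    t: float

    @property
    def length(self) -> float:
        return self.L_plus - self.L_minus

    @property
    def x(self) -> np.ndarray:
        """Physical node positions (µm)."""
        return self.L_minus + self.xi * self.length


@dataclass(frozen=True)
class ReducedFieldState:
    """Snapshot of the reduced two-field model on the reference grid."""

    xi: np.ndarray
    q: np.ndarray
    h: np.ndarray
    L_minus: float
    L_plus: float
    t: float

    @property
    def length(self) -> float:
        return self.L_plus - self.L_minus

    @property
    def x(self) -> np.ndarray:
        return self.L_minus + self.xi * self.length


@dataclass(frozen=True)
class Trajectory:
    """Time series of tip positions, length, and tip velocities.

    ``termination`` is ``completed`` (horizon reached), ``disassembled``
    (length hit the L_min cutoff), or ``runaway`` (length hit L_max).
    ``snapshots`` holds the saved field states when requested.
    """

    times: np.ndarray
    L_minus_series: np.ndarray
    L_plus_series: np.ndarray
    length_series: np.ndarray
    tip_velocity_series: np.ndarray  # shape (k, 2): (dL+/dt, dL-/dt)
    termination: str
    snapshots: list = field(default_factory=list)

    @property
    def final_length(self) -> float:
        return float(self.length_series[-1])


def tip_velocities_full(
    L: float, p_at_plus: float, m_at_minus: float, tips: TipParams
) -> tuple[float, float]:
    """Tip velocities (dL₊/dt, dL₋/dt) given the length and the motor
    densities at the respective tips:

        dL₊/dt = α₊ − β₊ L − γ₊ p(L₊)
        dL₋/dt = −α₋ + β₋ L + γ₋ m(L₋)
    """
    if L < 0:
        raise InvalidStateError(f"length must be non-negative, got {L}")
    dLp = tips.alpha_plus - tips.beta_plus * L - tips.gamma_plus * p_at_plus
    dLm = -tips.alpha_minus + tips.beta_minus * L + tips.gamma_minus * m_at_minus
    return dLp, dLm


def _upwind_gradient(u: np.ndarray, a: np.ndarray, h: float) -> np.ndarray:
    """First-order upwind one-sided derivative at interior nodes."""
    g = np.zeros_like(u)
    bwd = (u[1:-1] - u[:-2]) / h
    fwd = (u[2:] - u[1:-1]) / h
    g[1:-1] = np.where(a[1:-1] > 0.0, bwd, fwd)
    return g


def _central_gradient(u: np.ndarray, a: np.ndarray, h: float) -> np.ndarray:
    """Second-order central derivative at interior nodes (appropriate when
    the cell Péclet number is small)."""
    g = np.zeros_like(u)
    g[1:-1] = (u[2:] - u[:-2]) / (2.0 * h)
    return g


def _gradient(u: np.ndarray, a: np.ndarray, h: float, scheme: str) -> np.ndarray:
    if scheme == "central":
        return _central_gradient(u, a, h)
    return _upwind_gradient(u, a, h)


def _laplacian(u: np.ndarray, h: float) -> np.ndarray:
    lap = np.zeros_like(u)
    lap[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / (h * h)
    return lap


def _full_rhs_core(
    p: np.ndarray,
    c: np.ndarray,
    m: np.ndarray,
    f: np.ndarray,
    L_minus: float,
    L_plus: float,
    params: ModelParams,
    xi: np.ndarray,
    dxi: float,
    freeze_tips: bool,
    scheme: str = "upwind",
):
    L = L_plus - L_minus
    if not np.isfinite(L) or L <= 0:
        raise InvalidStateError(f"non-positive or non-finite length L = {L}")
    if freeze_tips:
        dLp = dLm = 0.0
    else:
        dLp, dLm = tip_velocities_full(L, p[-1], m[0], params.tips)
    xdot = dLm + xi * (dLp - dLm)
    h = L * dxi
    pm, mm = params.plus_motor, params.minus_motor

    # total advection velocities (physical minus mesh); the bound minus
    # motor walks toward the minus end, i.e. physical velocity -v
    a_p = pm.v - xdot
    a_c = -xdot
    a_m = -mm.v - xdot
    a_f = -xdot

    dp = -a_p * _gradient(p, a_p, h, scheme) + pm.D_on * _laplacian(p, h)
    dp += pm.k_on * c - pm.k_off * p
    dc = -a_c * _gradient(c, a_c, h, scheme) + pm.D_off * _laplacian(c, h)
    dc += -pm.k_on * c + pm.k_off * p
    dm = -a_m * _gradient(m, a_m, h, scheme) + mm.D_on * _laplacian(m, h)
    dm += mm.k_on * f - mm.k_off * m
    df = -a_f * _gradient(f, a_f, h, scheme) + mm.D_off * _laplacian(f, h)
    df += -mm.k_on * f + mm.k_off * m

    # boundary rows: Dirichlet nodes are constant; zero-gradient nodes
    # track their neighbour so the one-sided derivative stays zero
    dp[0] = 0.0          # p(L-) = 1
    dc[0] = 0.0          # c(L-) = 1
    df[0] = 0.0          # f(L-) = 1
    dm[0] = dm[1]        # dm/dx|_{L-} = 0
    dc[-1] = 0.0         # c(L+) = 1
    dm[-1] = 0.0         # m(L+) = 1
    df[-1] = 0.0         # f(L+) = 1
    dp[-1] = dp[-2]      # dp/dx|_{L+} = 0
    return dp, dc, dm, df, dLp, dLm


def full_rhs(
    state: FullFieldState, params: ModelParams, freeze_tips: bool = False
):
    """Time derivatives of all four fields and both tips for the full model.

    Returns ``(dp, dc, dm, df, dL_plus_dt, dL_minus_dt)`` on the reference
    grid, with boundary rows already made consistent with the boundary
    conditions.
    """
    for name, arr in (("p", state.p), ("c", state.c), ("m", state.m), ("f", state.f)):
        if not np.all(np.isfinite(arr)):
            raise NumericalFailureError(f"non-finite values in field {name}")
    n = state.xi.size
    dxi = 1.0 / (n - 1)
    return _full_rhs_core(
        state.p, state.c, state.m, state.f,
        state.L_minus, state.L_plus, params, state.xi, dxi, freeze_tips,
    )


def apply_boundary_conditions(state: FullFieldState) -> FullFieldState:
    """Impose the full-model boundary conditions on a field state.

    Minus end (ξ=0): p = c = f = 1 (reservoir), ∂m/∂x = 0.  Plus end (ξ=1):
    c = m = f = 1, ∂p/∂x = 0.  Zero gradients use the one-sided discrete
    derivative, i.e. the boundary node copies its neighbour.  Idempotent.
    """
    p = state.p.copy()
    c = state.c.copy()
    m = state.m.copy()
    f = state.f.copy()
    p[0] = 1.0
    c[0] = 1.0
    f[0] = 1.0
    c[-1] = 1.0
    m[-1] = 1.0
    f[-1] = 1.0
    m[0] = m[1]
    p[-1] = p[-2]
    return replace(state, p=p, c=c, m=m, f=f)


def _initial_field(solver: SolverConfig, xi: np.ndarray) -> np.ndarray:
    if solver.ic_mode == "uniform-one":
        return np.ones_like(xi)
    if solver.ic_mode == "zero-interior":
        return np.zeros_like(xi)
    out = np.asarray(solver.custom_ic(xi), dtype=float)
    if out.shape != xi.shape:
        raise InvalidParameterError("custom_ic must return one value per node")
    return out


def _full_sparsity(n: int) -> lil_matrix:
    size = 4 * n + 2
    S = lil_matrix((size, size), dtype=np.int8)
    i_lm, i_lp = 4 * n, 4 * n + 1
    special = [i_lm, i_lp, n - 1, 2 * n]  # tips, p(L+), m(L-)
    for blk in range(4):
        o = blk * n
        partner = {0: 1, 1: 0, 2: 3, 3: 2}[blk] * n
        for i in range(n):
            # +-2 band: boundary rows that copy a neighbour's derivative
            # inherit that neighbour's stencil
            lo, hi = max(i - 2, 0), min(i + 2, n - 1)
            for j in range(lo, hi + 1):
                S[o + i, o + j] = 1
                S[o + i, partner + j] = 1
            for j in special:
                S[o + i, j] = 1
    for row in (i_lm, i_lp):
        for j in special:
            S[row, j] = 1
    return S


def _make_events(solver: SolverConfig, i_lm: int, i_lp: int):
    def hit_min(t, y):
        return (y[i_lp] - y[i_lm]) - solver.L_min

    hit_min.terminal = True
    hit_min.direction = -1

    def hit_max(t, y):
        return (y[i_lp] - y[i_lm]) - solver.L_max

    hit_max.terminal = True
    hit_max.direction = 1
    return [hit_min, hit_max]


def _integrate(rhs, y0, t_end, solver: SolverConfig, sparsity, events):
    t_eval = np.arange(0.0, t_end + 0.5 * solver.save_every, solver.save_every)
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    rel, abst = solver.rel_tol, solver.abs_tol
    last_msg = ""
    for _ in range(2):  # one retry with tightened tolerances
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            y0,
            method=solver.method,
            t_eval=t_eval,
            rtol=rel,
            atol=abst,
            jac_sparsity=sparsity,
            events=events,
            dense_output=False,
        )
        if sol.status >= 0:
            return sol
        last_msg = sol.message
        rel, abst = rel / 100.0, abst / 100.0
    raise NumericalFailureError(
        f"stiff integration failed after tolerance tightening: {last_msg}"
    )


def _termination(sol) -> tuple[str, float | None, np.ndarray | None]:
    if sol.status == 1:
        if len(sol.t_events[0]) > 0:
            return "disassembled", sol.t_events[0][0], sol.y_events[0][0]
        return "runaway", sol.t_events[1][0], sol.y_events[1][0]
    return "completed", None, None


def simulate_full(scenario: ScenarioConfig, solver: SolverConfig) -> Trajectory:
    """Integrate the full four-field model for one scenario.

    Runs from t = 0 to ``scenario.t_end`` or until the length reaches a
    termination cutoff.  The trajectory is sampled every ``save_every``
    seconds; the run is deterministic for fixed inputs.
    """
    scenario.validate()
    solver.validate(scenario.L0)
    params = scenario.params
    n = solver.n_cells + 1
    xi = np.linspace(0.0, 1.0, n)
    dxi = 1.0 / solver.n_cells

    u0 = _initial_field(solver, xi)
    state0 = FullFieldState(
        xi=xi, p=u0.copy(), c=u0.copy(), m=u0.copy(), f=u0.copy(),
        L_minus=0.0, L_plus=scenario.L0, t=0.0,
    )
    state0 = apply_boundary_conditions(state0)
    y0 = np.concatenate(
        [state0.p, state0.c, state0.m, state0.f, [0.0], [scenario.L0]]
    )
    i_lm, i_lp = 4 * n, 4 * n + 1

    def rhs(t, y):
        p, c = y[0:n], y[n : 2 * n]
        m, f = y[2 * n : 3 * n], y[3 * n : 4 * n]
        dp, dc, dm, df, dLp, dLm = _full_rhs_core(
            p, c, m, f, y[i_lm], y[i_lp], params, xi, dxi,
            solver.freeze_tips, solver.advection_scheme,
        )
        return np.concatenate([dp, dc, dm, df, [dLm], [dLp]])

    sol = _integrate(
        rhs, y0, scenario.t_end, solver, _full_sparsity(n),
        _make_events(solver, i_lm, i_lp),
    )
    term, t_ev, y_ev = _termination(sol)

    ts = list(sol.t)
    ys = [sol.y[:, k] for k in range(sol.y.shape[1])]
    if t_ev is not None and (not ts or t_ev > ts[-1] + 1e-12):
        ts.append(t_ev)
        ys.append(y_ev)

    times, lm_s, lp_s, tv, snaps = [], [], [], [], []
    for t, y in zip(ts, ys):
        Lm, Lp = float(y[i_lm]), float(y[i_lp])
        L = Lp - Lm
        if solver.freeze_tips:
            dLp = dLm = 0.0
        else:
            dLp, dLm = tip_velocities_full(L, y[n - 1], y[2 * n], params.tips)
        times.append(t)
        lm_s.append(Lm)
        lp_s.append(Lp)
        tv.append((dLp, dLm))
        if solver.store_snapshots:
            snaps.append(
                FullFieldState(
                    xi=xi,
                    p=y[0:n].copy(), c=y[n : 2 * n].copy(),
                    m=y[2 * n : 3 * n].copy(), f=y[3 * n : 4 * n].copy(),
                    L_minus=Lm, L_plus=Lp, t=float(t),
                )
            )
    times = np.asarray(times)
    lm_s = np.asarray(lm_s)
    lp_s = np.asarray(lp_s)
    return Trajectory(
        times=times,
        L_minus_series=lm_s,
        L_plus_series=lp_s,
        length_series=lp_s - lm_s,
        tip_velocity_series=np.asarray(tv),
        termination=term,
        snapshots=snaps,
    )


def _reduced_sparsity(n: int) -> lil_matrix:
    size = 2 * n + 2
    S = lil_matrix((size, size), dtype=np.int8)
    i_lm, i_lp = 2 * n, 2 * n + 1
    special = [i_lm, i_lp, n - 1, n]  # tips, q(L+), h(L-)
    for blk in range(2):
        o = blk * n
        for i in range(n):
            # Robin rows copy second-order boundary stencils of their
            # neighbours, reaching 4 nodes inward
            width = 4 if (i <= 1 or i >= n - 2) else 2
            lo, hi = max(i - width, 0), min(i + width, n - 1)
            for j in range(lo, hi + 1):
                S[o + i, o + j] = 1
            for j in special:
                S[o + i, j] = 1
    for row in (i_lm, i_lp):
        for j in special:
            S[row, j] = 1
    return S


def _reduced_apply_bcs(
    q: np.ndarray,
    h: np.ndarray,
    L: float,
    eff: EffectiveParams,
    dxi: float,
    q_robin_rhs: float = 1.0,
) -> None:
    """Impose the reduced-model boundary constraints in place.

    q(L₋) = 1 and h(L₊) = 1 are Dirichlet.  The plus-end flux condition
    V₊ q(L₊) − D₊ ∂q/∂x|₊ = ``q_robin_rhs`` and the minus-end Robin
    condition h(L₋) + ∂h/∂n|₋ = 1 are discretized with second-order
    one-sided derivatives (gradient coefficient 1 µm).

    The minus-end gradient is taken along the outward normal (−x at the
    minus end), i.e. h − ∂h/∂x = 1 in coordinates.  The uniform state
    h ≡ 1 satisfies the condition under either sign convention, but only
    the outward-normal reading is dissipative: with the inward sign the
    perturbation problem has a positive eigenvalue for any domain longer
    than 1 µm, and no relaxation to the uniform state exists.
    """
    q[0] = 1.0
    h[-1] = 1.0
    dx = L * dxi
    rho = eff.D_plus / (2.0 * dx)
    if abs(3.0 * rho - eff.V_plus) < 1e-12:
        raise NumericalFailureError("degenerate Robin stencil for q")
    q[-1] = (rho * (4.0 * q[-2] - q[-3]) - q_robin_rhs) / (3.0 * rho - eff.V_plus)
    sig = 1.0 / (2.0 * dx)
    h[0] = (1.0 + sig * (4.0 * h[1] - h[2])) / (1.0 + 3.0 * sig)


def simulate_reduced_pde(
    effective: EffectiveParams,
    tips: TipParams,
    scenario: ScenarioConfig,
    solver: SolverConfig,
    q_robin_rhs: float = 1.0,
) -> Trajectory:
    """Integrate the reduced two-field model (total densities q and h) on
    the same moving-domain engine as :func:`simulate_full`.

    The Robin boundary nodes are evolved by the exact time derivative of
    their discrete constraints plus a stiff damping toward the constraint
    manifold, so the conditions hold at every accepted step up to
    integrator tolerance.  Tip coupling uses q(L₊) at the plus end and
    h(L₋) at the minus end.

    ``q_robin_rhs`` is the right-hand side of the plus-end flux condition
    V₊q − D₊∂q/∂x = rhs.  The default (+1) is the printed reservoir value;
    the closed-form steady profile :func:`mtends.reduced.steady_profile_plus`
    corresponds to rhs = −1 (see :func:`mtends.reduced.robin_steady_profile`).
    """
    scenario.validate()
    solver.validate(scenario.L0)
    for name, val in (("V_plus", effective.V_plus), ("D_plus", effective.D_plus),
                      ("D_minus", effective.D_minus)):
        if not np.isfinite(val) or val < 0:
            raise InvalidParameterError(f"effective.{name} must be finite, >= 0")
    if effective.D_plus <= 0 or effective.D_minus <= 0:
        raise InvalidParameterError("effective diffusivities must be positive")

    n = solver.n_cells + 1
    xi = np.linspace(0.0, 1.0, n)
    dxi = 1.0 / solver.n_cells
    V, Dq, Dh = effective.V_plus, effective.D_plus, effective.D_minus

    q0 = _initial_field(solver, xi)
    h0 = _initial_field(solver, xi)
    _reduced_apply_bcs(q0, h0, scenario.L0, effective, dxi, q_robin_rhs)
    y0 = np.concatenate([q0, h0, [0.0], [scenario.L0]])
    i_lm, i_lp = 2 * n, 2 * n + 1

    def rhs(t, y):
        q, h = y[0:n], y[n : 2 * n]
        Lm, Lp = y[i_lm], y[i_lp]
        L = Lp - Lm
        if not np.isfinite(L) or L <= 0:
            raise InvalidStateError(f"non-positive length L = {L}")
        if solver.freeze_tips:
            dLp = dLm = 0.0
        else:
            dLp = tips.alpha_plus - tips.beta_plus * L - tips.gamma_plus * q[-1]
            dLm = -tips.alpha_minus + tips.beta_minus * L + tips.gamma_minus * h[0]
        dL = dLp - dLm
        xdot = dLm + xi * dL
        hsp = L * dxi

        a_q = V - xdot
        a_h = -xdot
        dq = -a_q * _gradient(q, a_q, hsp, solver.advection_scheme)
        dq += Dq * _laplacian(q, hsp)
        dh = -a_h * _gradient(h, a_h, hsp, solver.advection_scheme)
        dh += Dh * _laplacian(h, hsp)

        dq[0] = 0.0  # q(L-) = 1
        dh[-1] = 0.0  # h(L+) = 1
        # Robin nodes evolve by the exact time derivative of the discrete
        # constraint (second-order one-sided stencils), plus stiff damping
        # toward the constraint manifold so local integration errors cannot
        # accumulate off it.
        dx = L * dxi
        rho = Dq / (2.0 * dx)  # d(rho)/dt = -rho * dL/L
        den_q = 3.0 * rho - V
        A = 4.0 * q[-2] - q[-3]
        q_target = (rho * A - q_robin_rhs) / den_q
        kappa_q = Dq / dx**2
        dq[-1] = (
            (rho * (4.0 * dq[-2] - dq[-3])) / den_q
            + ((3.0 * q_robin_rhs - A * V) / den_q**2) * (-rho * dL / L)
            + kappa_q * (q_target - q[-1])
        )
        # minus-end Robin for h (outward-normal gradient):
        # h_0 (1 + 3 sig) = 1 + sig (4 h_1 - h_2), sig = 1/(2 dx)
        sig = 1.0 / (2.0 * dx)
        B = 4.0 * h[1] - h[2]
        den_h = 1.0 + 3.0 * sig
        h_target = (1.0 + sig * B) / den_h
        kappa_h = Dh / dx**2
        dh[0] = (
            (sig * (4.0 * dh[1] - dh[2])) / den_h
            + ((B - 3.0) / den_h**2) * (-sig * dL / L)
            + kappa_h * (h_target - h[0])
        )
        return np.concatenate([dq, dh, [dLm], [dLp]])

    sol = _integrate(
        rhs, y0, scenario.t_end, solver, _reduced_sparsity(n),
        _make_events(solver, i_lm, i_lp),
    )
    term, t_ev, y_ev = _termination(sol)
    ts = list(sol.t)
    ys = [sol.y[:, k] for k in range(sol.y.shape[1])]
    if t_ev is not None and (not ts or t_ev > ts[-1] + 1e-12):
        ts.append(t_ev)
        ys.append(y_ev)

    times, lm_s, lp_s, tv, snaps = [], [], [], [], []
    for t, y in zip(ts, ys):
        Lm, Lp = float(y[i_lm]), float(y[i_lp])
        L = Lp - Lm
        if solver.freeze_tips:
            dLp = dLm = 0.0
        else:
            dLp = tips.alpha_plus - tips.beta_plus * L - tips.gamma_plus * y[n - 1]
            dLm = -tips.alpha_minus + tips.beta_minus * L + tips.gamma_minus * y[n]
        times.append(t)
        lm_s.append(Lm)
        lp_s.append(Lp)
        tv.append((dLp, dLm))
        if solver.store_snapshots:
            snaps.append(
                ReducedFieldState(
                    xi=xi, q=y[0:n].copy(), h=y[n : 2 * n].copy(),
                    L_minus=Lm, L_plus=Lp, t=float(t),
                )
            )
    times = np.asarray(times)
    lm_s = np.asarray(lm_s)
    lp_s = np.asarray(lp_s)
    return Trajectory(
        times=times,
        L_minus_series=lm_s,
        L_plus_series=lp_s,
        length_series=lp_s - lm_s,
        tip_velocity_series=np.asarray(tv),
        termination=term,
        snapshots=snaps,
    )


def refinement_error(
    scenario: ScenarioConfig,
    solver: SolverConfig,
    factor: int = 2,
    model: str = "full",
    effective: EffectiveParams | None = None,
) -> float:
    """Estimate the spatial discretization error of the length trajectory.

    Reruns the scenario with ``n_cells × factor`` and returns the maximum
    absolute difference of the length series on common save times (the fine
    run is the reference).
    """
    if factor < 2:
        raise InvalidParameterError("refinement factor must be >= 2")
    fine = replace(solver, n_cells=solver.n_cells * factor,
                   store_snapshots=False)
    coarse = replace(solver, store_snapshots=False)
    if model == "full":
        tr_c = simulate_full(scenario, coarse)
        tr_f = simulate_full(scenario, fine)
    elif model == "reduced-pde":
        if effective is None:
            raise InvalidParameterError("reduced-pde refinement needs effective")
        tr_c = simulate_reduced_pde(effective, scenario.params.tips, scenario, coarse)
        tr_f = simulate_reduced_pde(effective, scenario.params.tips, scenario, fine)
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    t_hi = min(tr_c.times[-1], tr_f.times[-1])
    t_common = tr_c.times[tr_c.times <= t_hi + 1e-12]
    len_c = np.interp(t_common, tr_c.times, tr_c.length_series)
    len_f = np.interp(t_common, tr_f.times, tr_f.length_series)
    return float(np.max(np.abs(len_c - len_f)))
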
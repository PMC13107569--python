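"""Fast-switching and adiabatic reductions of the two-motor model.

When binding/unbinding between the moving (lattice-bound) and diffusing
(cytoplasmic) motor states is fast relative to transport, each species'
total density obeys a single advection–diffusion equation with kinetically
averaged coefficients:

    V = k_on/(k_on + k_off) · v
    D_eff = k_on/(k_on + k_off) · D_on + k_off/(k_on + k_off) · D_off

If, further, motor profiles equilibrate fast relative to tip motion
(adiabatic limit), the steady profiles can be substituted into the tip laws,
collapsing the model to a one-dimensional flow for the length L:

    dL/dt = (α₊ + α₋) − (β₊ + β₋)L − γ₊ q(L) − γ₋

with q(L) the steady plus-motor density at the plus end.  The flow has a
unique positive equilibrium L† whenever α₊ + α₋ > γ₊ + γ₋; generically it is
a *treadmilling* equilibrium (both tips move while the length is constant).
Both tips are simultaneously stationary only on a measure-zero parameter set
characterized by a Lambert-W nullcline-coincidence condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

from .errors import (
    DegenerateProfileError,
    InvalidParameterError,
    NumericalFailureError,
    OutOfRangeError,
)
from .params import ModelParams, MotorParams, TipParams

__all__ = [
    "EffectiveParams",
    "EquilibriumResult",
    "effective_parameters",
    "effective_params_from_model",
    "steady_profile_plus",
    "steady_profile_minus",
    "robin_steady_profile",
    "adiabatic_length_flow",
    "adiabatic_tip_velocities",
    "equilibrium_length",
    "fixed_end_residual",
]

# exp() overflows near 709; stay clearly inside the modeled regime
_MAX_EXPONENT = 500.0


@dataclass(frozen=True)
class EffectiveParams:
    """Kinetically averaged transport coefficients of the reduced model.

    ``V_plus`` (µm/s) and ``D_plus`` (µm²/s) govern the total plus-motor
    density; ``D_minus`` (µm²/s) governs the total minus-motor density
    (whose effective velocity vanishes for a non-motile species).
    """

    V_plus: float
    D_plus: float
    D_minus: float


def effective_parameters(motor: MotorParams) -> tuple[float, float]:
    """Effective (velocity, diffusivity) of one species in the
    fast-switching limit: duty-ratio-weighted averages of the bound and
    unbound transport coefficients."""
    total = motor.k_on + motor.k_off
    if total <= 0:
        raise InvalidParameterError("k_on + k_off must be positive")
    duty = motor.k_on / total
    V = duty * motor.v
    D_eff = duty * motor.D_on + (1.0 - duty) * motor.D_off
    return V, D_eff


def effective_params_from_model(params: ModelParams) -> EffectiveParams:
    """Assemble :class:`EffectiveParams` for both species of a model."""
    V_plus, D_plus = effective_parameters(params.plus_motor)
    _, D_minus = effective_parameters(params.minus_motor)
    return EffectiveParams(V_plus=V_plus, D_plus=D_plus, D_minus=D_minus)


def steady_profile_plus(
    x: float | np.ndarray, L_minus: float, eff: EffectiveParams
) -> float | np.ndarray:
    """Steady total plus-motor density at position ``x``:

        q(x) = (1 + 1/V₊) exp(V₊/D₊ (x − L₋)) − 1/V₊

    Anchored at q(L₋) = 1 and strictly increasing toward the plus end (the
    antenna effect: longer filaments collect more motors at the tip).
    """
    if eff.V_plus <= 0:
        raise DegenerateProfileError(
            "steady_profile_plus requires V_plus > 0; use "
            "robin_steady_profile for the purely diffusive case"
        )
    if eff.D_plus <= 0:
        raise DegenerateProfileError("steady_profile_plus requires D_plus > 0")
    arg = (eff.V_plus / eff.D_plus) * (np.asarray(x, dtype=float) - L_minus)
    if np.any(arg > _MAX_EXPONENT):
        raise OutOfRangeError(
            "steady plus-motor profile overflows: length far beyond the "
            "modeled regime"
        )
    out = (1.0 + 1.0 / eff.V_plus) * np.exp(arg) - 1.0 / eff.V_plus
    return float(out) if np.isscalar(x) else out


def steady_profile_minus() -> float:
    """Steady total minus-motor density: spatially uniform, equal to the
    reservoir value 1 (satisfies both the Robin condition at the minus end
    and the Dirichlet condition at the plus end)."""
    return 1.0


def robin_steady_profile(
    x: float | np.ndarray,
    L_minus: float,
    eff: EffectiveParams,
    rhs: float = 1.0,
) -> float | np.ndarray:
    """General steady advection–diffusion profile with Dirichlet data
    q(L₋) = 1 and flux condition V₊ q(L₊) − D₊ q'(L₊) = ``rhs``.

    For V₊ > 0 the exponential ansatz q = a + b·exp(V₊ x/D₊) makes the flux
    condition independent of L₊ (V₊ a = rhs), giving

        q(x) = rhs/V₊ + (1 − rhs/V₊) exp(V₊/D₊ (x − L₋)).

    With ``rhs = -1`` this reproduces :func:`steady_profile_plus`.  For
    V₊ = 0 the steady profile is linear: q(x) = 1 − rhs·(x − L₋)/D₊.
    """
    if eff.D_plus <= 0:
        raise DegenerateProfileError("robin_steady_profile requires D_plus > 0")
    xs = np.asarray(x, dtype=float)
    if eff.V_plus == 0:
        out = 1.0 - rhs * (xs - L_minus) / eff.D_plus
    else:
        a = rhs / eff.V_plus
        arg = (eff.V_plus / eff.D_plus) * (xs - L_minus)
        if np.any(arg > _MAX_EXPONENT):
            raise OutOfRangeError("robin_steady_profile overflows")
        out = a + (1.0 - a) * np.exp(arg)
    return float(out) if np.isscalar(x) else out


def adiabatic_length_flow(
    L: float, tips: TipParams, eff: EffectiveParams
) -> float:
    """Right-hand side of the adiabatic length ODE,

        dL/dt = (α₊+α₋) − (β₊+β₋)L − γ₊ q(L) − γ₋,

    with q the steady plus-motor profile evaluated at the plus end.
    """
    if L < 0:
        raise InvalidParameterError(f"length must be non-negative, got {L}")
    q_at_plus = steady_profile_plus(L, 0.0, eff)
    return (
        (tips.alpha_plus + tips.alpha_minus)
        - (tips.beta_plus + tips.beta_minus) * L
        - tips.gamma_plus * q_at_plus
        - tips.gamma_minus
    )


def adiabatic_tip_velocities(
    L: float, tips: TipParams, eff: EffectiveParams
) -> tuple[float, float]:
    """Tip velocities (dL₊/dt, dL₋/dt) in the adiabatic limit, using the
    steady motor profiles (q at the plus end, h ≡ 1 at the minus end).
    Their difference equals :func:`adiabatic_length_flow`."""
    if L < 0:
        raise InvalidParameterError(f"length must be non-negative, got {L}")
    q_at_plus = steady_profile_plus(L, 0.0, eff)
    dLp = tips.alpha_plus - tips.beta_plus * L - tips.gamma_plus * q_at_plus
    dLm = -tips.alpha_minus + tips.beta_minus * L + tips.gamma_minus
    return dLp, dLm


@dataclass(frozen=True)
class EquilibriumResult:
    """Adiabatic equilibrium analysis of one parameter set.

    ``exists`` records the growth-vs-shrinkage dichotomy
    (α₊+α₋ > γ₊+γ₋).  When an equilibrium exists, ``L_dagger`` is the unique
    positive root of the length flow and ``tip_velocities_at_eq`` the tip
    velocities there (generically nonzero: treadmilling).  ``L_star`` is the
    motor-free equilibrium (α₊+α₋)/(β₊+β₋) when defined.
    ``fixed_end_residual`` measures how far the parameters are from the
    special set where both tips are simultaneously stationary.
    """

    exists: bool
    L_dagger: float | None
    L_star: float | None
    tip_velocities_at_eq: tuple[float, float] | None
    fixed_end_residual: float | None


def equilibrium_length(tips: TipParams, eff: EffectiveParams) -> EquilibriumResult:
    """Locate the adiabatic equilibrium length L† by bracketed root finding.

    The flow dL/dt = f(L) − g(L) has f strictly decreasing and g strictly
    increasing, so a sign change of the flow brackets the unique root.  The
    upper bracket is expanded geometrically from the characteristic scale
    until the flow is negative.
    """
    beta_sum = tips.beta_plus + tips.beta_minus
    alpha_sum = tips.alpha_plus + tips.alpha_minus
    gamma_sum = tips.gamma_plus + tips.gamma_minus
    exists = alpha_sum > gamma_sum
    L_star = alpha_sum / beta_sum if beta_sum > 0 else None

    residual: float | None
    try:
        residual = fixed_end_residual(tips, eff)
    except (InvalidParameterError, OutOfRangeError):
        residual = None

    if not exists:
        return EquilibriumResult(
            exists=False,
            L_dagger=None,
            L_star=L_star,
            tip_velocities_at_eq=None,
            fixed_end_residual=residual,
        )

    def flow(L: float) -> float:
        try:
            return adiabatic_length_flow(L, tips, eff)
        except OutOfRangeError:
            return -np.inf

    if flow(0.0) == 0.0:  # boundary-degenerate: alpha_sum == gamma_sum excluded
        L_dagger = 0.0
    else:
        hi = 1.0
        for _ in range(200):
            if flow(hi) < 0:
                break
            hi *= 2.0
        else:
            raise NumericalFailureError(
                "could not bracket the equilibrium length (flow never "
                "becomes negative); beta and gamma_plus may all be zero"
            )
        L_dagger = brentq(flow, 0.0, hi, xtol=1e-14, rtol=1e-15, maxiter=200)

    tip_v = adiabatic_tip_velocities(L_dagger, tips, eff)
    return EquilibriumResult(
        exists=True,
        L_dagger=float(L_dagger),
        L_star=L_star,
        tip_velocities_at_eq=tip_v,
        fixed_end_residual=residual,
    )


def fixed_end_residual(tips: TipParams, eff: EffectiveParams) -> float:
    """Residual of the fixed-ends coincidence condition.

    Each tip's stationarity condition is a line of unit slope in the
    (L₋, L₊) plane, so both tips can be simultaneously at rest only when the
    two intercepts coincide:

        (α₋ − γ₋)/β₋  =  (D₊/(β₊V₊)) (−β₊ Ω(z) + (α₊V₊ + γ₊)/D₊),
        z = (V₊/D₊) γ₊ (1 + 1/V₊) exp( (V₊/(D₊β₊)) (α₊ + γ₊/V₊) ) / β₊,

    with Ω the principal-branch Lambert-W function (its argument is positive
    for positive parameters).  Returns LHS − RHS (µm); a residual near zero
    means a fixed-ends equilibrium is attainable.
    """
    if tips.beta_minus <= 0 or tips.beta_plus <= 0:
        raise InvalidParameterError(
            "fixed_end_residual requires beta_plus > 0 and beta_minus > 0"
        )
    if eff.V_plus <= 0 or eff.D_plus <= 0:
        raise InvalidParameterError(
            "fixed_end_residual requires V_plus > 0 and D_plus > 0"
        )
    V, D = eff.V_plus, eff.D_plus
    k = V / D
    lhs = (tips.alpha_minus - tips.gamma_minus) / tips.beta_minus
    exponent = (V / (D * tips.beta_plus)) * (
        tips.alpha_plus + tips.gamma_plus / V
    )
    if exponent > _MAX_EXPONENT:
        raise OutOfRangeError("Lambert-W argument overflows")
    z = k * tips.gamma_plus * (1.0 + 1.0 / V) * math.exp(exponent) / tips.beta_plus
    w = lambertw(z, 0)
    if abs(w.imag) > 1e-12:
        raise OutOfRangeError("Lambert-W returned a non-real value")
    rhs = (D / (tips.beta_plus * V)) * (
        -tips.beta_plus * w.real + (tips.alpha_plus * V + tips.gamma_plus) / D
    )
    return lhs - rhs
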
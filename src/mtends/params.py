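"""Model parameters, units, and rate derivations from measured growth speeds.

All quantities are expressed in µm and s: speeds in µm/s, diffusivities in
µm²/s, kinetic rates in 1/s.  Motor densities are nondimensional, normalized
so that the boundary reservoir density equals 1; the motor-driven shrinking
coefficients ``gamma_plus``/``gamma_minus`` therefore carry units of µm/s per
unit normalized density.

The default parameter set describes two depolymerase species on a
non-centrosomal microtubule: a slow, processive plus-end-directed motor
(kinesin-8 like) and a purely diffusive motor that attacks the minus end
(kinesin-13 like), together with tip kinetics measured in *Drosophila*
sensory neurons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .errors import (
    InvalidParameterError,
    NegativeRateWarning,
    SlowSwitchingWarning,
)

__all__ = [
    "MotorParams",
    "TipParams",
    "ModelParams",
    "ScenarioConfig",
    "table1_defaults",
    "validate_params",
    "alpha_from_max_growth",
    "beta_from_avg_growth",
    "CHARACTERISTIC_LENGTH",
]

#: Characteristic microtubule length (µm) used to convert average growth
#: speeds into length-dependent disassembly rates, and as the default
#: initial length of every scenario.
CHARACTERISTIC_LENGTH = 10.0


@dataclass(frozen=True)
class MotorParams:
    """Kinetic description of one depolymerizing motor species.

    Parameters
    ----------
    direction : {"plus-end-directed", "minus-end-directed"}
        Which filament end the species walks toward (a purely diffusive
        species still targets one end for depolymerization).
    v : float
        Walking speed on the microtubule lattice (µm/s, ≥ 0).  Zero for a
        purely diffusive species.
    D_on : float
        Diffusivity while bound to the microtubule (µm²/s, ≥ 0).
    D_off : float
        Cytoplasmic diffusivity while unbound (µm²/s, > 0).
    k_on, k_off : float
        Binding and unbinding rates between the bound, moving state and the
        unbound, diffusing state (1/s, > 0).
    """

    direction: str
    v: float
    D_on: float
    D_off: float
    k_on: float
    k_off: float

    def validate(self, label: str = "motor") -> None:
        if self.direction not in ("plus-end-directed", "minus-end-directed"):
            raise InvalidParameterError(
                f"{label}.direction must be 'plus-end-directed' or "
                f"'minus-end-directed', got {self.direction!r}"
            )
        for name in ("v", "D_on", "D_off", "k_on", "k_off"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidParameterError(f"{label}.{name} is not finite")
            if value < 0:
                raise InvalidParameterError(
                    f"{label}.{name} must be non-negative, got {value}"
                )
        for name in ("D_off", "k_on", "k_off"):
            if getattr(self, name) == 0:
                raise InvalidParameterError(
                    f"{label}.{name} must be strictly positive"
                )


@dataclass(frozen=True)
class TipParams:
    """Tip-dynamics rates for the two filament ends.

    ``alpha_plus``/``alpha_minus`` are intrinsic polymerization speeds
    (µm/s); ``beta_plus``/``beta_minus`` are intrinsic length-dependent
    disassembly rates (1/s, modelling e.g. ragged-protofilament
    destabilization of long filaments); ``gamma_plus``/``gamma_minus``
    convert the local motor density at a tip into a depolymerization speed
    (µm/s per unit normalized density).
    """

    alpha_plus: float
    alpha_minus: float
    beta_plus: float
    beta_minus: float
    gamma_plus: float
    gamma_minus: float

    def validate(self, label: str = "tips") -> None:
        for name in (
            "alpha_plus",
            "alpha_minus",
            "beta_plus",
            "beta_minus",
            "gamma_plus",
            "gamma_minus",
        ):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidParameterError(f"{label}.{name} is not finite")
            if value < 0:
                raise InvalidParameterError(
                    f"{label}.{name} must be non-negative, got {value}"
                )


@dataclass(frozen=True)
class ModelParams:
    """Full kinetic description: both motor species plus tip dynamics."""

    plus_motor: MotorParams
    minus_motor: MotorParams
    tips: TipParams

    def replace_tips(self, **kwargs: float) -> "ModelParams":
        """Return a copy with selected tip rates overridden."""
        return replace(self, tips=replace(self.tips, **kwargs))


@dataclass(frozen=True)
class ScenarioConfig:
    """A named simulation scenario: parameters, initial length, horizon."""

    name: str
    params: ModelParams
    L0: float = CHARACTERISTIC_LENGTH
    t_end: float = 300.0
    initial_density_spec: str = "uniform-one"

    def validate(self) -> None:
        if not (self.L0 > 0 and math.isfinite(self.L0)):
            raise InvalidParameterError(f"scenario.L0 must be > 0, got {self.L0}")
        if not (self.t_end > 0 and math.isfinite(self.t_end)):
            raise InvalidParameterError(
                f"scenario.t_end must be > 0, got {self.t_end}"
            )


def table1_defaults() -> ModelParams:
    """Baseline parameter set for the full model.

    Plus-end motor: slow (0.05 µm/s), weakly diffusive on the lattice
    (0.01 µm²/s), long-lived bound state (k_off = 0.25/s).  Minus-end motor:
    non-motile, rapidly diffusive on the lattice (0.38 µm²/s), short-lived
    bound state (k_off = 1.2/s, the lower end of the measured range).  Both
    diffuse at 4 µm²/s in the cytoplasm and bind at a baseline 1/s.  Tips:
    intrinsic growth 0.15 / 0.02 µm/s, intrinsic length-dependent disassembly
    0.05 / 0.0006 1/s, motor-driven shrinking coefficient 0.01 at each end.
    """
    return ModelParams(
        plus_motor=MotorParams(
            direction="plus-end-directed",
            v=0.05,
            D_on=0.01,
            D_off=4.0,
            k_on=1.0,
            k_off=0.25,
        ),
        minus_motor=MotorParams(
            direction="minus-end-directed",
            v=0.0,
            D_on=0.38,
            D_off=4.0,
            k_on=1.0,
            k_off=1.2,
        ),
        tips=TipParams(
            alpha_plus=0.15,
            alpha_minus=0.02,
            beta_plus=0.05,
            beta_minus=0.0006,
            gamma_plus=0.01,
            gamma_minus=0.01,
        ),
    )


def validate_params(
    params: ModelParams, L_ref: float = CHARACTERISTIC_LENGTH
) -> ModelParams:
    """Validate a full parameter set; return it unchanged if consistent.

    Raises :class:`InvalidParameterError` on any invariant violation.  Emits
    a :class:`SlowSwitchingWarning` when binding/unbinding is not fast
    compared with transport over the reference length ``L_ref`` (the regime
    the fast-switching reduction assumes): the reduction requires
    ``k_on, k_off >> v/L_ref`` and ``>> D/L_ref**2`` for each species.
    """
    params.plus_motor.validate("plus_motor")
    params.minus_motor.validate("minus_motor")
    params.tips.validate("tips")
    if params.plus_motor.direction == params.minus_motor.direction:
        raise InvalidParameterError(
            "plus_motor and minus_motor must have opposite directions"
        )
    for label, motor in (
        ("plus_motor", params.plus_motor),
        ("minus_motor", params.minus_motor),
    ):
        transport_rate = max(
            motor.v / L_ref,
            motor.D_on / L_ref**2,
            motor.D_off / L_ref**2,
        )
        if min(motor.k_on, motor.k_off) < transport_rate:
            warnings.warn(
                f"{label}: switching rates (k_on={motor.k_on}, "
                f"k_off={motor.k_off}) are not fast relative to transport "
                f"({transport_rate:.3g}/s at L={L_ref} µm); the "
                "fast-switching reduction may be inaccurate",
                SlowSwitchingWarning,
                stacklevel=2,
            )
    return params


def alpha_from_max_growth(v_g_max: float) -> float:
    """Convert a maximal tip growth speed (µm/min) into an intrinsic growth
    rate α (µm/s).

    When polymerization at a tip is driven entirely by intrinsic growth,
    dL/dt = α, so α equals the maximal observed growth speed; only the unit
    changes (minutes to seconds).
    """
    if not (v_g_max >= 0 and math.isfinite(v_g_max)):
        raise InvalidParameterError(f"v_g_max must be >= 0, got {v_g_max}")
    return v_g_max / 60.0


def beta_from_avg_growth(v_g_avg: float, alpha: float, L_bar: float) -> float:
    """Convert an average tip growth speed (µm/min) into a length-dependent
    disassembly rate β (1/s).

    Assuming the average speed reflects intrinsic growth minus intrinsic
    length-dependent loss at the characteristic length ``L_bar``,
    dL/dt = α − βL ≈ v_g_avg at L = L_bar, so β = (α − v_g_avg/60)/L_bar.
    The arithmetic is exact; note that published tables may round.
    """
    if not (L_bar > 0 and math.isfinite(L_bar)):
        raise InvalidParameterError(f"L_bar must be > 0, got {L_bar}")
    if not (v_g_avg >= 0 and math.isfinite(v_g_avg)):
        raise InvalidParameterError(f"v_g_avg must be >= 0, got {v_g_avg}")
    beta = (alpha - v_g_avg / 60.0) / L_bar
    if beta < 0:
        warnings.warn(
            f"average growth speed {v_g_avg} µm/min exceeds 60·alpha = "
            f"{60 * alpha} µm/min; derived beta = {beta:.3g}/s is negative",
            NegativeRateWarning,
            stacklevel=2,
        )
    return beta
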
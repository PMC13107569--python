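"""Exception and warning types shared across the package."""


class MTEndsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MTEndsError, ValueError):
    """A model parameter violates its physical constraints."""


class InvalidStateError(MTEndsError, ValueError):
    """A field state violates its invariants (e.g. negative length)."""


class InvalidScenarioError(MTEndsError, ValueError):
    """An unknown built-in scenario name was requested."""


class ConfigurationError(MTEndsError, ValueError):
    """A configuration file failed to parse or contained unknown keys."""


class NumericalFailureError(MTEndsError, RuntimeError):
    """The integrator or a root finder failed to converge."""


class DegenerateProfileError(MTEndsError, ValueError):
    """A closed-form profile is undefined for the given parameters."""


class OutOfRangeError(MTEndsError, ValueError):
    """An analytic expression overflowed outside the modeled regime."""


class SlowSwitchingWarning(UserWarning):
    """Binding kinetics are not fast relative to transport; the
    fast-switching and adiabatic reductions may be inaccurate."""


class NegativeRateWarning(UserWarning):
    """A derived rate came out negative (inconsistent input speeds)."""
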
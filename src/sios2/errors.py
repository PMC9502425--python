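"""Exception types raised by the process-model layers."""


class Sios2Error(Exception):
    """Base class for all package errors."""


class DomainError(Sios2Error, ValueError):
    """An argument lies outside the physically meaningful domain."""


class BracketingError(Sios2Error, ValueError):
    """A root-finding bracket does not contain the target value.

    Carries the bracket endpoints and the viscosities evaluated there so the
    caller can see how far the target is from the attainable range.
    """

    def __init__(self, target, bracket, endpoint_values):
        self.target = target
        self.bracket = bracket
        self.endpoint_values = endpoint_values
        lo, hi = bracket
        v_lo, v_hi = endpoint_values
        super().__init__(
            f"target viscosity {target:.6g} Pa*s not attainable on "
            f"[{lo:.2f} K, {hi:.2f} K]: eta({lo:.2f} K) = {v_lo:.6g} Pa*s, "
            f"eta({hi:.2f} K) = {v_hi:.6g} Pa*s"
        )


class FittingError(Sios2Error, RuntimeError):
    """A regression or nonlinear fit could not be carried out."""


class SchemaError(Sios2Error, ValueError):
    """A tabular input does not match the expected column schema."""
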
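"""The extrusion die as a capillary rheometer.

For steady laminar flow of a Newtonian fluid through a cylindrical die of
radius r and length l (Hagen-Poiseuille), the wall shear stress and the
apparent wall shear rate are

    tau_die      = dp * r / (2 l)
    gammadot_die = 4 Vdot / (pi r**3)

and their ratio is the apparent die viscosity. Polymer melts are shear
thinning, so the parabolic velocity profile assumption fails; the
Weissenberg-Rabinowitsch correction rescales the apparent shear rate with
the Ostwald flow index n (equivalently the Carreau index c = 1 - n):

    gammadot_corr = (3n + 1)/(4n) * gammadot_die = (4 - 3c)/(4 - 4c) * gammadot_die

Entrance-pressure (Bagley) and elongational (Cogswell) effects are out of
scope here; die viscosities are therefore relative, not absolute, which is
all the autogenic correlation needs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .feeding import ExtruderGeometry

import math


@dataclass(frozen=True)
class DieObservation:
    """Pressure drop and volume flow through the die at one steady state."""

    pressure_drop: float  # Pa
    volume_flow: float  # m^3/s

    def __post_init__(self):
        if self.pressure_drop < 0:
            raise DomainError("pressure drop must be non-negative")
        if not self.volume_flow > 0:
            raise DomainError("volume flow must be positive")


def die_shear_stress(pressure_drop: float, geom: ExtruderGeometry) -> float:
    """Wall shear stress dp * r_die / (2 * l_die), Pa."""
    if pressure_drop < 0:
        raise DomainError("pressure drop must be non-negative")
    return pressure_drop * geom.r_die / (2.0 * geom.l_die)


def die_shear_rate(volume_flow: float, geom: ExtruderGeometry) -> float:
    """Apparent Newtonian wall shear rate 4 * Vdot / (pi * r_die**3), 1/s."""
    if not volume_flow > 0:
        raise DomainError("volume flow must be positive")
    return 4.0 * volume_flow / (math.pi * geom.r_die ** 3)


def apparent_viscosity(pressure_drop: float, volume_flow: float,
                       geom: ExtruderGeometry) -> float:
    """Apparent die viscosity tau_die / gammadot_die, Pa*s."""
    if not pressure_drop > 0:
        raise DomainError("pressure drop must be positive")
    return die_shear_stress(pressure_drop, geom) / die_shear_rate(volume_flow, geom)


def wr_correction_factor(c: float) -> float:
    """Weissenberg-Rabinowitsch factor (4 - 3c)/(4 - 4c) = (3n + 1)/(4n).

    Equals 1 for a Newtonian melt (c = 0) and grows with shear thinning;
    diverges as c -> 1.
    """
    if not 0 <= c < 1:
        raise DomainError(f"flow index c must lie in [0, 1), got {c}")
    return (4.0 - 3.0 * c) / (4.0 - 4.0 * c)


def wr_corrected_shear_rate(shear_rate: float, c: float) -> float:
    """Shear rate rescaled for shear-thinning flow in the die, 1/s."""
    if shear_rate < 0:
        raise DomainError("shear rate must be non-negative")
    return shear_rate * wr_correction_factor(c)
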
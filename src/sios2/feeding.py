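"""Barrel-load model of the feeding section.

A twin-screw extruder's throughput ceiling is set where the feeding screws
can no longer convey the powder fed to them and a backlog forms. Two
dimensionless load numbers describe this:

* the specific feed load, ``SFL = (mdot/rho_true) / (n * d**3)`` -- the
  classic volumetric throughput per screw turn, normalised by the screw
  diameter cubed;
* the normalised feed load ``SFL*``, which measures the same throughput
  against the *actual* geometric transport capacity of the feeding screws
  (free cross-section times pitch per turn), corrected by the powder slip
  ``s``: SFL* = 1 means a completely filled feeding section, SFL* = 0 an
  empty one.

The slip is the fraction of the geometric transport capacity the powder does
not realise. Once it is known for a powder, the maximum mass flow at any
screw speed -- and with it the maximum specific feed load SFLmax -- follows
from geometry and bulk density alone, which is what lets the first,
experiment-hungry optimisation step of the original strategy be replaced by
a small slip calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FittingError


@dataclass(frozen=True)
class ExtruderGeometry:
    """Screw, feeding-section and die dimensions of one extruder setup.

    Parameters
    ----------
    d
        Screw diameter, m.
    A_free
        Free cross-sectional area of the screw pair, m^2.
    l_pitch
        Screw pitch in the feeding section, m.
    r_die
        Die bore radius, m.
    l_die
        Die land length, m.
    n_max
        Nominal (maximum) screw speed, 1/s.
    """

    d: float
    A_free: float
    l_pitch: float
    r_die: float
    l_die: float
    n_max: float

    def __post_init__(self):
        for name in ("d", "A_free", "l_pitch", "r_die", "l_die", "n_max"):
            if not getattr(self, name) > 0:
                raise DomainError(f"geometry field {name} must be positive, "
                                  f"got {getattr(self, name)}")


@dataclass(frozen=True)
class PowderState:
    """Densities and conveying slip of one powder.

    ``slip`` is the fraction of the feeding screws' geometric transport
    capacity not realised by the powder; 0 means ideal plug conveying,
    values approaching 1 mean the powder barely moves with the screw.
    """

    rho_bulk: float  # kg/m^3
    rho_true: float  # kg/m^3
    slip: float = 0.0

    def __post_init__(self):
        if not 0 < self.rho_bulk <= self.rho_true:
            raise DomainError(
                f"need 0 < rho_bulk <= rho_true, got rho_bulk={self.rho_bulk}, "
                f"rho_true={self.rho_true}")
        if not 0 <= self.slip < 1:
            raise DomainError(f"slip must lie in [0, 1), got {self.slip}")


def sfl(mass_flow: float, rho_true: float, n: float, d: float) -> float:
    """Specific feed load (mdot/rho_true) / (n * d**3), dimensionless."""
    if n <= 0:
        raise DomainError(f"screw speed must be positive, got {n}")
    if d <= 0 or rho_true <= 0 or mass_flow < 0:
        raise DomainError("mass flow, density and diameter must be positive")
    return (mass_flow / rho_true) / (n * d ** 3)


def sfl_star(mass_flow: float, powder: PowderState, geom: ExtruderGeometry,
             n: float) -> float:
    """Normalised feed load; 1 = completely filled feeding section."""
    if n <= 0:
        raise DomainError(f"screw speed must be positive, got {n}")
    if mass_flow < 0:
        raise DomainError("mass flow must be non-negative")
    if powder.slip >= 1:
        raise DomainError("slip = 1 means no powder transport at all")
    return (mass_flow / powder.rho_bulk) / (
        (1.0 - powder.slip) * geom.l_pitch * geom.A_free * n)


def slip_from_filled_point(mass_flow: float, rho_bulk: float,
                           geom: ExtruderGeometry, n: float) -> float:
    """Slip from a single filled-barrel operating point (SFL* = 1).

    At the backlog point the feeding section is completely filled, so
    s = 1 - (mdot/rho_bulk) / (l_pitch * A_free * n). A negative result
    (powder outrunning the screw geometry) is physically suspect and is
    returned with a warning; a result >= 1 is inconsistent and raises.
    """
    if n <= 0 or mass_flow <= 0 or rho_bulk <= 0:
        raise DomainError("mass flow, bulk density and screw speed must be positive")
    s = 1.0 - (mass_flow / rho_bulk) / (geom.l_pitch * geom.A_free * n)
    if s >= 1.0:
        raise DomainError(f"computed slip {s} >= 1: inconsistent inputs "
                          "(zero mass flow at a filled barrel?)")
    if s < 0.0:
        warnings.warn(
            f"computed slip {s:.4f} < 0: throughput exceeds the geometric "
            "transport capacity; check inputs", stacklevel=2)
    return s


def fit_slip(speeds, max_mass_flows, rho_bulk: float,
             geom: ExtruderGeometry) -> float:
    """Slip from a multi-speed feeding-limit calibration.

    The maximum conveyable mass flow is proportional to screw speed,
    mdot_max = (1 - s) * l_pitch * A_free * rho_bulk * n, with no intercept
    (a resting screw conveys nothing), so the slope of a least-squares
    regression of mdot_max on n *through the origin* yields the slip.
    """
    n = np.asarray(speeds, dtype=float)
    m = np.asarray(max_mass_flows, dtype=float)
    if n.size != m.size or n.size < 1:
        raise FittingError("need equal-length, non-empty speed and mass-flow arrays")
    if np.any(n <= 0) or np.any(m <= 0):
        raise DomainError("speeds and mass flows must be positive")
    if n.size >= 2 and np.unique(n).size < 2:
        raise FittingError("need at least two distinct screw speeds")
    slope = float(np.sum(n * m) / np.sum(n * n))
    one_minus_s = slope / (geom.l_pitch * geom.A_free * rho_bulk)
    if one_minus_s <= 0:
        raise FittingError(f"fitted (1 - s) = {one_minus_s} is non-positive")
    s = 1.0 - one_minus_s
    if s < 0:
        raise FittingError(
            f"fitted slip {s:.4f} < 0: measured transport exceeds the "
            "geometric capacity; check pitch/area/bulk-density inputs")
    return s


def sfl_max(powder: PowderState, geom: ExtruderGeometry) -> float:
    """Maximum specific feed load from geometry, densities and slip.

    SFLmax = (1 - s) * (rho_bulk/rho_true) * A_free * l_pitch / d**3. This is
    the SFL reached when the feeding section is completely filled, and it is
    independent of screw speed.
    """
    return ((1.0 - powder.slip) * (powder.rho_bulk / powder.rho_true)
            * geom.A_free * geom.l_pitch / geom.d ** 3)


def max_mass_flow(powder: PowderState, geom: ExtruderGeometry, n: float) -> float:
    """Maximum conveyable mass flow (kg/s) at screw speed ``n``:
    mdot_max = (1 - s) * l_pitch * A_free * rho_bulk * n."""
    if n <= 0:
        raise DomainError(f"screw speed must be positive, got {n}")
    return (1.0 - powder.slip) * geom.l_pitch * geom.A_free * powder.rho_bulk * n
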
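"""Carreau melt-viscosity model with Arrhenius time-temperature superposition.

The shear-thinning viscosity of a polymer melt is described by the Carreau
model

    eta(gammadot, T) = eta0 * a_T * (1 + a_T * gammadot / gammadot_c)**(-c)

with the Arrhenius shift factor

    a_T = exp( (Ea / R) * (1/T - 1/T_ref) )

collapsing flow curves measured at different temperatures onto a master curve
at the reference temperature ``T_ref``. The Arrhenius form is appropriate far
above the glass transition, which is where extrusion-relevant measurements of
the pharmaceutical polymers considered here are made.

Melt temperature prediction requires the inverse problem -- given a shear
rate and a target viscosity, find the temperature that produces it. The model
cannot be inverted analytically in T, but viscosity is strictly monotone in
temperature (for Ea > 0), so a bracketed root find is exact for practical
purposes; see :func:`invert_temperature`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import BracketingError, DomainError, FittingError

#: Universal gas constant, J/(mol K).
R_GAS = 8.314

#: Default search bracket for temperature inversion, offsets from T_ref in K.
DEFAULT_BRACKET_HALF_WIDTH = 150.0

#: Absolute tolerance of the temperature inversion, K. Far tighter than the
#: 0.01 K needed physically so that fit/predict round trips close to within
#: numerical noise.
INVERSION_XTOL = 1.0e-6


@dataclass(frozen=True)
class CarreauArrheniusParams:
    """Carreau parameters plus Arrhenius temperature shift for one polymer.

    Parameters
    ----------
    eta0
        Zero-shear viscosity at the reference temperature, Pa*s.
    gammadot_c
        Critical shear rate marking the onset of shear thinning, 1/s.
    c
        Carreau flow index, dimensionless, in [0, 1). The high-shear
        power-law slope is -c; the Ostwald flow index is n = 1 - c.
    Ea
        Arrhenius activation energy of flow, J/mol.
    T_ref
        Reference temperature of the master curve, K.
    """

    eta0: float
    gammadot_c: float
    c: float
    Ea: float
    T_ref: float

    def __post_init__(self):
        if not self.eta0 > 0:
            raise DomainError(f"eta0 must be positive, got {self.eta0}")
        if not self.gammadot_c > 0:
            raise DomainError(f"gammadot_c must be positive, got {self.gammadot_c}")
        if not 0 <= self.c < 1:
            raise DomainError(f"flow index c must lie in [0, 1), got {self.c}")
        if not self.Ea > 0:
            raise DomainError(f"activation energy Ea must be positive, got {self.Ea}")
        if not self.T_ref > 0:
            raise DomainError(f"reference temperature must be positive, got {self.T_ref}")


@dataclass(frozen=True)
class FlowCurvePoint:
    """One measured (shear rate, temperature, viscosity) triple."""

    shear_rate: float  # 1/s
    temperature: float  # K
    viscosity: float  # Pa*s

    def __post_init__(self):
        if self.shear_rate < 0:
            raise DomainError(f"shear rate must be >= 0, got {self.shear_rate}")
        if not self.viscosity > 0:
            raise DomainError(f"viscosity must be positive, got {self.viscosity}")
        if not self.temperature > 0:
            raise DomainError(f"temperature must be positive, got {self.temperature}")


def shift_factor(params: CarreauArrheniusParams, T):
    """Arrhenius time-temperature shift factor a_T.

    Strictly decreasing in T; equals 1 exactly at ``T = T_ref``. Accepts a
    scalar or array temperature in kelvin.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be positive (kelvin)")
    out = np.exp(params.Ea / R_GAS * (1.0 / T - 1.0 / params.T_ref))
    return out if out.ndim else float(out)


def viscosity(params: CarreauArrheniusParams, shear_rate, T):
    """Carreau-Arrhenius melt viscosity, Pa*s.

    eta = eta0 * a_T * (1 + a_T*gammadot/gammadot_c)**(-c). Strictly
    decreasing in shear rate (for c > 0) and in temperature (for Ea > 0).
    Vectorised over both arguments.
    """
    shear_rate = np.asarray(shear_rate, dtype=float)
    if np.any(shear_rate < 0):
        raise DomainError("shear rate must be non-negative")
    aT = shift_factor(params, T)
    out = params.eta0 * aT * (1.0 + aT * shear_rate / params.gammadot_c) ** (-params.c)
    return out if np.ndim(out) else float(out)


def ostwald_index(params: CarreauArrheniusParams) -> float:
    """Ostwald (power-law) flow index n = 1 - c, used by the
    Weissenberg-Rabinowitsch correction."""
    return 1.0 - params.c


def invert_temperature(
    params: CarreauArrheniusParams,
    shear_rate: float,
    target_viscosity: float,
    bracket: tuple[float, float] | None = None,
    xtol: float = INVERSION_XTOL,
) -> float:
    """Temperature (K) at which the melt reaches ``target_viscosity``.

    The viscosity is strictly monotone decreasing in temperature, so the root
    is unique inside any bracket that contains it. The default bracket,
    ``T_ref`` +/- 150 K, spans all extrusion-relevant temperatures.

    Raises
    ------
    BracketingError
        If the target viscosity lies outside the range attainable on the
        bracket; the message carries the endpoint viscosities.
    """
    if not target_viscosity > 0:
        raise DomainError(f"target viscosity must be positive, got {target_viscosity}")
    if shear_rate < 0:
        raise DomainError("shear rate must be non-negative")
    if bracket is None:
        bracket = (params.T_ref - DEFAULT_BRACKET_HALF_WIDTH,
                   params.T_ref + DEFAULT_BRACKET_HALF_WIDTH)
    lo, hi = bracket
    if not 0 < lo < hi:
        raise DomainError(f"invalid temperature bracket {bracket}")

    def objective(T):
        return viscosity(params, shear_rate, T) - target_viscosity

    f_lo, f_hi = objective(lo), objective(hi)
    # eta decreases with T: f_lo >= 0 >= f_hi must hold for a root.
    if f_lo < 0 or f_hi > 0:
        raise BracketingError(target_viscosity, (lo, hi),
                              (f_lo + target_viscosity, f_hi + target_viscosity))
    return float(brentq(objective, lo, hi, xtol=xtol))


def fit_carreau_arrhenius(
    points: Iterable[FlowCurvePoint] | Sequence[FlowCurvePoint],
    T_ref: float,
) -> CarreauArrheniusParams:
    """Refit flow-curve data to the Carreau-Arrhenius model.

    Minimises the sum of squared residuals in log viscosity (viscosity spans
    decades, so a linear-scale fit would be dominated by the zero-shear
    plateau). ``T_ref`` is fixed by the caller, not estimated; the refits of
    the three reference polymers all use 473 K.

    Requires at least four points spanning at least two distinct temperatures
    (the activation energy is unidentifiable from an isothermal flow curve).

    Raises
    ------
    FittingError
        For an under-determined design or optimizer non-convergence.
    """
    pts = list(points)
    if len(pts) < 4:
        raise FittingError(f"need >= 4 flow-curve points to fit 4 parameters, got {len(pts)}")
    temps = np.array([p.temperature for p in pts])
    if np.unique(temps).size < 2:
        raise FittingError(
            "flow-curve points lie at a single temperature: the activation "
            "energy Ea is unidentifiable; provide >= 2 distinct temperatures"
        )
    gdot = np.array([p.shear_rate for p in pts])
    eta = np.array([p.viscosity for p in pts])
    log_eta = np.log(eta)

    # Parameter vector: [ln eta0, ln gammadot_c, c, ln Ea].
    nonzero = gdot[gdot > 0]
    x0 = np.array([
        float(np.max(log_eta)),
        float(np.log(np.median(nonzero))) if nonzero.size else 0.0,
        0.4,
        np.log(1.5e5),
    ])

    def residuals(x):
        p = CarreauArrheniusParams(
            eta0=math.exp(x[0]), gammadot_c=math.exp(x[1]),
            c=x[2], Ea=math.exp(x[3]), T_ref=T_ref,
        )
        return np.log(viscosity(p, gdot, temps)) - log_eta

    result = least_squares(
        residuals, x0,
        bounds=([-np.inf, -np.inf, 0.0, np.log(1.0)],
                [np.inf, np.inf, 0.999, np.log(1.0e7)]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not result.success:
        raise FittingError(f"Carreau-Arrhenius fit did not converge: "
                           f"status {result.status} ({result.message})")
    x = result.x
    return CarreauArrheniusParams(
        eta0=math.exp(x[0]), gammadot_c=math.exp(x[1]),
        c=float(x[2]), Ea=math.exp(x[3]), T_ref=T_ref,
    )
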
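"""Autogenic extrusion correlations: fitting and operating-point prediction.

In autogenic operation the barrel heaters are off and the melt temperature
is set entirely by viscous dissipation of screw power. Two empirical
correlations, fitted from a handful of steady-state experiments, then
describe the extruder:

1. The die viscosity is a hyperbola in screw speed,

       eta_die = tau_extruder / n,

   where ``tau_extruder`` (Pa) acts as a characteristic shear stress of the
   extruder/die setup. It is a setup constant, the same for all materials;
   its particular value has no direct physical meaning because the screw
   speed, not a true shear rate, appears in the denominator.

2. The ratio of the (measured) die viscosity to the (calculated)
   Carreau-Arrhenius viscosity at the same shear rate and melt temperature
   follows a double-logarithmic law in reduced screw speed,

       lg(eta_die / eta_calculated) = s_extruder * lg(n / n_max) + i_extruder,

   with lg = log10 and n_max the nominal screw speed. Slope and intercept
   are extruder-specific and material-independent.

Chaining the two correlations backwards -- screw speed -> die viscosity ->
extruder-independent viscosity -> temperature via the rheology model's
numerical inversion -- predicts the melt temperature for any screw speed.
Combined with the feeding model's maximum feed load this yields the full
operating point (throughput, melt temperature) without further experiments.

Observations at low screw speed (below about 100 rpm) systematically violate
correlation 2, most likely because autogenic thermal equilibrium is not
reached at low throughput, and are excluded from fitting by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import die_flow, feeding, rheology
from .errors import DomainError, FittingError
from .feeding import ExtruderGeometry
from .materials import MaterialProperties
from .units import rpm_to_per_s

#: Default lower screw-speed bound for fitting, 1/s (100 rpm).
DEFAULT_MIN_SPEED = rpm_to_per_s(100.0)


@dataclass(frozen=True)
class ExtrusionObservation:
    """One autogenic steady-state record."""

    n: float  # screw speed, 1/s
    mass_flow: float  # kg/s
    melt_temperature: float  # K
    die_pressure: float  # Pa

    def __post_init__(self):
        for name in ("n", "mass_flow", "melt_temperature", "die_pressure"):
            if not getattr(self, name) > 0:
                raise DomainError(f"observation field {name} must be positive, "
                                  f"got {getattr(self, name)}")


@dataclass(frozen=True)
class AutogenicFit:
    """Fitted extruder-specific autogenic parameters.

    ``tau_extruder`` is reported with the standard deviation of the
    per-observation estimates (eta_die * n); slope/intercept come from the
    log-log regression together with its Pearson correlation coefficient.
    """

    tau_extruder: float  # Pa
    tau_sd: float  # Pa
    s_extruder: float  # dimensionless slope
    i_extruder: float  # dimensionless intercept
    r_correlation: float  # Pearson R of the log-log regression
    n_points_used: int | None = None

    def __post_init__(self):
        if not self.tau_extruder > 0:
            raise DomainError("tau_extruder must be positive")
        if self.tau_sd < 0:
            raise DomainError("tau_sd must be non-negative")
        if math.isfinite(self.r_correlation) and not -1 <= self.r_correlation <= 1:
            raise DomainError("correlation coefficient must lie in [-1, 1]")


@dataclass(frozen=True)
class PredictionResult:
    """Predicted operating point at one screw speed."""

    n: float  # 1/s
    mass_flow: float  # kg/s
    eta_die: float  # Pa*s, tau_extruder / n
    eta_calculated: float  # Pa*s, extruder-independent viscosity
    corrected_die_shear_rate: float  # 1/s
    melt_temperature: float  # K


#: Published autogenic fits for the reference ZSE 27 setup (tau av +/- sd,
#: slope, intercept, Pearson R of the log-log regression).
REFERENCE_FITS = {
    "PVPVA": AutogenicFit(399.0, 26.9, 0.409, 0.131, 0.958),
    "SOL": AutogenicFit(361.0, 12.3, 0.318, 0.036, 0.986),
    "bBMA": AutogenicFit(361.0, 14.2, 0.126, 0.045, 0.979),
}


def observation_die_viscosity(
    obs: ExtrusionObservation,
    geom: ExtruderGeometry,
    material: MaterialProperties,
    melt_density: float | None = None,
    wr_correction: bool = True,
) -> tuple[float, float]:
    """Die viscosity and (corrected) die shear rate for one observation.

    The volume flow through the die is the mass flow divided by the melt
    density; by default the true (pycnometric) density stands in for the melt
    density, which is the closest available quantity, and can be overridden.
    With ``wr_correction`` (default) the Weissenberg-Rabinowitsch-corrected
    shear rate is used both for the viscosity and in the returned shear rate.
    """
    rho = material.rho_true if melt_density is None else melt_density
    volume_flow = obs.mass_flow / rho
    gammadot = die_flow.die_shear_rate(volume_flow, geom)
    if wr_correction:
        gammadot = die_flow.wr_corrected_shear_rate(gammadot, material.rheology.c)
    eta = die_flow.die_shear_stress(obs.die_pressure, geom) / gammadot
    return eta, gammadot


def _qualifying(observations: Sequence[ExtrusionObservation],
                min_speed: float) -> list[ExtrusionObservation]:
    kept = [o for o in observations if o.n >= min_speed]
    if len(kept) < 2:
        raise FittingError(
            f"need >= 2 observations at screw speed >= {min_speed:.4g} 1/s "
            f"({min_speed * 60:.0f} rpm); {len(kept)} of {len(observations)} qualify")
    return kept


def fit_tau_extruder(
    observations: Sequence[ExtrusionObservation],
    geom: ExtruderGeometry,
    material: MaterialProperties,
    min_speed: float = DEFAULT_MIN_SPEED,
    melt_density: float | None = None,
    wr_correction: bool = True,
) -> tuple[float, float, int]:
    """Characteristic shear stress tau_extruder = mean of eta_die * n.

    Returns ``(tau, sd, n_used)`` over the observations at or above
    ``min_speed``; the hyperbola eta_die = tau/n makes eta_die * n a
    per-point estimate of tau, and the mean weights all speeds equally.
    """
    kept = _qualifying(observations, min_speed)
    taus = np.array([
        observation_die_viscosity(o, geom, material, melt_density,
                                  wr_correction)[0] * o.n
        for o in kept
    ])
    return float(taus.mean()), float(taus.std(ddof=1)), len(kept)


def fit_viscosity_ratio(
    observations: Sequence[ExtrusionObservation],
    geom: ExtruderGeometry,
    material: MaterialProperties,
    min_speed: float = DEFAULT_MIN_SPEED,
    melt_density: float | None = None,
    wr_correction: bool = True,
) -> tuple[float, float, float]:
    """Slope, intercept and Pearson R of the log-log viscosity-ratio law.

    For each qualifying observation, eta_die comes from die pressure and
    volume flow, and eta_calculated from the Carreau-Arrhenius model at the
    corrected die shear rate and the *measured* melt temperature; ordinary
    least squares of lg(eta_die/eta_calculated) on lg(n/n_max) gives the
    extruder parameters.
    """
    kept = _qualifying(observations, min_speed)
    x, y = [], []
    for o in kept:
        eta_die, gammadot = observation_die_viscosity(
            o, geom, material, melt_density, wr_correction)
        eta_calc = rheology.viscosity(material.rheology, gammadot,
                                      o.melt_temperature)
        x.append(math.log10(o.n / geom.n_max))
        y.append(math.log10(eta_die / eta_calc))
    x = np.array(x)
    y = np.array(y)
    if np.ptp(x) == 0:
        raise FittingError("all qualifying observations share one screw speed; "
                           "the slope is unidentifiable")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def fit_autogenic(
    observations: Sequence[ExtrusionObservation],
    geom: ExtruderGeometry,
    material: MaterialProperties,
    min_speed: float = DEFAULT_MIN_SPEED,
    melt_density: float | None = None,
    wr_correction: bool = True,
) -> AutogenicFit:
    """Fit both autogenic correlations and bundle the result."""
    tau, sd, n_used = fit_tau_extruder(observations, geom, material, min_speed,
                                       melt_density, wr_correction)
    slope, intercept, r = fit_viscosity_ratio(observations, geom, material,
                                              min_speed, melt_density,
                                              wr_correction)
    return AutogenicFit(tau_extruder=tau, tau_sd=sd, s_extruder=slope,
                        i_extruder=intercept, r_correlation=r,
                        n_points_used=n_used)


def predict_operating_point(
    n: float,
    fit: AutogenicFit,
    material: MaterialProperties,
    geom: ExtruderGeometry,
    sfl_max: float,
    melt_density: float | None = None,
    wr_correction: bool = True,
) -> PredictionResult:
    """Predict the full operating point at screw speed ``n`` (1/s).

    Chain: mass flow at the maximum feed load; die shear rate from the
    volume flow; die viscosity tau/n; extruder-independent viscosity by
    inverting the log-log ratio law; melt temperature by numerically
    inverting the Carreau-Arrhenius model at that viscosity and shear rate.
    """
    if n <= 0:
        raise DomainError(f"screw speed must be positive, got {n}")
    mass_flow = sfl_max * material.rho_true * n * geom.d ** 3
    rho = material.rho_true if melt_density is None else melt_density
    gammadot = die_flow.die_shear_rate(mass_flow / rho, geom)
    if wr_correction:
        gammadot = die_flow.wr_corrected_shear_rate(gammadot, material.rheology.c)
    eta_die = fit.tau_extruder / n
    log_ratio = fit.s_extruder * math.log10(n / geom.n_max) + fit.i_extruder
    eta_calc = eta_die * 10.0 ** (-log_ratio)
    T = rheology.invert_temperature(material.rheology, gammadot, eta_calc)
    return PredictionResult(n=n, mass_flow=mass_flow, eta_die=eta_die,
                            eta_calculated=eta_calc,
                            corrected_die_shear_rate=gammadot,
                            melt_temperature=T)


def crossover_parameters(fits: Iterable[AutogenicFit]) -> AutogenicFit:
    """Combine donor fits into transfer parameters by arithmetic averaging.

    Used for crossover validation: the extruder parameters for one material
    are derived from fits on the other materials. tau, slope and intercept
    are averaged; the tau dispersion is averaged as well, and the correlation
    coefficient (a property of each donor regression, not of the combination)
    is reported as NaN unless there is a single donor.
    """
    donor_list = list(fits)
    if not donor_list:
        raise FittingError("crossover requires at least one donor fit")
    if len(donor_list) == 1:
        return replace(donor_list[0])
    return AutogenicFit(
        tau_extruder=float(np.mean([f.tau_extruder for f in donor_list])),
        tau_sd=float(np.mean([f.tau_sd for f in donor_list])),
        s_extruder=float(np.mean([f.s_extruder for f in donor_list])),
        i_extruder=float(np.mean([f.i_extruder for f in donor_list])),
        r_correlation=float("nan"),
        n_points_used=sum(f.n_points_used or 0 for f in donor_list) or None,
    )
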
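"""Virtual autogenic extruder.

Forward-generates steady-state observation tables from ground-truth
parameters so every fitting and prediction stage can be exercised, and its
error calibrated, without a physical extruder. The generator runs the
prediction chain forwards at each requested screw speed:

* mass flow at maximum feed load (SFL* = 1, the condition an operator holds
  during the throughput ramp),
* die viscosity from the hyperbola eta_die = tau/n,
* extruder-independent viscosity from the log-log ratio law,
* melt temperature by numerically inverting the rheology model at the
  corrected die shear rate,
* die pressure by running the capillary equations backwards from the die
  viscosity.

Measurement noise is then applied: additive Gaussian on the melt temperature
(IR-camera-like reading error) and multiplicative Gaussian on the die
pressure (gauge error proportional to the reading). Mass flow and screw
speed are set-points and carry no noise. With both noise terms at zero the
generated table is an exact fixed point of the fitting routines: fitting
recovers the ground truth to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import die_flow, feeding, rheology
from .autogenic import AutogenicFit, ExtrusionObservation
from .errors import BracketingError, DomainError, Sios2Error
from .feeding import ExtruderGeometry
from .materials import PVPVA, REFERENCE_SLIPS, MaterialProperties, zse27_geometry
from .units import rpm_to_per_s

#: Default campaign speeds: an 8-point ramp over 100-500 rpm, matching the
#: window in which autogenic steady state is reliably reached.
DEFAULT_SPEEDS = tuple(rpm_to_per_s(r) for r in
                       (100.0, 157.0, 214.0, 271.0, 329.0, 386.0, 443.0, 500.0))


@dataclass(frozen=True)
class SimulationScenario:
    """Ground truth plus noise model for one simulated autogenic campaign."""

    material: MaterialProperties
    geometry: ExtruderGeometry
    true_slip: float
    true_tau: float  # Pa
    true_slope: float
    true_intercept: float
    speeds: tuple = DEFAULT_SPEEDS  # 1/s
    noise_T: float = 1.0  # K, additive std dev on melt temperature
    noise_p_rel: float = 0.01  # relative std dev on die pressure
    seed: int = 0

    def __post_init__(self):
        if self.noise_T < 0 or self.noise_p_rel < 0:
            raise DomainError("noise magnitudes must be non-negative")
        if not 0 <= self.true_slip < 1:
            raise DomainError(f"slip must lie in [0, 1), got {self.true_slip}")
        if not self.true_tau > 0:
            raise DomainError("true_tau must be positive")
        speeds = tuple(float(s) for s in self.speeds)
        if len(speeds) == 0 or any(s <= 0 for s in speeds):
            raise DomainError("speeds must be positive")
        if len(set(speeds)) != len(speeds):
            raise DomainError("speeds must be distinct")
        object.__setattr__(self, "speeds", speeds)


def reference_scenario(material: MaterialProperties = PVPVA,
                       seed: int = 0, **overrides) -> SimulationScenario:
    """Scenario for a reference material on the bundled ZSE 27 setup.

    Ground truth uses the material's published slip and autogenic fit, so the
    simulated campaign emulates the real one at its documented conditions.
    """
    from .autogenic import REFERENCE_FITS

    fit = REFERENCE_FITS[material.name]
    base = dict(
        material=material,
        geometry=zse27_geometry(),
        true_slip=REFERENCE_SLIPS[material.name],
        true_tau=fit.tau_extruder,
        true_slope=fit.s_extruder,
        true_intercept=fit.i_extruder,
        seed=seed,
    )
    base.update(overrides)
    return SimulationScenario(**base)


def scenario_fit(scenario: SimulationScenario) -> AutogenicFit:
    """The scenario's ground truth packaged as an :class:`AutogenicFit`."""
    return AutogenicFit(tau_extruder=scenario.true_tau, tau_sd=0.0,
                        s_extruder=scenario.true_slope,
                        i_extruder=scenario.true_intercept,
                        r_correlation=1.0, n_points_used=len(scenario.speeds))


def simulate_autogenic_campaign(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> list[ExtrusionObservation]:
    """Generate one observation per scenario speed, deterministic per seed.

    An explicit ``rng`` overrides the scenario seed (used for replicate
    studies that manage their own seed streams).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    mat, geom = scenario.material, scenario.geometry
    powder = mat.powder(scenario.true_slip)
    wr = die_flow.wr_correction_factor(mat.rheology.c)

    observations = []
    for n in scenario.speeds:
        mass_flow = feeding.max_mass_flow(powder, geom, n)  # SFL* = 1
        gammadot_app = die_flow.die_shear_rate(mass_flow / mat.rho_true, geom)
        gammadot = gammadot_app * wr
        eta_die = scenario.true_tau / n
        log_ratio = (scenario.true_slope * np.log10(n / geom.n_max)
                     + scenario.true_intercept)
        eta_calc = eta_die * 10.0 ** (-log_ratio)
        try:
            T = rheology.invert_temperature(mat.rheology, gammadot, eta_calc)
        except BracketingError as err:
            raise Sios2Error(
                f"cannot realise the scenario at n = {n * 60:.0f} rpm: {err}"
            ) from err
        # Invert the capillary relation: eta_die = (dp r / 2l) / gammadot.
        dp = eta_die * gammadot * 2.0 * geom.l_die / geom.r_die

        T_obs = T + rng.normal(0.0, scenario.noise_T) if scenario.noise_T else T
        dp_obs = dp * (1.0 + rng.normal(0.0, scenario.noise_p_rel)) \
            if scenario.noise_p_rel else dp
        observations.append(ExtrusionObservation(
            n=n, mass_flow=mass_flow, melt_temperature=T_obs,
            die_pressure=dp_obs))
    return observations


def noiseless(scenario: SimulationScenario) -> SimulationScenario:
    """Copy of the scenario with both noise terms switched off."""
    return replace(scenario, noise_T=0.0, noise_p_rel=0.0)
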
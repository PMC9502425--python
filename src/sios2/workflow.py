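"""End-to-end orchestration: slip calibration, autogenic fit, prediction.

The procedure this module automates replaces most of the original two-step
extrusion optimisation with calculation:

1. measure material characteristics (densities, melt rheology);
2. record the extruder geometry;
3. calibrate the powder slip from maximum-conveyable-mass-flow runs at a few
   screw speeds (linear regression through the origin);
4. run a handful of autogenic steady states at maximum feed load, fit the
   extruder correlations (characteristic shear stress; log-log viscosity
   ratio), and from then on *calculate* throughput and melt temperature as
   functions of screw speed.

:func:`run_sios2` executes 3-4 plus a prediction sweep from tabular inputs
and returns a serialisable report; :func:`plan_experiments` prints the
autogenic experiment protocol with concrete set-points;
:func:`crossover_report` validates transferability by predicting one
material from parameters fitted on others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import autogenic, feeding, io, units
from .autogenic import AutogenicFit, ExtrusionObservation, PredictionResult
from .errors import DomainError, FittingError
from .feeding import ExtruderGeometry
from .materials import MaterialProperties

DEFAULT_DOWN_RATIO = 2.0 / 3.0
DEFAULT_UP_RATIO = 4.0 / 3.0


@dataclass(frozen=True)
class PlanStep:
    """One step of the autogenic experiment protocol."""

    label: str
    instruction: str
    screw_speed: float | None = None  # 1/s
    mass_flow: float | None = None  # kg/s


@dataclass(frozen=True)
class Sios2Report:
    """Everything the fitting-plus-prediction pipeline produces."""

    material: str
    slip: float
    slip_points_used: int
    sfl_max: float
    fit: AutogenicFit
    predictions: tuple[PredictionResult, ...]
    min_speed: float  # 1/s threshold used for autogenic fitting
    n_observations: int
    n_excluded: int
    provenance: dict

    def __post_init__(self):
        speeds = [p.n for p in self.predictions]
        if any(b <= a for a, b in zip(speeds, speeds[1:])):
            raise DomainError("prediction table speeds must be strictly increasing")
        object.__setattr__(self, "predictions", tuple(self.predictions))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Sios2Report":
        d = dict(d)
        d["fit"] = AutogenicFit(**d["fit"])
        d["predictions"] = tuple(PredictionResult(**p) for p in d["predictions"])
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Sios2Report":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def prediction_frame(self) -> pd.DataFrame:
        """Prediction sweep in operator units (rpm, kg/h, degC)."""
        return pd.DataFrame({
            "screw_speed_rpm": [units.per_s_to_rpm(p.n) for p in self.predictions],
            "mass_flow_kg_h": [units.kg_s_to_kg_h(p.mass_flow)
                               for p in self.predictions],
            "eta_die_Pa_s": [p.eta_die for p in self.predictions],
            "eta_calculated_Pa_s": [p.eta_calculated for p in self.predictions],
            "melt_temp_C": [units.kelvin_to_celsius(p.melt_temperature)
                            for p in self.predictions],
        })


def plan_experiments(
    powder: feeding.PowderState,
    geom: ExtruderGeometry,
    start_speed: float,
    down_ratio: float = DEFAULT_DOWN_RATIO,
    up_ratio: float = DEFAULT_UP_RATIO,
) -> list[PlanStep]:
    """Autogenic experiment protocol with concrete set-points.

    The first operating point is the completely-filled-feeding-section
    (SFL* = 1) mass flow at ``start_speed``; follow-up points scale speed
    and mass flow by the same ratio (down if power consumption is low, up if
    it is high), which preserves SFL* = 1 exactly.
    """
    if start_speed <= 0:
        raise DomainError("start speed must be positive")
    m0 = feeding.max_mass_flow(powder, geom, start_speed)
    rpm = units.per_s_to_rpm
    kgh = units.kg_s_to_kg_h
    return [
        PlanStep("setup", "Set barrels to the manufacturer's recommended "
                          "process temperature; cool the feeding section to "
                          "ambient to avoid clogging."),
        PlanStep("first point",
                 f"Run at {rpm(start_speed):.0f} rpm with the SFL* = 1 mass "
                 f"flow of {kgh(m0):.2f} kg/h; wait for coherent extrudate, "
                 "then switch off barrel temperature control (keep feeding "
                 "section cooled, die heated). Record speed, mass flow, melt "
                 "temperature and die pressure at steady state.",
                 screw_speed=start_speed, mass_flow=m0),
        PlanStep("low-power branch",
                 f"If power consumption is below ~50% of nominal, scale speed "
                 f"and mass flow by {down_ratio:.3g}: "
                 f"{rpm(start_speed * down_ratio):.0f} rpm at "
                 f"{kgh(m0 * down_ratio):.2f} kg/h (SFL* stays 1). Record the "
                 "same quantities at steady state.",
                 screw_speed=start_speed * down_ratio,
                 mass_flow=m0 * down_ratio),
        PlanStep("high-power branch",
                 f"If power consumption is high, scale speed and mass flow by "
                 f"{up_ratio:.3g}: {rpm(start_speed * up_ratio):.0f} rpm at "
                 f"{kgh(m0 * up_ratio):.2f} kg/h (SFL* stays 1). Record the "
                 "same quantities at steady state.",
                 screw_speed=start_speed * up_ratio,
                 mass_flow=m0 * up_ratio),
        PlanStep("fit", "Fit the characteristic shear stress and the log-log "
                        "viscosity-ratio law from the recorded points; "
                        "calculate melt temperature vs screw speed."),
    ]


def run_sios2(
    slip_table,
    autogenic_table,
    material: MaterialProperties,
    geom: ExtruderGeometry,
    prediction_speeds: Sequence[float],
    min_speed: float = autogenic.DEFAULT_MIN_SPEED,
) -> Sios2Report:
    """Full pipeline: slip fit -> SFLmax -> autogenic fit -> prediction sweep.

    ``slip_table`` and ``autogenic_table`` may be CSV paths or DataFrames in
    the documented operator-unit schemas; ``prediction_speeds`` are in 1/s
    and must be strictly increasing.
    """
    speeds, flows = io.read_feeding_csv(slip_table) \
        if not isinstance(slip_table, tuple) else slip_table
    slip = feeding.fit_slip(speeds, flows, material.rho_bulk, geom)
    powder = material.powder(slip)
    sflmax = feeding.sfl_max(powder, geom)

    observations = autogenic_table if _is_observation_list(autogenic_table) \
        else io.read_autogenic_csv(autogenic_table)
    fit = autogenic.fit_autogenic(observations, geom, material,
                                  min_speed=min_speed)
    predictions = tuple(
        autogenic.predict_operating_point(n, fit, material, geom, sflmax)
        for n in prediction_speeds
    )
    return Sios2Report(
        material=material.name,
        slip=slip,
        slip_points_used=len(speeds),
        sfl_max=sflmax,
        fit=fit,
        predictions=predictions,
        min_speed=min_speed,
        n_observations=len(observations),
        n_excluded=len(observations) - (fit.n_points_used or 0),
        provenance={
            "min_speed_rpm": units.per_s_to_rpm(min_speed),
            "slip_source": str(slip_table) if isinstance(slip_table, (str, Path))
            else "in-memory",
            "autogenic_source": str(autogenic_table)
            if isinstance(autogenic_table, (str, Path)) else "in-memory",
        },
    )


def _is_observation_list(obj) -> bool:
    return isinstance(obj, (list, tuple)) and obj and \
        isinstance(obj[0], ExtrusionObservation)


def crossover_report(
    donor_fits: Sequence[AutogenicFit],
    donor_slips: Sequence[float],
    target_material: MaterialProperties,
    geom: ExtruderGeometry,
    target_observations: Sequence[ExtrusionObservation],
) -> pd.DataFrame:
    """Predict a material from parameters fitted on *other* materials.

    The donor fits are averaged into transfer parameters; the donor slips are
    averaged and combined with the *target's own* bulk density to predict the
    mass flow. Per observation the report lists predicted vs measured melt
    temperature (ΔT, K) and the relative mass-flow deviation.
    """
    if len(donor_fits) == 0 or len(donor_fits) != len(donor_slips):
        raise FittingError("need matching, non-empty donor fits and slips")
    combined = autogenic.crossover_parameters(donor_fits)
    slip = float(np.mean(donor_slips))
    powder = target_material.powder(slip)
    sflmax = feeding.sfl_max(powder, geom)

    rows = []
    for obs in target_observations:
        pred = autogenic.predict_operating_point(
            obs.n, combined, target_material, geom, sflmax)
        rows.append({
            "screw_speed_rpm": units.per_s_to_rpm(obs.n),
            "measured_melt_temp_C": units.kelvin_to_celsius(obs.melt_temperature),
            "predicted_melt_temp_C": units.kelvin_to_celsius(pred.melt_temperature),
            "delta_T_K": pred.melt_temperature - obs.melt_temperature,
            "measured_mass_flow_kg_h": units.kg_s_to_kg_h(obs.mass_flow),
            "predicted_mass_flow_kg_h": units.kg_s_to_kg_h(pred.mass_flow),
            "rel_delta_mass_flow": (pred.mass_flow - obs.mass_flow) / obs.mass_flow,
        })
    return pd.DataFrame(rows)
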
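"""File formats: YAML parameter configs and operator-unit CSV tables.

Config and CSV files use the units an extrusion line is run in (rpm, degC,
bar, kg/h); conversion to the package's internal SI units happens here and
only here.

Schemas
-------
Material config (YAML)::

    eta0_Pa_s: 169.7
    gammadot_c_per_s: 133.1
    c: 0.387
    Ea_J_per_mol: 198292
    T_ref_K: 473
    rho_bulk_kg_m3: 315
    rho_true_kg_m3: 1190
    name: PVPVA            # optional

Geometry config (YAML)::

    d_m: 0.0283
    A_free_m2: 4.91e-4
    l_pitch_m: 0.06
    r_die_m: 0.0015
    l_die_m: 0.0117
    n_max_rpm: 1200

Autogenic-experiment CSV: screw_speed_rpm, mass_flow_kg_h, melt_temp_C,
die_pressure_bar. Feeding-experiment CSV: screw_speed_rpm,
max_mass_flow_kg_h. Flow-curve CSV: shear_rate_per_s, temperature_C,
viscosity_Pa_s.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import units
from .autogenic import ExtrusionObservation
from .errors import SchemaError
from .feeding import ExtruderGeometry
from .materials import MaterialProperties
from .rheology import CarreauArrheniusParams, FlowCurvePoint

MATERIAL_KEYS = ("eta0_Pa_s", "gammadot_c_per_s", "c", "Ea_J_per_mol",
                 "T_ref_K", "rho_bulk_kg_m3", "rho_true_kg_m3")
GEOMETRY_KEYS = ("d_m", "A_free_m2", "l_pitch_m", "r_die_m", "l_die_m",
                 "n_max_rpm")
AUTOGENIC_COLUMNS = ("screw_speed_rpm", "mass_flow_kg_h", "melt_temp_C",
                     "die_pressure_bar")
FEEDING_COLUMNS = ("screw_speed_rpm", "max_mass_flow_kg_h")
FLOW_CURVE_COLUMNS = ("shear_rate_per_s", "temperature_C", "viscosity_Pa_s")


def _require_keys(mapping: dict, keys, what: str, path) -> None:
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise SchemaError(f"{what} {path}: missing keys {missing}")


def load_material(path) -> MaterialProperties:
    """Read a material parameter file (YAML)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"material config {path}: expected a mapping")
    _require_keys(data, MATERIAL_KEYS, "material config", path)
    return MaterialProperties(
        name=str(data.get("name", path.stem)),
        rho_bulk=float(data["rho_bulk_kg_m3"]),
        rho_true=float(data["rho_true_kg_m3"]),
        rheology=CarreauArrheniusParams(
            eta0=float(data["eta0_Pa_s"]),
            gammadot_c=float(data["gammadot_c_per_s"]),
            c=float(data["c"]),
            Ea=float(data["Ea_J_per_mol"]),
            T_ref=float(data["T_ref_K"]),
        ),
    )


def save_material(material: MaterialProperties, path) -> None:
    rh = material.rheology
    Path(path).write_text(yaml.safe_dump({
        "name": material.name,
        "eta0_Pa_s": rh.eta0,
        "gammadot_c_per_s": rh.gammadot_c,
        "c": rh.c,
        "Ea_J_per_mol": rh.Ea,
        "T_ref_K": rh.T_ref,
        "rho_bulk_kg_m3": material.rho_bulk,
        "rho_true_kg_m3": material.rho_true,
    }, sort_keys=False))


def load_geometry(path) -> ExtruderGeometry:
    """Read an extruder geometry file (YAML)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"geometry config {path}: expected a mapping")
    _require_keys(data, GEOMETRY_KEYS, "geometry config", path)
    return ExtruderGeometry(
        d=float(data["d_m"]),
        A_free=float(data["A_free_m2"]),
        l_pitch=float(data["l_pitch_m"]),
        r_die=float(data["r_die_m"]),
        l_die=float(data["l_die_m"]),
        n_max=units.rpm_to_per_s(float(data["n_max_rpm"])),
    )


def save_geometry(geom: ExtruderGeometry, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "d_m": geom.d,
        "A_free_m2": geom.A_free,
        "l_pitch_m": geom.l_pitch,
        "r_die_m": geom.r_die,
        "l_die_m": geom.l_die,
        "n_max_rpm": units.per_s_to_rpm(geom.n_max),
    }, sort_keys=False))


def _read_table(path_or_frame, columns, what: str) -> pd.DataFrame:
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
        where = "<in-memory frame>"
    else:
        where = str(path_or_frame)
        df = pd.read_csv(path_or_frame)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} {where}: missing columns {missing}")
    sub = df[list(columns)]
    bad = sub.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.loc[row][bad.loc[row]].index[0]
        raise SchemaError(f"{what} {where}: missing value in column "
                          f"'{col}', row {row}")
    return sub


def read_autogenic_csv(path) -> list[ExtrusionObservation]:
    """Read an autogenic experiment table into SI observations."""
    df = _read_table(path, AUTOGENIC_COLUMNS, "autogenic table")
    return [
        ExtrusionObservation(
            n=units.rpm_to_per_s(row.screw_speed_rpm),
            mass_flow=units.kg_h_to_kg_s(row.mass_flow_kg_h),
            melt_temperature=units.celsius_to_kelvin(row.melt_temp_C),
            die_pressure=units.bar_to_pa(row.die_pressure_bar),
        )
        for row in df.itertuples(index=False)
    ]


def write_autogenic_csv(observations, path) -> None:
    """Write observations in the operator-unit autogenic CSV schema."""
    pd.DataFrame({
        "screw_speed_rpm": [units.per_s_to_rpm(o.n) for o in observations],
        "mass_flow_kg_h": [units.kg_s_to_kg_h(o.mass_flow) for o in observations],
        "melt_temp_C": [units.kelvin_to_celsius(o.melt_temperature)
                        for o in observations],
        "die_pressure_bar": [units.pa_to_bar(o.die_pressure)
                             for o in observations],
    }).to_csv(path, index=False)


def read_feeding_csv(path) -> tuple[list[float], list[float]]:
    """Read a feeding-limit table; returns (speeds 1/s, max mass flows kg/s)."""
    df = _read_table(path, FEEDING_COLUMNS, "feeding table")
    return ([units.rpm_to_per_s(v) for v in df["screw_speed_rpm"]],
            [units.kg_h_to_kg_s(v) for v in df["max_mass_flow_kg_h"]])


def read_flow_curve_csv(path) -> list[FlowCurvePoint]:
    """Read rheometer flow-curve data."""
    df = _read_table(path, FLOW_CURVE_COLUMNS, "flow-curve table")
    return [
        FlowCurvePoint(
            shear_rate=row.shear_rate_per_s,
            temperature=units.celsius_to_kelvin(row.temperature_C),
            viscosity=row.viscosity_Pa_s,
        )
        for row in df.itertuples(index=False)
    ]
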
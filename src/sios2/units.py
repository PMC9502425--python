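"""Unit conversions at the I/O boundary.

Everything inside the package is SI: temperatures in kelvin, screw speeds in
1/s, pressures in Pa, mass flows in kg/s. Operator-facing files and the CLI
use the units an extrusion line is run in (rpm, degC, bar, kg/h); these
helpers are the only place the conversions live.
"""

KELVIN_OFFSET = 273.15
PA_PER_BAR = 1.0e5
SECONDS_PER_HOUR = 3600.0


def rpm_to_per_s(n_rpm):
    """Screw speed, revolutions per minute -> revolutions per second."""
    return n_rpm / 60.0


def per_s_to_rpm(n):
    return n * 60.0


def celsius_to_kelvin(t_c):
    return t_c + KELVIN_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - KELVIN_OFFSET


def bar_to_pa(p_bar):
    return p_bar * PA_PER_BAR


def pa_to_bar(p_pa):
    return p_pa / PA_PER_BAR


def kg_h_to_kg_s(mdot):
    return mdot / SECONDS_PER_HOUR


def kg_s_to_kg_h(mdot):
    return mdot * SECONDS_PER_HOUR
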
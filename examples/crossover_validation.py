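"""Transfer extruder parameters between materials (crossover validation).

The autogenic parameters (tau, slope, intercept) are properties of the
extruder setup, not of the material. To test that, each reference polymer's
campaign is predicted using parameters averaged from the *other two*
polymers, and the predicted melt temperatures and mass flows are compared
with the material's own (simulated) campaign.
"""

import sios2 as s
from sios2.units import rpm_to_per_s

geom = s.zse27_geometry()
names = ["PVPVA", "SOL", "bBMA"]
speeds = tuple(rpm_to_per_s(r) for r in (200.0, 300.0, 400.0, 500.0))

for target_name in names:
    donors = [n for n in names if n != target_name]
    mat = s.REFERENCE_MATERIALS[target_name]
    observations = s.simulate_autogenic_campaign(
        s.noiseless(s.reference_scenario(mat, speeds=speeds)))
    frame = s.crossover_report(
        [s.REFERENCE_FITS[n] for n in donors],
        [s.REFERENCE_SLIPS[n] for n in donors],
        mat, geom, observations)
    print(f"\n{target_name} predicted from {donors[0]} + {donors[1]}:")
    print(frame[["screw_speed_rpm", "measured_melt_temp_C",
                 "predicted_melt_temp_C", "delta_T_K",
                 "rel_delta_mass_flow"]].to_string(
        index=False, float_format=lambda v: f"{v:8.2f}"))

print("\nAt high speed (the desired operating range) the temperature "
      "transfer error stays within a few kelvin; it grows toward low "
      "speeds, where autogenic equilibrium is hard to reach in practice. "
      "Mass-flow deviations reflect the (small) slip differences between "
      "the powders.")
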
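"""Print the autogenic experiment protocol with concrete set-points.

Given a powder's slip and the extruder geometry, the planner emits the
minimal campaign needed to calibrate the autogenic correlations: a first
steady state at a completely filled feeding section (SFL* = 1), plus
follow-up points scaled up or down by a fixed ratio depending on power
consumption -- scaling speed and mass flow together keeps SFL* = 1.
"""

import sios2 as s
from sios2.units import rpm_to_per_s

steps = s.plan_experiments(
    s.PVPVA.powder(slip=0.865),
    s.zse27_geometry(),
    start_speed=rpm_to_per_s(200.0),
)
for i, step in enumerate(steps, 1):
    print(f"{i}. [{step.label}] {step.instruction}\n")
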
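"""Closed-form SLM pattern design for the two objective configurations.

Prints the numbers an instrument builder checks before wiring anything:
demagnification of the SLM-to-sample relay, grating period in µm and SLM
pixels, pattern orientation angles of the three integer SLM vectors, the
pinhole-mask spot offset and the zero/first diffraction-order ratio.
"""

import json

from simtools.illumination import design_table
from simtools.optics import OpticalModel

for name, model in (
    ("1.35 NA silicone oil", OpticalModel.silicone_oil()),
    ("1.27 NA water", OpticalModel.water()),
):
    table = design_table(model, duty_cycle=0.33)
    print(f"--- {name}")
    print(json.dumps(table, indent=1))

print(
    "\nThe periods (45.5 µm and 37.6 µm at 488 nm) set the ±1-order beams "
    "at 92% of the pupil radius; the ~0.39 zero/first intensity ratio at "
    "33% duty cycle keeps the axial interference orders strong."
)
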
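"""OTF support geometry of the five imaging modalities.

Builds the (k_r, k_z) support masks and prints their lateral and axial
extents plus the set relations between them — the frequency-space story
of why four-beam interference improves axial resolution.
"""

from simtools.optics import OpticalModel
from simtools.otf import MODALITIES, support

model = OpticalModel.water()
sups = {mod: support(mod, model, dk=0.05) for mod in MODALITIES}
for mod in MODALITIES:
    s = sups[mod]
    print(
        f"{mod:>13}: lateral extent {s.lateral_extent:.2f} cycles/µm, "
        f"axial extent {s.axial_extent:.2f} cycles/µm, "
        f"{int(s.mask.sum())} mask pixels"
    )
for small, large in (("widefield", "sim3d"), ("sim3d", "four_beam"), ("four_beam", "i5s")):
    print(f"{small} ⊆ {large}: {sups[large].contains(sups[small])}")
print(
    "\nThe standing-wave support shows the on-axis gaps at ±2n/λ_ex that "
    "preclude sectioning; four-beam SIM fills them with the seven 3D SIM "
    "components plus the reflected-beam cross terms, reaching almost the "
    "axial extent of the two-objective I⁵S geometry."
)
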
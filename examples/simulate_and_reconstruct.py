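"""Simulate a 3-beam SIM acquisition of beads and reconstruct it.

Builds a small bead field, renders the 5-phase × 3-orientation raw stack
with photon noise, recovers the pattern parameters from the data and runs
the generalized Wiener reconstruction.  Prints the estimated pattern
parameters and the bead FWHMs before and after reconstruction.
"""

import numpy as np

from simtools.metrics import bead_resolution_report
from simtools.optics import OpticalModel, make_beams
from simtools.otf import model_otfs
from simtools.phantoms import (
    AcquisitionConfig,
    bead_volume,
    simulate_acquisition,
    simulate_widefield,
)
from simtools.reconstruction import design_guess_kvecs, reconstruct

model = OpticalModel.water()
rng = np.random.default_rng(7)
n, px, dz = 96, 80.0, 125.0
positions = [
    (48 + rng.uniform(-1, 1), rng.uniform(20, 76), rng.uniform(20, 76))
    for _ in range(8)
]
volume = bead_volume((n, n, n), positions, 100.0, px, dz)

acq = AcquisitionConfig(modality="3-beam", z_step_nm=dz, pixel_size_nm=px, seed=1)
stack = simulate_acquisition(volume, model, acq)
print(f"raw stack: {stack.data.shape} (orientation, phase, z, y, x)")

otfs = model_otfs(model, make_beams(model, 0.0), shape=(n, n, n),
                  pixel_size_nm=px, z_step_nm=dz)
recon = reconstruct(stack, otfs, model, guess_kvecs=design_guess_kvecs(model, stack))
for d, p in enumerate(recon.params):
    mag = float(np.hypot(*p.wave_vector))
    print(
        f"orientation {d}: |k| = {mag:.4f} cycles/µm, φ₀ = {p.initial_phase:+.3f} rad, "
        f"m1 = {p.modulation_depth_1:.2f}, m2 = {p.modulation_depth_2:.2f}"
    )

wf = simulate_widefield(volume, model, px, dz)
wf_report = bead_resolution_report(wf, positions, px, dz)
recon_pos = [(z, 2 * y, 2 * x) for (z, y, x) in positions]
sim_report = bead_resolution_report(
    recon.volume, recon_pos, recon.pixel_size_nm, recon.z_step_nm
)
print(f"wide-field : lateral {wf_report.lateral_mean:.0f} ± {wf_report.lateral_sd:.0f} nm, "
      f"axial {wf_report.axial_mean:.0f} ± {wf_report.axial_sd:.0f} nm (n={wf_report.n})")
print(f"3-beam SIM : lateral {sim_report.lateral_mean:.0f} ± {sim_report.lateral_sd:.0f} nm, "
      f"axial {sim_report.axial_mean:.0f} ± {sim_report.axial_sd:.0f} nm (n={sim_report.n})")
print(
    "\nThe ~2× smaller lateral FWHM after reconstruction is the classic "
    "SIM resolution doubling; the design wave vector is 2.394 cycles/µm, "
    "so |k| above should sit within ~0.2% of it."
)
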
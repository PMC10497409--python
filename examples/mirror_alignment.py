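"""Closed-loop mirror alignment against the bead simulator.

Four-beam SIM needs the axial pattern maxima on the detection focal
plane.  The loop images a fiducial bead, estimates the focal plane from
the defocus (FWHM) curve and the standing-wave peak from the axial
profile, and feeds the difference back to the simulated piezo actuators.
"""

from simtools.alignment import AlignmentConfig, align_feedback
from simtools.optics import OpticalModel
from simtools.phantoms import MirrorAlignmentSimulator

model = OpticalModel.water()
sim = MirrorAlignmentSimulator(
    model, pattern_error_nm=40.0, stage_error_nm=120.0, noise=True,
    photon_scale=500.0, seed=3,
)
state = align_feedback(sim, AlignmentConfig(tolerance_nm=10.0))
for h in state.history:
    print(
        f"iteration {h['iteration']}: PSF offset {h['psf_offset']:+7.1f} nm, "
        f"SW peak {h['sw_peak']:+7.1f} nm, difference {h['difference']:+6.1f} nm"
    )
print(f"converged: {state.converged} after {state.iterations} iterations")
print(
    "\nThe first difference reads the initial 40-nm pattern offset; after "
    "the corrective mirror move the residual falls below the 10-nm "
    "tolerance, matching the instrument's 10–20 nm stability."
)
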
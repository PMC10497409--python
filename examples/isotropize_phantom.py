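"""Six-direction isotropization of an anisotropically blurred phantom.

The mixed dot/line/hollow-sphere phantom is blurred to SIM-like
anisotropic resolution (σ = 1.3, 1.3, 3.7 voxels in x, y, z), then passed
through the six-direction pipeline with the training-free known-kernel
Wiener operator and fused by max-modulus spectral selection.
"""

import numpy as np

from simtools.isotropize import DirectionalWiener, isotropize
from simtools.metrics import fwhm, ssim_psnr
from simtools.phantoms import PhantomConfig, blur_gaussian, make_mixed_phantom

config = PhantomConfig().scaled((96, 96, 96)).model_copy(update={"seed": 0})
phantom = make_mixed_phantom(config)
print(
    f"phantom: {phantom.count('dot')} dots, {phantom.count('line')} lines, "
    f"{phantom.count('sphere')} hollow spheres on a {config.grid_shape} grid"
)
ground_truth = blur_gaussian(phantom.volume, (1.3, 1.3, 1.3))
degraded = blur_gaussian(phantom.volume, (3.7, 1.3, 1.3))
fused = isotropize(degraded, DirectionalWiener(1.3, 3.7))

for name, vol in (("degraded", degraded), ("fused", fused)):
    s, p = ssim_psnr(vol, ground_truth)
    print(f"{name}: SSIM {s:.3f}, PSNR {p:.1f} dB vs isotropic ground truth")

dots = [
    s["pos"] for s in phantom.structures
    if s["kind"] == "dot" and s["intensity"] > 4000
    and all(12 < c < 84 for c in s["pos"])
]
ratios = []
for (z, y, x) in dots:
    if fused[z - 8 : z + 9, y - 8 : y + 9, x - 8 : x + 9].max() > fused[z, y, x] * 1.2:
        continue
    try:
        fl = fwhm(fused[z, y, x - 8 : x + 9], 1.0, "gaussian")
        fa = fwhm(fused[z - 8 : z + 9, y, x], 1.0, "gaussian")
        ratios.append(fa / fl)
    except (ValueError, RuntimeError):
        continue
print(
    f"median axial/lateral FWHM ratio on {len(ratios)} isolated dots: "
    f"{np.median(ratios):.2f} (degraded input ≈ 2.85)"
)
print(
    "\nA ratio near 1.1 means the fused volume is close to isotropic; the "
    "SSIM gain shows the enhancement adds fidelity, not just sharpness."
)
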
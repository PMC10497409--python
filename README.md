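# simtools — 3D and four-beam structured illumination microscopy, end to end in software

Three-dimensional structured illumination microscopy (3D SIM) illuminates a
fluorescent sample with the interference pattern of three coherent beams and
acquires five pattern phases at three orientations per plane. The patterned
excitation mixes object frequencies into the detection passband; unmixing and
reassembling them doubles lateral **and** axial resolution over wide-field
imaging. Placing a mirror directly opposite the sample back-reflects the
central beam, and the resulting **four-beam** interference adds an axial
standing wave at up to 2n/λ_ex — roughly doubling axial resolution again,
provided the pattern maxima are servoed onto the detection focal plane.

`simtools` implements the complete computational side of this instrument on
synthetic data, for people building or studying such systems without access
to one:

- **illumination** — SLM binary-grating design (orientation vectors, periods,
  duty cycle, pinhole-mask geometry) and the plane-wave interference model;
- **otf** — OTF support geometry for wide-field, 3D SIM, standing-wave,
  four-beam and I⁵S; model OTFs; per-order OTF extraction from bead stacks;
- **phantoms** — mixed dot/line/hollow-sphere volumes, bead fields, and the
  forward simulator producing full 5-phase × 3-orientation raw stacks with
  Poisson and read noise;
- **reconstruction** — band separation with the 5×5 phase matrix, pattern
  parameter estimation by cross-correlation, and the generalized Wiener
  filter (w = 0.001) with triangular apodization;
- **alignment** — the bead-based mirror/focus feedback loop for four-beam
  acquisition;
- **isotropize** — the six-direction rotation / enhancement / max-frequency
  fusion pipeline with a training-free known-kernel deconvolution operator
  standing in for a trained network;
- **metrics** — bead FWHM reports, SSIM/PSNR, spectral bandwidths.

The core relation implemented by the reconstruction is the generalized
Wiener combination over orientations d and orders m ∈ {0, ±1, ±2}:

```
S(k) = A(k) · Σ_{d,m} m̄_m · OTF*_m(k + m·p_d) · D_{d,m}(k + m·p_d)
       ─────────────────────────────────────────────────────────────
            Σ_{d,m} |m_m|² · |OTF_m(k + m·p_d)|²  +  w²
```

with D the separated bands, p_d the estimated pattern wave vector, m_m the
complex modulation depths and A a triangular apodization to the extended
cutoff. Four-beam data run through the identical machinery — the extra axial
frequencies live inside the per-order OTFs.

## Worked example

`python examples/simulate_and_reconstruct.py` simulates a noisy 3-beam
acquisition of eight 100-nm beads (96³ voxels, 80-nm pixels, 125-nm steps,
1.27 NA / 488 nm), estimates the pattern parameters from the data and
reconstructs:

```
orientation 0: |k| = 2.3925 cycles/µm, φ₀ = -0.000 rad, m1 = 0.94, m2 = 0.96
orientation 1: |k| = 2.3924 cycles/µm, φ₀ = +0.071 rad, m1 = 0.96, m2 = 0.95
orientation 2: |k| = 2.3938 cycles/µm, φ₀ = +0.078 rad, m1 = 0.93, m2 = 0.95
wide-field : lateral 210 ± 1 nm, axial 503 ± 3 nm (n=8)
3-beam SIM : lateral 116 ± 5 nm, axial 275 ± 8 nm (n=8)
```

The recovered |k| sits within 0.2% of the design value 2.394 cycles/µm, and
the lateral FWHM halves — the classic SIM doubling.
`python examples/four_beam_axial_resolution.py` adds the mirror:

```
3-beam: lateral FWHM 116 nm, axial FWHM 314 nm
4-beam: lateral FWHM 119 nm, axial FWHM 162 nm
```

`python examples/isotropize_phantom.py` runs the six-direction pipeline on
the blurred mixed phantom and reports the SSIM gain (0.77 → 0.92) and the
axial/lateral FWHM ratio falling from ≈2.85 to ≈1.14.

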
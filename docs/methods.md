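# Methods

This note records the models, conventions and numerical choices behind
`simtools`, in the order data flows through the package.

## Optical model and conventions

All geometry derives from `OpticalModel`: excitation/emission wavelengths,
NA, immersion index n, the side-beam pupil fraction r (default 0.92), the
SLM-to-sample relay (demagnification M = (f3/f_obj)·(f5/f4)) and the
sampling of camera and z piezo. Two presets mirror common configurations: a
1.35 NA silicone-oil lens (M = 115.7) and a 1.27 NA water lens (M = 90.1).
Volumes are `(z, y, x)` arrays; spatial frequencies are in cycles/µm;
spectra use the unshifted FFT layout internally and are only shifted for
display. All randomness flows through explicit seeds.

## Illumination

The SLM is modelled as a binary π phase grating. Orientations are integer
vectors A on the SLM grid (the three defaults give 10.3°, 70.3°, 130.2°);
the grating period is P = M·λ_ex/(r·NA); pixels switch to the π state when
the projection onto the unit pattern normal, reduced modulo the period,
falls below duty·period (ties to the 0 state). Ideal scalar diffraction
gives order amplitudes c₀ = 1 − 2d and |c₁| = 2·sin(πd)/π; hardware factors
(fill factor, reflections) that shift the measured zero/first ratio are not
modelled.

At the sample, each orientation is a set of plane waves with |k| = n/λ_ex:
three for 3D SIM, plus the mirrored central beam (k_z negated, amplitude
ρ·e^{iθ_m}) for four-beam operation. Expanding |Σ a_j e^{2πik_j·r}|²
pairwise and grouping by lateral harmonic m yields the complex axial
modulation J_m(z) per order — 7 frequency components for three beams, 13
for four. The mirror phase maps to physical travel as θ_m = 4πn·Δz/λ_ex;
s-polarization (unit contrast) is assumed, with a scalar contrast factor
for imperfect polarization.

## Forward model

Acquisition follows the sample-scanning convention: pattern and detection
focal plane fixed in the lab frame, sample translated axially. The recorded
volume is then an exact 3D convolution:

D_p = Re Σ_m e^{i·m·(φ₀+2πp/5)} · [S·e^{2πi·m·p_d·ρ}] ⊛ H_m,
H_m(ρ, ζ) = J_m(−ζ − Δ)·h_det(ρ, ζ),

where Δ is an optional pattern–focus offset (mirror misalignment). The
detection PSF h_det is a scalar pupil integral (per-plane defocus phase);
a Gaussian approximation is available for quick tests. The pupil PSF is
tapered to zero laterally well inside the grid: at NA 1.27 the defocus cone
outruns any finite field, and on a periodic grid that light would wrap
around and break the rotational symmetry that radial OTF averaging assumes.
Photon noise is Poisson on the scaled intensity (default 500 peak photons),
followed by Gaussian read noise (σ = 1.4 counts) and a constant offset
(100 counts) — typical sCMOS values, set in `AcquisitionConfig`, not taken
from any instrument. Default z steps are 125 nm (3-beam) and 60 nm
(four-beam), Nyquist for each modality's axial band.

## Phantoms

The mixed-structure generator places exactly 3,000 single-voxel dots
(2,000–7,000 counts), 1,800 unit-width lines (random 3D orientation drawn
over 1–360° in both angles (the double coverage of orientation space is
deliberate), lengths 1–72 px, 100–500 counts) and 600 hollow
spheres (inner diameter 2–20 px, shell 1–2 px, 10–200 counts) on a 300³
grid of 40-nm voxels, bit-reproducibly per seed. `scaled()` shrinks the
grid with proportional counts for desk-scale runs. Bead fields are
band-limited renderings of 100-nm solid spheres built in the Fourier
domain, so OTF extraction can compensate the bead size exactly.
`blur_gaussian` uses periodic boundaries and a 6σ kernel: mass is conserved
exactly and the blur is a true circular convolution, consistent with the
FFT deconvolutions applied downstream (a truncated or reflected kernel
leaves spectral tails that deconvolution amplifies into ringing).

## OTFs

Support masks live on a (k_r, k_z) grid. The wide-field toroid
cross-section is the region within n/λ_em of both arc centers
(NA/λ_em, ±n·cosα/λ_em); composed modalities are unions of that region
placed at the illumination components (7 for 3D SIM, +2 standing-wave and
+4 reflected-side terms for four-beam, the 19-component two-objective
geometry for I⁵S, whose coherent-detection support is rasterized
numerically). Masks are fattened by half a grid cell so boundary-touching
regions (the DC point, the standing-wave islands) survive rasterization.
The I⁵S support exists for comparison and plotting only.

Per-order OTFs are stored radially averaged (nearest-bin, count-weighted)
on the (k_z, k_r) grid, masked to their support and normalized to the
order-0 DC. `model_otfs` computes them directly from the forward kernels;
`extract_otf` recovers them from a simulated bead stack following the
measured-OTF procedure: phase summation, parabolic sub-pixel centering
(3-point lateral; 3-point axial for 3-beam, 5-point for four-beam),
squared-sine edge softening over 10% of each dimension, separation-matrix
unmixing, phase-ramp recentering, division by the solid-sphere transform
3[sin u − u·cos u]/u³ evaluated at the carried object frequency (clamped
where |transform| < 0.05), removal of the order-m carrier phase
e^{2πi·m·p·r₀} (otherwise the stored OTF would depend on where the bead
sat), rotational averaging, support masking and DC normalization.
Reconstruction revolves the 2D OTFs back to 3D by bilinear interpolation
at radius √(k_x²+k_y²).

## Reconstruction

1. **Preprocess** — offset subtraction with zero clamp, squared-sine edge
   window (10% of each lateral dimension), intensity normalization to the
   stack mean. One factor is shared by the five phases of each
   (orientation, z) plane: on sparse scenes the phase-to-phase variation
   of the total intensity is band information, and normalizing it away
   per image leaks order 0 into the higher bands. Per-image normalization
   remains available for bleaching-dominated data.
2. **Band separation** — the five phase spectra are unmixed with the
   inverse of V[p,m] = e^{i·m·2πp/5} (a scaled unitary; inverse Vᴴ/5).
3. **Parameter estimation** — the order-2 shift is found by correlating
   two object-spectrum estimates over the support overlap: order 0, and
   order 2 moved by the candidate shift, both divided by their own OTF
   and weighted so their *total* transfers are identical. With identical
   transfers the correlation kernel is a positive envelope times
   e^{2πiΔ·ρ}; any one-sided weighting imprints an envelope phase tilt
   that biases the shift (measured: −0.1…−0.2% of |k|). The residual Δ is
   refined by Nelder–Mead to 10⁻⁴ px over two re-weighting rounds,
   starting from the design guess or a coarse matched-filter peak. Order
   1 sits at exactly half the order-2 shift; its correlation argument
   gives φ₀ and the magnitudes give the modulation depths (orders ±m
   share one depth). Overlap threshold 2% of each band's own peak,
   division regularization 10⁻³ — the order-0/order-2 overlap lives at
   both supports' edges when the side beams sit at 92% of the pupil.
4. **Generalized Wiener** — data bands are moved to their true positions
   on a 2× laterally upsampled grid by real-space ramps; the OTFs are
   evaluated analytically at the shifted coordinate (shifting a gridded
   |OTF|² by a fractional-bin ramp leaks its DC spike across the whole
   spectrum). w = 0.001 on DC-normalized OTFs, entering squared.
   Triangular apodization A = max(0, 1−ρ) with an ellipsoidal ρ reaching
   1 at the extended cutoffs (detection + 2|p| laterally; the OTF set's
   axial extent). Inverse FFT, then negative and imaginary parts are
   discarded. Modulation depths are global per volume, not per z-chunk.

## Mirror alignment

The focal plane is estimated from per-plane 2D Gaussian fits (center fixed
at the sub-pixel bead position; amplitude, widths and background free):
the mean of FWHM(x) and FWHM(y) forms a defocus curve, smoothed with a
3-plane moving average (per-plane width estimates jitter at low photon
counts, and the branch inversion keeps only running maxima), whose two
branches are resampled at 100 FWHM values over the configured interval
(300–500 nm by default); both branches share the same sampling interval so
symmetric pairs average exactly to the focus. The standing-wave peak is a
1D Gaussian fit to the disk-summed axial profile around the local maximum
nearest the focus, with a low-modulation warning when the detrended
oscillation amplitude falls below 2%. Feedback applies the stage and
mirror moves instantly (no settling model); noiseless convergence from a
40-nm offset takes two iterations, and the noisy single-shot estimate is
stable to ~2 nm s.d. at 500 peak photons.

## Isotropization

The pipeline crops x-windows of z-matched width (10-px overlap,
end-aligned final window), rotates each in the x–z plane in 30° steps
(bilinear, zero-padded, `scipy.ndimage.rotate`), applies the enhancement
operator, rotates back, center-crops, stitches by averaging overlaps and
fuses in the Fourier domain by keeping the complex coefficient of maximal
modulus (ties to the lowest angle index; phase is preserved), returning
the magnitude of the inverse transform. Bounding boxes use ceiling
rounding — (800, 800, 80) at 60° grows to z-extent 733, one 80-wide
window only to 110.

The reference `DirectionalWiener` operator makes the pipeline testable
without training: it inverts the known Gaussian degradation along the
rotated x axis, re-bandlimits to the target (lateral) resolution, and

- caps the 1-D boost at the exact inverse of the full 2-D blur in the
  rotated frame — a marginal-kernel 1-D filter over-amplifies off-axis
  frequencies, and max-modulus fusion keeps every inflated coefficient;
- uses noise-adaptive regularization: exact rotations (multiples of 90°)
  run at ε = 10⁻⁵, matched to noiseless single-precision data, while
  interpolated angles run at ε = 10⁻² because the bilinear MTF ripple
  acts as a few-percent model error under a deep boost;
- tapers the recovery edge with a raised cosine over the last decade of
  transfer, trading a little width for much less ringing.

A linear operator cannot restore frequencies the blur pushed below the
numerical noise floor — on the σ = (1.3, 1.3, 3.7) phantom the axial band
recovers to ≈0.2 cycles/voxel, giving fused axial/lateral FWHM ratios of
≈1.1–1.2 rather than exactly 1. Learned operators plug into the same
interface (`for_angle` optional; a subprocess hook in the CLI), and must
declare their training provenance.

Training-pair synthesis supports two settings: σ_x = 2.8 px /
σ_z = 1.0 px for 50-nm-interpolated reconstructions, σ_x = 3.6 px /
σ_z = 0.5 px for 40-nm simulation-scale volumes, with optional bilinear
x down/upsampling to mimic coarse axial sampling.

## Metrics

FWHM is measured at half of (max − baseline) with the baseline as the
median of the outer 20% tails, by Gaussian fit (default) or linear
half-maximum crossing. Bead reports aggregate per-bead lateral/axial FWHM
as mean ± s.d. with logged rejects. SSIM/PSNR run on min–max normalized
volumes with standard constants (7-voxel window, unit data range).
Spectral bandwidth is the largest frequency where the axis-averaged |FFT|
exceeds the noise floor by 1% of the peak.

## What the synthetic data does and does not show

The generator reproduces realistic acquisition conditions: the standard phantom
composition, bead sizes, z steps, five phases × three orientations, and
typical sCMOS noise. It does not model aberrations (index mismatch, coma),
vectorial high-NA polarization effects, photobleaching, sample motion, or
SLM/LCPR hardware imperfections. Passing tests therefore demonstrate that
the algorithms are correct and self-consistent under an ideal scalar
model — not that a physical instrument meets the same numbers. Absolute
resolution values here (e.g. ≈116 nm lateral / ≈162 nm axial four-beam
FWHM at 1.27 NA) come from this ideal model on desk-scale grids (64³–128³
voxels; 96³ phantoms with proportionally scaled structure counts), chosen
so the full suite runs on a laptop; the resolution *ratios* between
modalities are the robust quantities.
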
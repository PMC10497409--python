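"""Synthetic-data generation: phantoms, bead fields and raw SIM stacks.

The mixed-structure phantom (dots, lines, hollow spheres on a 300³ grid of
40-nm voxels) exercises the isotropization pipeline; bead fields exercise
OTF extraction, alignment and resolution metrics; and the forward simulator
produces complete 5-phase × 3-orientation raw acquisitions for both 3-beam
and four-beam illumination.

The forward model uses the sample-scanning convention: illumination pattern
and detection focal plane are fixed in the lab frame and the sample is
translated axially, which makes the acquisition an exact 3D convolution of
the object with the pattern-modulated detection PSF.  Per lateral order m
the effective kernel is H_m(ρ, ζ) = J_m(−ζ)·h_det(ρ, ζ), with J_m the
complex axial modulation of that order, so the recorded phase-p volume is

    D_p = Re Σ_m exp(i·m·(φ₀ + 2πp/5)) · [S·e^{2πi·m·p_d·ρ}] ⊛ H_m .
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft as fft
from pydantic import BaseModel, model_validator
from scipy import ndimage

from .illumination import N_PHASES, axial_order_profile
from .optics import BeamSet, OpticalModel, make_beams
from .otf import detection_psf, sphere_transform

DEFAULT_ORIENTATION_ANGLES = (10.3, 70.3, 130.2)


# ---------------------------------------------------------------------------
# Mixed-structure phantom


class PhantomConfig(BaseModel):
    """Parameters of the mixed dot/line/hollow-sphere phantom."""

    grid_shape: tuple[int, int, int] = (300, 300, 300)  # (z, y, x) voxels
    voxel_nm: float = 40.0
    n_dots: int = 3000
    dot_intensity: tuple[float, float] = (2000.0, 7000.0)
    n_lines: int = 1800
    line_polar_deg: tuple[float, float] = (1.0, 360.0)  # vs axial axis
    line_azimuth_deg: tuple[float, float] = (1.0, 360.0)  # in lateral plane
    line_length_px: tuple[float, float] = (1.0, 72.0)
    line_intensity: tuple[float, float] = (100.0, 500.0)
    n_spheres: int = 600
    sphere_inner_diameter_px: tuple[float, float] = (2.0, 20.0)
    sphere_thickness_px: tuple[float, float] = (1.0, 2.0)
    sphere_intensity: tuple[float, float] = (10.0, 200.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        if min(self.n_dots, self.n_lines, self.n_spheres) < 0:
            raise ValueError("structure counts must be nonnegative")
        for name in (
            "dot_intensity",
            "line_polar_deg",
            "line_azimuth_deg",
            "line_length_px",
            "line_intensity",
            "sphere_inner_diameter_px",
            "sphere_thickness_px",
            "sphere_intensity",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"range {name} is empty")
        return self

    def scaled(self, shape: tuple[int, int, int]) -> "PhantomConfig":
        """Config for a smaller grid with proportionally scaled counts."""
        ratio = np.prod(shape) / np.prod(self.grid_shape)
        return self.model_copy(
            update=dict(
                grid_shape=shape,
                n_dots=max(1, int(round(self.n_dots * ratio))),
                n_lines=max(1, int(round(self.n_lines * ratio))),
                n_spheres=max(1, int(round(self.n_spheres * ratio))),
            )
        )


@dataclass
class Phantom:
    """A ground-truth volume plus the record of every placed structure."""

    volume: np.ndarray  # (z, y, x) float32
    voxel_nm: float
    structures: list = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(1 for s in self.structures if s["kind"] == kind)


class PlacementError(RuntimeError):
    """A structure could not be placed inside the grid."""


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi))


def make_mixed_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Generate the mixed dot/line/hollow-sphere phantom.

    Exactly ``n_dots`` single-voxel dots, ``n_lines`` unit-width lines with
    random 3D orientation and ``n_spheres`` hollow shells are placed
    uniformly at random; attribute draws use the configured ranges.  Output
    is bit-reproducible for a fixed seed.  A structure that cannot be
    placed inside the grid after 100 attempts raises
    :class:`PlacementError`.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.grid_shape
    vol = np.zeros(config.grid_shape, dtype=np.float32)
    structures: list[dict] = []

    for _ in range(config.n_dots):
        z, y, x = (int(rng.integers(0, n)) for n in (nz, ny, nx))
        inten = _uniform(rng, config.dot_intensity)
        vol[z, y, x] += inten
        structures.append({"kind": "dot", "pos": (z, y, x), "intensity": inten})

    for _ in range(config.n_lines):
        placed = False
        for _attempt in range(100):
            length = _uniform(rng, config.line_length_px)
            polar = math.radians(_uniform(rng, config.line_polar_deg))
            azim = math.radians(_uniform(rng, config.line_azimuth_deg))
            inten = _uniform(rng, config.line_intensity)
            dz = math.cos(polar)
            dy = math.sin(polar) * math.sin(azim)
            dx = math.sin(polar) * math.cos(azim)
            z0 = rng.uniform(0, nz - 1)
            y0 = rng.uniform(0, ny - 1)
            x0 = rng.uniform(0, nx - 1)
            z1, y1, x1 = z0 + dz * length, y0 + dy * length, x0 + dx * length
            if not (0 <= z1 <= nz - 1 and 0 <= y1 <= ny - 1 and 0 <= x1 <= nx - 1):
                continue
            n_steps = max(int(math.ceil(length * 2)), 1)
            t = np.linspace(0.0, 1.0, n_steps + 1)
            zi = np.round(z0 + (z1 - z0) * t).astype(int)
            yi = np.round(y0 + (y1 - y0) * t).astype(int)
            xi = np.round(x0 + (x1 - x0) * t).astype(int)
            voxels = np.unique(np.stack([zi, yi, xi], axis=1), axis=0)
            vol[voxels[:, 0], voxels[:, 1], voxels[:, 2]] += inten
            structures.append(
                {
                    "kind": "line",
                    "start": (z0, y0, x0),
                    "direction": (dz, dy, dx),
                    "length": length,
                    "intensity": inten,
                }
            )
            placed = True
            break
        if not placed:
            raise PlacementError("line placement failed after 100 attempts")

    for _ in range(config.n_spheres):
        placed = False
        for _attempt in range(100):
            d_in = _uniform(rng, config.sphere_inner_diameter_px)
            thick = _uniform(rng, config.sphere_thickness_px)
            inten = _uniform(rng, config.sphere_intensity)
            r_out = d_in / 2.0 + thick
            if 2 * r_out >= min(nz, ny, nx):
                continue
            cz = rng.uniform(r_out, nz - 1 - r_out)
            cy = rng.uniform(r_out, ny - 1 - r_out)
            cx = rng.uniform(r_out, nx - 1 - r_out)
            lo = np.floor([cz - r_out, cy - r_out, cx - r_out]).astype(int)
            hi = np.ceil([cz + r_out, cy + r_out, cx + r_out]).astype(int) + 1
            zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            dist = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
            shell = (dist >= d_in / 2.0) & (dist < r_out)
            sub = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            sub[shell] += inten
            structures.append(
                {
                    "kind": "sphere",
                    "center": (cz, cy, cx),
                    "inner_diameter": d_in,
                    "thickness": thick,
                    "intensity": inten,
                }
            )
            placed = True
            break
        if not placed:
            raise PlacementError("sphere placement failed after 100 attempts")

    return Phantom(volume=vol, voxel_nm=config.voxel_nm, structures=structures)


def blur_gaussian(volume: np.ndarray, sigmas: Sequence[float]) -> np.ndarray:
    """Separable Gaussian blur with per-axis sigmas in voxels.

    Periodic boundaries conserve total intensity exactly and match the
    FFT-based (circular) deconvolution downstream consumers apply.  ``sigmas`` follows the array axis order (z, y, x).  The kernel
    is truncated at 6σ (not scipy's default 4σ) so its spectral tails stay
    below single precision — deconvolution-based consumers would otherwise
    amplify the truncation error.
    """
    sigmas = tuple(float(s) for s in sigmas)
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be nonnegative")
    return ndimage.gaussian_filter(volume, sigma=sigmas, mode="wrap", truncate=6.0)


# ---------------------------------------------------------------------------
# Acquisition


class AcquisitionConfig(BaseModel):
    """Noise and sampling parameters of a simulated acquisition.

    Defaults model a typical sCMOS camera: ~500 peak photons, 1.4-count
    read noise, 100-count offset.  z-steps default to the Nyquist choices
    of the two modalities (125 nm for 3-beam, 60 nm for four-beam).
    """

    modality: str = "3-beam"  # "3-beam" | "4-beam"
    z_step_nm: float | None = None
    pixel_size_nm: float = 80.0
    phases: int = N_PHASES
    orientation_angles: tuple[float, ...] = DEFAULT_ORIENTATION_ANGLES
    photon_scale: float = 500.0
    normalize: bool = True  # scale so the brightest pixel carries photon_scale
    camera_offset: float = 100.0
    read_noise_sigma: float = 1.4
    background: float = 0.0
    noise: bool = True
    psf_kind: str = "pupil"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionConfig":
        if self.modality not in ("3-beam", "4-beam"):
            raise ValueError("modality must be '3-beam' or '4-beam'")
        if self.phases != N_PHASES:
            raise ValueError("phases must be 5")
        if self.z_step_nm is None:
            object.__setattr__(
                self, "z_step_nm", 125.0 if self.modality == "3-beam" else 60.0
            )
        return self


@dataclass
class RawSIMStack:
    """A raw SIM acquisition: (orientation, phase, z, y, x) array + metadata."""

    data: np.ndarray
    pixel_size_nm: float
    z_step_nm: float
    modality: str
    camera_offset: float = 0.0
    orientation_angles: tuple[float, ...] = DEFAULT_ORIENTATION_ANGLES
    initial_phases: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("data must be 5D (orientation, phase, z, y, x)")
        if self.data.shape[1] != N_PHASES:
            raise ValueError("exactly 5 phases are required")
        if self.data.shape[0] not in (1, 3):
            raise ValueError("1 or 3 orientations are required")

    @property
    def n_orientations(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]


def _effective_kernels(
    model: OpticalModel,
    beams: BeamSet,
    shape: tuple[int, int, int],
    pixel_size_nm: float,
    z_step_nm: float,
    psf_kind: str,
    pattern_focus_offset_nm: float = 0.0,
) -> dict[int, np.ndarray]:
    """Fourier transforms of the per-order kernels H_m(ρ, ζ) = J_m(−ζ−Δ)·h.

    ``pattern_focus_offset_nm`` is an axial displacement Δ of the whole
    illumination pattern relative to the detection focal plane (on top of
    whatever the mirror phase encodes).
    """
    nz = shape[0]
    h = detection_psf(model, shape, pixel_size_nm, z_step_nm, kind=psf_kind)
    zeta_um = (np.arange(nz) - nz // 2) * z_step_nm * 1e-3
    delta_um = pattern_focus_offset_nm * 1e-3
    out = {}
    for m in (-2, -1, 0, 1, 2):
        jm = axial_order_profile(beams, m, -(zeta_um + delta_um))
        km = (h * jm[:, None, None]).astype(np.complex64)
        out[m] = fft.fftn(fft.ifftshift(km), workers=-1)
    return out


def simulate_acquisition(
    phantom_volume: np.ndarray,
    model: OpticalModel,
    acq: AcquisitionConfig,
    *,
    mirror_phase: float = 0.0,
    initial_phases: Sequence[float] = (0.0, 0.0, 0.0),
    pattern_contrast: float = 1.0,
    pattern_focus_offset_nm: float = 0.0,
) -> RawSIMStack:
    """Simulate a full raw SIM acquisition of a ground-truth volume.

    The phantom volume must share the acquisition grid (``pixel_size_nm``
    laterally, ``z_step_nm`` axially).  ``pattern_contrast`` scales the
    side-beam amplitudes (1 = ideal s-polarization, 0 = uniform
    illumination).  Returns data in (orientation, phase, z, y, x) order; on
    disk this becomes the XYPAZ page order.
    """
    vol = np.asarray(phantom_volume, dtype=np.float32)
    shape = vol.shape
    rng = np.random.default_rng(acq.seed)
    four = acq.modality == "4-beam"
    ny, nx = shape[1], shape[2]
    x_um = np.arange(nx) * acq.pixel_size_nm * 1e-3
    y_um = np.arange(ny) * acq.pixel_size_nm * 1e-3

    out = np.empty((len(acq.orientation_angles), N_PHASES) + shape, dtype=np.float32)
    for d, ang in enumerate(acq.orientation_angles):
        side = pattern_contrast
        beams = make_beams(
            model,
            ang,
            four_beam=four,
            mirror_phase=mirror_phase,
            amplitudes=(side, 1.0, side),
        )
        kernels = _effective_kernels(
            model,
            beams,
            shape,
            acq.pixel_size_nm,
            acq.z_step_nm,
            acq.psf_kind,
            pattern_focus_offset_nm,
        )
        ks = model.pattern_lateral_frequency
        th = math.radians(ang)
        proj = (
            ks * math.cos(th) * x_um[None, :] + ks * math.sin(th) * y_um[:, None]
        )
        phi0 = initial_phases[d]
        spec_m = {}
        for m in (-2, -1, 0, 1, 2):
            carrier = np.exp(2j * math.pi * m * proj).astype(np.complex64)
            spec_m[m] = fft.fftn(vol * carrier[None, :, :], workers=-1)
        for p in range(N_PHASES):
            phi = phi0 + 2.0 * math.pi * p / N_PHASES
            acc = np.zeros(shape, dtype=np.complex64)
            for m in (-2, -1, 0, 1, 2):
                acc += np.exp(1j * m * phi) * spec_m[m] * kernels[m]
            out[d, p] = fft.ifftn(acc, workers=-1).real

    peak = float(out.max())
    if acq.normalize and peak > 0:
        out *= acq.photon_scale / peak
    elif not acq.normalize:
        out *= acq.photon_scale
    out += acq.background
    if acq.noise:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float32)
        out += rng.normal(0.0, acq.read_noise_sigma, out.shape).astype(np.float32)
    out += acq.camera_offset
    return RawSIMStack(
        data=out,
        pixel_size_nm=acq.pixel_size_nm,
        z_step_nm=acq.z_step_nm,
        modality=acq.modality,
        camera_offset=acq.camera_offset,
        orientation_angles=tuple(acq.orientation_angles),
        initial_phases=tuple(initial_phases),
    )


def simulate_widefield(
    phantom_volume: np.ndarray,
    model: OpticalModel,
    pixel_size_nm: float,
    z_step_nm: float,
    psf_kind: str = "pupil",
) -> np.ndarray:
    """Noise-free wide-field image: 3D convolution with the detection PSF."""
    vol = np.asarray(phantom_volume, dtype=np.float32)
    h = detection_psf(model, vol.shape, pixel_size_nm, z_step_nm, kind=psf_kind)
    spec = fft.fftn(vol, workers=-1) * fft.fftn(
        fft.ifftshift(h.astype(np.float32)), workers=-1
    )
    return fft.ifftn(spec, workers=-1).real.astype(np.float32)


def bead_volume(
    shape: tuple[int, int, int],
    positions_px: Sequence[tuple[float, float, float]],
    bead_diameter_nm: float,
    pixel_size_nm: float,
    z_step_nm: float,
    intensity: float = 1.0,
) -> np.ndarray:
    """Band-limited rendering of solid spheres at sub-voxel positions.

    Built in the Fourier domain from the analytic sphere transform so that
    OTF extraction can compensate the bead size exactly.  ``positions_px``
    are (z, y, x) in voxel units.
    """
    nz, ny, nx = shape
    kz = fft.fftfreq(nz, d=z_step_nm)
    ky = fft.fftfreq(ny, d=pixel_size_nm)
    kx = fft.fftfreq(nx, d=pixel_size_nm)
    KZ, KY, KX = np.meshgrid(kz, ky, kx, indexing="ij")
    kmag = np.sqrt(KZ**2 + KY**2 + KX**2)  # cycles/nm
    env = sphere_transform(bead_diameter_nm, kmag)
    spec = np.zeros(shape, dtype=np.complex128)
    for (pz, py, px) in positions_px:
        spec += np.exp(-2j * math.pi * (KZ * pz * z_step_nm + KY * py * pixel_size_nm + KX * px * pixel_size_nm))
    return (intensity * fft.ifftn(spec * env).real).astype(np.float32)


def simulate_bead_stack(
    positions_px: Sequence[tuple[float, float, float]],
    model: OpticalModel,
    acq: AcquisitionConfig,
    *,
    shape: tuple[int, int, int] = (100, 64, 64),
    bead_diameter_nm: float = 100.0,
    mirror_phase: float = 0.0,
    orientation_deg: float = 0.0,
    pattern_focus_offset_nm: float = 0.0,
) -> np.ndarray:
    """Raw 5-phase stack of a bead field for one orientation.

    Supports the two layouts the instrument uses: a single centered bead
    for OTF measurement and a sparse field for mirror alignment (then
    typically with ``acq.z_step_nm`` = 20 nm over a 2-µm range).  The
    mirror phase (or an explicit pattern-focus offset) displaces the axial
    interference pattern from the focal plane by a known amount.
    """
    vol = bead_volume(
        shape, positions_px, bead_diameter_nm, acq.pixel_size_nm, acq.z_step_nm
    )
    stack = simulate_acquisition(
        vol,
        model,
        acq.model_copy(update={"orientation_angles": (orientation_deg,)}),
        mirror_phase=mirror_phase,
        initial_phases=(0.0,),
        pattern_focus_offset_nm=pattern_focus_offset_nm,
    )
    return stack.data[0]


def mirror_phase_for_offset(model: OpticalModel, offset_nm: float) -> float:
    """Mirror phase θ_m that displaces the axial pattern peak by ``offset_nm``.

    The standing wave has axial frequency 2n/λ_ex; a mirror phase θ_m moves
    its maxima by θ_m·λ_ex/(4π·n), i.e. θ_m = 4π·n·Δz/λ_ex.
    """
    return (
        4.0
        * math.pi
        * model.refractive_index
        * offset_nm
        / model.excitation_wavelength
    )


class MirrorAlignmentSimulator:
    """Closed-loop stand-in for the four-beam mirror-alignment hardware.

    Holds two hidden state variables: the stage error (bead displacement
    from the stack center, nm) and the pattern error (axial displacement of
    the illumination-pattern maxima from the detection focal plane, nm).
    ``acquire`` renders a 5-phase four-beam bead stack under the current
    state; ``move_stage`` / ``move_mirror`` emulate the piezo actuators
    (moves applied instantly; settling is not modelled).
    """

    def __init__(
        self,
        model: OpticalModel,
        stage_error_nm: float = 0.0,
        pattern_error_nm: float = 0.0,
        *,
        shape: tuple[int, int, int] = (100, 48, 48),
        z_step_nm: float = 20.0,
        pixel_size_nm: float = 80.0,
        photon_scale: float = 500.0,
        noise: bool = False,
        psf_kind: str = "pupil",
        seed: int = 0,
    ) -> None:
        self.model = model
        self.stage_error_nm = float(stage_error_nm)
        self.pattern_error_nm = float(pattern_error_nm)
        self.shape = shape
        self.z_step_nm = z_step_nm
        self.pixel_size_nm = pixel_size_nm
        self.photon_scale = photon_scale
        self.noise = noise
        self.psf_kind = psf_kind
        self._seed = seed
        self._n_acquired = 0

    def move_stage(self, delta_nm: float) -> None:
        self.stage_error_nm += delta_nm

    def move_mirror(self, delta_nm: float) -> None:
        self.pattern_error_nm += delta_nm

    def acquire(self) -> np.ndarray:
        """5-phase four-beam stack of the fiducial bead, (5, Z, Y, X)."""
        nz, ny, nx = self.shape
        self._n_acquired += 1
        acq = AcquisitionConfig(
            modality="4-beam",
            z_step_nm=self.z_step_nm,
            pixel_size_nm=self.pixel_size_nm,
            photon_scale=self.photon_scale,
            camera_offset=0.0,
            noise=self.noise,
            psf_kind=self.psf_kind,
            seed=self._seed + self._n_acquired,
        )
        pos = (
            nz // 2 + self.stage_error_nm / self.z_step_nm,
            ny / 2.0,
            nx / 2.0,
        )
        return simulate_bead_stack(
            [pos],
            self.model,
            acq,
            shape=self.shape,
            pattern_focus_offset_nm=self.pattern_error_nm,
        )

    def acquire_widefield(self) -> np.ndarray:
        """Phase-summed (wide-field-equivalent) image stack, (Z, Y, X)."""
        return self.acquire().sum(axis=0)
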
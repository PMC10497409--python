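"""Optical transfer functions: support geometry, modelling and extraction.

The wide-field 3D OTF support is a toroid whose meridional (k_r, k_z)
cross-section is enclosed by four circular arcs of radius n/λ_em centered at
(±NA/λ_em, ±n·cosα/λ_em); its lateral and axial extents are 2NA/λ_em and
(1−cosα)·n/λ_em.  Structured illumination extends the support by convolving
it with the illumination frequency components: seven for 3D SIM, plus the
±2n/λ_ex standing-wave pair and four reflected-side-beam cross terms for
four-beam SIM, and the 19-component two-objective geometry for I⁵S.

Per-order OTFs are stored radially averaged on a (k_z, k_r) grid, normalized
so the order-0 DC equals 1, and revolved back to 3D by bilinear
interpolation when reconstructing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as fft
from scipy.interpolate import RegularGridInterpolator

from .optics import BeamSet, OpticalModel, make_beams
from .illumination import N_PHASES, order_components

MODALITIES = ("widefield", "sim3d", "standing_wave", "four_beam", "i5s")


# ---------------------------------------------------------------------------
# Support geometry


def _widefield_cross_section(
    kr: np.ndarray, kz: np.ndarray, model: OpticalModel, tol: float = 0.0
) -> np.ndarray:
    """Membership test for the wide-field toroid cross-section.

    A point is inside iff it lies within n/λ_em of both arc centers
    (NA/λ_em, ±n·cosα/λ_em); ``kr`` may be signed (|kr| is used).  ``tol``
    fattens the boundary (set it to half the grid spacing when rasterizing
    so boundary-touching regions like the DC point survive).
    """
    lam = model.emission_wavelength * 1e-3  # µm
    r_arc = model.refractive_index / lam
    c_lat = model.numerical_aperture / lam
    c_ax = model.refractive_index * math.cos(model.half_angle) / lam
    kr = np.abs(kr)
    kz = np.abs(kz)
    d_hi = np.hypot(kr - c_lat, kz + c_ax)
    d_lo = np.hypot(kr - c_lat, kz - c_ax)
    return (d_hi <= r_arc + tol + 1e-12) & (d_lo <= r_arc + tol + 1e-12)


def _i2m_detection_cross_section(
    kr: np.ndarray, kz: np.ndarray, model: OpticalModel, n_samples: int = 240
) -> np.ndarray:
    """Membership mask for coherent two-objective (I²M) detection support.

    Emission is collected through two opposed caps; the support is the
    difference set of (cap ∪ −cap).  The cap−cap part is the wide-field
    toroid; the cap+cap part is rasterized numerically: for polar angles
    (φ1, φ2) the reachable radii form the interval [|r1−r2|, r1+r2] at
    axial frequency ±(cosφ1+cosφ2)·n/λ_em.
    """
    lam = model.emission_wavelength * 1e-3
    k0 = model.refractive_index / lam
    alpha = model.half_angle
    # Axes are recovered from the meshgrid rows/columns.
    kr_ax = np.asarray(kr, float)[0]
    kz_ax = np.asarray(kz, float)[:, 0]
    dkr = kr_ax[1] - kr_ax[0]
    dkz = kz_ax[1] - kz_ax[0]
    mask = _widefield_cross_section(kr, kz, model, 0.5 * dkr)
    phi = np.linspace(0.0, alpha, n_samples)
    r = k0 * np.sin(phi)
    c = k0 * np.cos(phi)
    sum_mask = np.zeros(mask.shape, bool)
    # Rasterize the (φ1, φ2) sum set by painting one radial interval per
    # pair; azimuthal freedom makes every radius in [|r1−r2|, r1+r2]
    # reachable at axial frequency ±(cosφ1+cosφ2)·n/λ.
    for i in range(n_samples):
        kz_sum = c[i] + c
        rmin = np.abs(r[i] - r)
        rmax = r[i] + r
        ir0 = np.floor(rmin / dkr).astype(int)
        ir1 = np.minimum(np.ceil(rmax / dkr).astype(int) + 1, kr_ax.size)
        for sign in (1.0, -1.0):
            iz = np.round((sign * kz_sum - kz_ax[0]) / dkz).astype(int)
            ok = (iz >= 0) & (iz < kz_ax.size)
            for j in np.nonzero(ok)[0]:
                sum_mask[iz[j], ir0[j] : ir1[j]] = True
    return mask | sum_mask


@dataclass
class OTFSupport:
    """Boolean OTF support mask on a (k_z, k_r) grid (k_r ≥ 0)."""

    modality: str
    mask: np.ndarray  # (n_kz, n_kr) bool
    kr: np.ndarray  # cycles/µm, ≥ 0
    kz: np.ndarray  # cycles/µm, symmetric about 0

    @property
    def lateral_extent(self) -> float:
        cols = np.any(self.mask, axis=0)
        return float(self.kr[cols].max()) if cols.any() else 0.0

    @property
    def axial_extent(self) -> float:
        rows = np.any(self.mask, axis=1)
        return float(np.abs(self.kz[rows]).max()) if rows.any() else 0.0

    def contains(self, other: "OTFSupport") -> bool:
        """True if this support is a superset of ``other`` (same grid)."""
        return bool(np.all(self.mask | ~other.mask))


def _illumination_shifts(beams: BeamSet) -> list[tuple[float, float]]:
    """(signed lateral, axial) frequencies of all illumination components."""
    ks = max(math.hypot(b.k[0], b.k[1]) for b in beams.components)
    return [(c.m * ks, c.kz) for c in order_components(beams)]


def _i5s_illumination_shifts(model: OpticalModel) -> list[tuple[float, float]]:
    """The 19 illumination components of the six-beam I⁵S geometry."""
    base = make_beams(model, 0.0)
    comps = list(base.components)
    mirrored = [
        type(b)(amplitude=b.amplitude, k=(b.k[0], b.k[1], -b.k[2]))
        for b in comps
    ]
    ks = max(math.hypot(b.k[0], b.k[1]) for b in comps)
    seen = {}
    for bj in comps + mirrored:
        for bl in comps + mirrored:
            m = int(round((bj.k[0] - bl.k[0]) / ks))
            kz = bj.k[2] - bl.k[2]
            seen[(m, round(kz, 9))] = (m * ks, kz)
    return list(seen.values())


def support(
    modality: str,
    model: OpticalModel,
    dk: float = 0.05,
    margin: float = 1.05,
) -> OTFSupport:
    """Construct the OTF support mask for one imaging geometry.

    ``dk`` is the grid spacing in cycles/µm.  The grid is sized to hold the
    largest (I⁵S) support so that masks of different modalities share axes
    and can be compared set-wise.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    lam_ex = model.excitation_wavelength * 1e-3
    n = model.refractive_index
    kr_max = margin * (2 * model.numerical_aperture / (model.emission_wavelength * 1e-3)
                       + 2 * model.pattern_lateral_frequency)
    kz_max = margin * (2 * n / lam_ex + model.detection_axial_cutoff
                       + 2 * n / (model.emission_wavelength * 1e-3) * 0.1)
    kr = np.arange(0.0, kr_max + dk, dk)
    nz = int(math.ceil(kz_max / dk))
    kz = np.arange(-nz, nz + 1) * dk
    KR, KZ = np.meshgrid(kr, kz)

    tol = 0.5 * dk
    if modality == "widefield":
        mask = _widefield_cross_section(KR, KZ, model, tol)
    elif modality == "standing_wave":
        sw = 2 * n / lam_ex
        mask = (
            _widefield_cross_section(KR, KZ, model, tol)
            | _widefield_cross_section(KR, KZ - sw, model, tol)
            | _widefield_cross_section(KR, KZ + sw, model, tol)
        )
    elif modality in ("sim3d", "four_beam"):
        beams = make_beams(model, 0.0, four_beam=(modality == "four_beam"))
        mask = np.zeros(KR.shape, bool)
        for s_lat, s_ax in _illumination_shifts(beams):
            mask |= _widefield_cross_section(KR - s_lat, KZ - s_ax, model, tol)
    else:  # i5s
        det = _i2m_detection_cross_section(KR, KZ, model)
        mask = np.zeros(KR.shape, bool)
        # Build a shiftable membership function by interpolation on the grid.
        for s_lat, s_ax in _i5s_illumination_shifts(model):
            mask |= _shift_mask(det, kr, kz, s_lat, s_ax)
    return OTFSupport(modality=modality, mask=mask, kr=kr, kz=kz)


def _shift_mask(
    mask: np.ndarray, kr: np.ndarray, kz: np.ndarray, s_lat: float, s_ax: float
) -> np.ndarray:
    """Shift a (k_z, k_r) mask by (s_lat, s_ax), folding signed k_r to ≥ 0."""
    KR, KZ = np.meshgrid(kr, kz)
    qr = np.abs(KR - s_lat)
    qz = KZ - s_ax
    ir = np.clip(np.round(qr / (kr[1] - kr[0])).astype(int), 0, kr.size - 1)
    iz = np.round((qz - kz[0]) / (kz[1] - kz[0])).astype(int)
    ok = (iz >= 0) & (iz < kz.size) & (qr <= kr[-1])
    out = np.zeros_like(mask)
    out[ok] = mask[iz[ok], ir[ok]]
    return out


# ---------------------------------------------------------------------------
# Analytic pieces


def sphere_transform(diameter_nm: float, k_cycles_per_nm: np.ndarray) -> np.ndarray:
    """Normalized 3D Fourier transform of a uniform solid sphere.

    F(k) = 3·[sin(u) − u·cos(u)]/u³ with u = π·d·k; F(0) = 1.  Used to
    compensate the finite size of the fluorescent bead in OTF extraction.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    u = math.pi * diameter_nm * np.asarray(k_cycles_per_nm, dtype=float)
    out = np.ones_like(u)
    nz = np.abs(u) > 1e-8
    un = u[nz]
    out[nz] = 3.0 * (np.sin(un) - un * np.cos(un)) / un**3
    return out


def parabolic_vertex_3pt(y: np.ndarray) -> float:
    """Sub-sample vertex offset from three samples at x = −1, 0, 1.

    x₀ = (y₋₁ − y₊₁) / (2·(y₋₁ − 2·y₀ + y₊₁)); exact for a quadratic.
    """
    ym, y0, yp = (float(v) for v in y)
    denom = 2.0 * (ym - 2.0 * y0 + yp)
    if denom == 0.0:
        return 0.0
    return (ym - yp) / denom


def parabolic_vertex_5pt(y: np.ndarray) -> float:
    """Least-squares quadratic vertex from five samples at x = −2..2."""
    x = np.arange(-2.0, 3.0)
    coef = np.polyfit(x, np.asarray(y, float), 2)
    if coef[0] == 0.0:
        return 0.0
    return float(-coef[1] / (2.0 * coef[0]))


# ---------------------------------------------------------------------------
# OTF sets


@dataclass
class OTFSet:
    """Per-order radially averaged OTFs on a shared (k_z, k_r) grid."""

    orders: dict  # {0: (n_kz, n_kr) complex, 1: ..., 2: ...}
    kr: np.ndarray
    kz: np.ndarray
    modality: str
    excitation_wavelength: float
    emission_wavelength: float
    normalized: bool = True

    def to_3d(
        self,
        order: int,
        shape: tuple[int, int, int],
        pixel_size_nm: float,
        z_step_nm: float,
    ) -> np.ndarray:
        """Revolve the 2D OTF of one order onto a 3D fftshifted grid."""
        nzv, nyv, nxv = shape
        kx = fft.fftshift(fft.fftfreq(nxv, d=pixel_size_nm * 1e-3))
        ky = fft.fftshift(fft.fftfreq(nyv, d=pixel_size_nm * 1e-3))
        kzv = fft.fftshift(fft.fftfreq(nzv, d=z_step_nm * 1e-3))
        return revolve_2d_to_3d(self.orders[order], self.kr, self.kz, kx, ky, kzv)


def revolve_2d_to_3d(
    radial: np.ndarray,
    kr: np.ndarray,
    kz: np.ndarray,
    kx: np.ndarray,
    ky: np.ndarray,
    kz_out: np.ndarray,
) -> np.ndarray:
    """Revolve a (k_z, k_r) array about the k_z axis onto a 3D grid.

    Each voxel (k_x, k_y, k_z) takes the bilinear interpolation of the 2D
    array at (√(k_x²+k_y²), k_z); radii or k_z beyond the 2D grid zero-fill.
    """
    interp = RegularGridInterpolator(
        (kz, kr), radial, method="linear", bounds_error=False, fill_value=0.0
    )
    KZ, KY, KX = np.meshgrid(kz_out, ky, kx, indexing="ij")
    pts = np.stack([KZ.ravel(), np.hypot(KX, KY).ravel()], axis=-1)
    out = interp(pts)
    return out.reshape(KZ.shape)


def radial_average(
    vol: np.ndarray, kx: np.ndarray, ky: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally average a (k_z, k_y, k_x) array about the k_z axis.

    Bins at the lateral grid spacing; each sample accumulates into its
    nearest (k_r, k_z) bin with a count-weighted mean.  Returns
    ``(averaged (n_kz, n_kr) array, kr axis)``.
    """
    dk = float(kx[1] - kx[0])
    KX, KY = np.meshgrid(kx, ky)
    rbin = np.round(np.hypot(KX, KY) / dk).astype(np.int64).ravel()
    nbin = int(rbin.max()) + 1
    counts = np.bincount(rbin, minlength=nbin).astype(float)
    nz = vol.shape[0]
    out = np.empty((nz, nbin), dtype=vol.dtype)
    flat = vol.reshape(nz, -1)
    for iz in range(nz):
        if np.iscomplexobj(vol):
            sums = np.bincount(rbin, weights=flat[iz].real, minlength=nbin) + 1j * np.bincount(
                rbin, weights=flat[iz].imag, minlength=nbin
            )
        else:
            sums = np.bincount(rbin, weights=flat[iz], minlength=nbin)
        out[iz] = sums / counts
    return out, np.arange(nbin) * dk


def order_support_mask(
    beams: BeamSet,
    model: OpticalModel,
    order: int,
    kr: np.ndarray,
    kz: np.ndarray,
) -> np.ndarray:
    """Support of the order-m OTF on a (k_z, k_r) grid.

    In band coordinates the lateral illumination shift is removed, so the
    order-m OTF is a union of wide-field toroids offset axially by the k_z
    of each illumination component in that order (two overlapping copies
    for 3D SIM order 1; three for four-beam order 0, four for order 1).
    """
    KR, KZ = np.meshgrid(kr, kz)
    tol = 0.5 * float(kr[1] - kr[0])
    mask = np.zeros(KR.shape, bool)
    for c in order_components(beams):
        if abs(c.m) == order:
            mask |= _widefield_cross_section(KR, KZ - c.kz, model, tol)
    return mask


# ---------------------------------------------------------------------------
# Detection PSF and model OTFs


def detection_psf(
    model: OpticalModel,
    shape: tuple[int, int, int],
    pixel_size_nm: float,
    z_step_nm: float,
    kind: str = "pupil",
) -> np.ndarray:
    """Detection PSF on a (z, y, x) grid, centered, normalized to unit sum.

    ``kind='pupil'`` evaluates the scalar diffraction integral over the
    pupil (a defocus phase per plane); ``kind='gaussian'`` is a fast
    Gaussian approximation with FWHMs 0.51·λ/NA laterally and
    0.88·λ/(n−√(n²−NA²)) axially, adequate for quick tests.
    """
    nzv, nyv, nxv = shape
    lam = model.emission_wavelength  # nm
    if kind == "gaussian":
        fl = 0.51 * lam / model.numerical_aperture
        na, n = model.numerical_aperture, model.refractive_index
        fa = 0.88 * lam / (n - math.sqrt(n * n - na * na))
        s = 2.0 * math.sqrt(2.0 * math.log(2.0))
        z = (np.arange(nzv) - nzv // 2) * z_step_nm
        y = (np.arange(nyv) - nyv // 2) * pixel_size_nm
        x = (np.arange(nxv) - nxv // 2) * pixel_size_nm
        h = np.exp(
            -0.5
            * (
                (z[:, None, None] / (fa / s)) ** 2
                + (y[None, :, None] / (fl / s)) ** 2
                + (x[None, None, :] / (fl / s)) ** 2
            )
        )
    elif kind == "pupil":
        lam_um = lam * 1e-3
        kx = fft.fftfreq(nxv, d=pixel_size_nm * 1e-3)
        ky = fft.fftfreq(nyv, d=pixel_size_nm * 1e-3)
        KX, KY = np.meshgrid(kx, ky)
        kr2 = KX**2 + KY**2
        k0 = model.refractive_index / lam_um
        pupil = kr2 <= (model.numerical_aperture / lam_um) ** 2
        kz_def = np.sqrt(np.maximum(k0**2 - kr2, 0.0))
        z = (np.arange(nzv) - nzv // 2) * z_step_nm * 1e-3  # µm
        h = np.empty((nzv, nyv, nxv), dtype=np.float64)
        for iz, zv in enumerate(z):
            amp = fft.ifft2(pupil * np.exp(2j * math.pi * zv * kz_def))
            h[iz] = np.abs(fft.fftshift(amp)) ** 2
        # Taper the PSF laterally to zero well inside the grid: at high NA
        # the defocused cone outruns any finite field, and on a periodic
        # grid that light would wrap around, breaking the rotational
        # symmetry the radially averaged OTF relies on.  The taper models
        # the finite detection field and keeps the kernel compact.
        yy, xx = np.mgrid[0:nyv, 0:nxv]
        r = np.hypot(yy - nyv // 2, xx - nxv // 2)
        r_max = 0.5 * min(nyv, nxv)
        r0, r1 = 0.6 * r_max, 0.92 * r_max
        taper = np.clip((r1 - r) / (r1 - r0), 0.0, 1.0)
        taper = np.sin(0.5 * math.pi * taper) ** 2
        h *= taper[None]
    else:
        raise ValueError(f"unknown PSF kind {kind!r}")
    return h / h.sum()


def model_otfs(
    model: OpticalModel,
    beams: BeamSet,
    shape: tuple[int, int, int] = (128, 128, 128),
    pixel_size_nm: float = 40.0,
    z_step_nm: float = 40.0,
    psf_kind: str = "pupil",
) -> OTFSet:
    """Per-order OTFs computed from the optical model (no bead data).

    The order-m effective kernel is H_m(ρ, ζ) = J_m(−ζ)·h_det(ρ, ζ) with
    J_m the axial modulation of the order; its 3D FFT, rotationally
    averaged about k_z and support-masked, is the order-m OTF.  This is the
    same object `extract_otf` recovers from a simulated bead.
    """
    from .illumination import axial_order_profile

    nzv, nyv, nxv = shape
    h = detection_psf(model, shape, pixel_size_nm, z_step_nm, kind=psf_kind)
    z_um = (np.arange(nzv) - nzv // 2) * z_step_nm * 1e-3
    kx = fft.fftshift(fft.fftfreq(nxv, d=pixel_size_nm * 1e-3))
    ky = fft.fftshift(fft.fftfreq(nyv, d=pixel_size_nm * 1e-3))
    kzv = fft.fftshift(fft.fftfreq(nzv, d=z_step_nm * 1e-3))
    orders = {}
    for m in (0, 1, 2):
        jm = axial_order_profile(beams, m, -z_um)  # J_m(−ζ)
        km = h * jm[:, None, None]
        spec = fft.fftshift(fft.fftn(fft.ifftshift(km)))
        avg, kr = radial_average(spec, kx, ky)
        mask = order_support_mask(beams, model, m, kr, kzv)
        avg = np.where(mask, avg, 0.0)
        orders[m] = avg
    dc = orders[0][np.argmin(np.abs(kzv)), 0]
    for m in orders:
        orders[m] = orders[m] / dc
    return OTFSet(
        orders=orders,
        kr=kr,
        kz=kzv,
        modality="four_beam" if beams.mirror_reflectivity > 0 else "sim3d",
        excitation_wavelength=model.excitation_wavelength,
        emission_wavelength=model.emission_wavelength,
    )


# ---------------------------------------------------------------------------
# Extraction from bead stacks


class BeadTooCloseToEdgeError(ValueError):
    """The bead center is not within the central half of the field."""


class BeadTooLargeError(ValueError):
    """Sphere-transform compensation is ill-conditioned for this bead."""


def extract_otf(
    bead_stack: np.ndarray,
    bead_diameter_nm: float,
    model: OpticalModel,
    beams: BeamSet,
    pixel_size_nm: float,
    z_step_nm: float,
    background: float = 0.0,
    window_fraction: float = 0.1,
    sphere_guard: float = 0.05,
) -> OTFSet:
    """Derive per-order OTFs from a single-bead, single-orientation stack.

    ``bead_stack`` has shape (5 phases, Z, Y, X).  The procedure follows the
    measured-OTF pipeline: (1) phase-sum → wide-field PSF, parabolic
    sub-pixel centering (3-point laterally; 3-point axially for 3-beam,
    5-point for four-beam data); (2) background subtraction, squared-sine
    edge softening, 3D FFT, 5×5 separation-matrix unmixing and phase-ramp
    recentering; (3) division by the solid-sphere transform evaluated at
    the carried object frequency, with a small-denominator clamp;
    (4) rotational averaging about k_z; (5) support masking; (6) DC
    normalization of order 0.
    """
    if bead_stack.ndim != 4 or bead_stack.shape[0] != N_PHASES:
        raise ValueError("bead_stack must have shape (5, Z, Y, X)")
    four_beam = beams.mirror_reflectivity > 0
    stack = np.asarray(bead_stack, dtype=np.float64)
    _, nzv, nyv, nxv = stack.shape

    # (1) wide-field PSF and sub-pixel center
    wf = stack.sum(axis=0)
    iz, iy, ix = np.unravel_index(np.argmax(wf), wf.shape)
    for idx, n in ((iz, nzv), (iy, nyv), (ix, nxv)):
        if not n // 4 <= idx <= 3 * n // 4:
            raise BeadTooCloseToEdgeError(
                f"bead peak at index {idx} of {n} is outside the central half"
            )
    x0 = ix + parabolic_vertex_3pt(wf[iz, iy, ix - 1 : ix + 2])
    y0 = iy + parabolic_vertex_3pt(wf[iz, iy - 1 : iy + 2, ix])
    if four_beam:
        z0 = iz + parabolic_vertex_5pt(wf[iz - 2 : iz + 3, iy, ix])
    else:
        z0 = iz + parabolic_vertex_3pt(wf[iz - 1 : iz + 2, iy, ix])

    # (2) preprocess, FFT, separate, recenter
    from .reconstruction import separation_matrix, squared_sine_window

    win = squared_sine_window((nzv, nyv, nxv), window_fraction)
    spectra = np.empty((N_PHASES, nzv, nyv, nxv), dtype=np.complex128)
    for p in range(N_PHASES):
        vol = np.clip(stack[p] - background, 0.0, None) * win
        spectra[p] = fft.fftshift(fft.fftn(vol))
    vinv = np.linalg.inv(separation_matrix())
    bands = np.tensordot(vinv, spectra, axes=(1, 0))  # m = -2..2 -> rows 0..4

    kx = fft.fftshift(fft.fftfreq(nxv, d=pixel_size_nm * 1e-3))
    ky = fft.fftshift(fft.fftfreq(nyv, d=pixel_size_nm * 1e-3))
    kzv = fft.fftshift(fft.fftfreq(nzv, d=z_step_nm * 1e-3))
    KZ, KY, KX = np.meshgrid(kzv, ky, kx, indexing="ij")
    ramp = np.exp(
        2j
        * math.pi
        * (
            KX * x0 * pixel_size_nm * 1e-3
            + KY * y0 * pixel_size_nm * 1e-3
            + KZ * z0 * z_step_nm * 1e-3
        )
    )
    bands *= ramp[None]

    # (3) sphere compensation at the carried object frequency k − m·p
    ks = max(math.hypot(b.k[0], b.k[1]) for b in beams.components)
    orders = {}
    n_clamped_max = 0.0
    for m in (0, 1, 2):
        band = bands[m + 2]
        # Remove the order-m carrier phase exp(2πi·m·p·r0): the band of a
        # bead at r0 keeps this constant phase after recentering; in a
        # reconstruction it would be absorbed into the estimated initial
        # phase, but the stored OTF should not depend on where the bead sat.
        band = band * np.exp(
            -2j * math.pi * m * ks * x0 * pixel_size_nm * 1e-3
        )
        kobj = np.sqrt((KX - m * ks) ** 2 + KY**2 + KZ**2)  # cycles/µm
        denom = sphere_transform(bead_diameter_nm, kobj * 1e-3)
        small = np.abs(denom) < sphere_guard
        signs = np.where(denom >= 0.0, 1.0, -1.0)
        denom = np.where(small, signs * sphere_guard, denom)
        band = band / denom
        # (4) rotational average
        avg, kr = radial_average(band, kx, ky)
        # (5) support mask
        mask = order_support_mask(beams, model, m, kr, kzv)
        if m == 0:
            frac = float(small[mask_3d_from_2d(mask, kr, kzv, kx, ky)].mean()) if mask.any() else 1.0
            n_clamped_max = max(n_clamped_max, frac)
        orders[m] = np.where(mask, avg, 0.0)
    if n_clamped_max > 0.2:
        raise BeadTooLargeError(
            "sphere-transform denominator below the guard over "
            f"{100 * n_clamped_max:.0f}% of the order-0 support"
        )

    # (6) normalize to the order-0 DC
    dc = orders[0][np.argmin(np.abs(kzv)), 0]
    if dc == 0:
        raise ValueError("order-0 DC is zero; cannot normalize")
    for m in orders:
        orders[m] = orders[m] / dc
    return OTFSet(
        orders=orders,
        kr=kr,
        kz=kzv,
        modality="four_beam" if four_beam else "sim3d",
        excitation_wavelength=model.excitation_wavelength,
        emission_wavelength=model.emission_wavelength,
    )


def mask_3d_from_2d(
    mask2d: np.ndarray,
    kr: np.ndarray,
    kz: np.ndarray,
    kx: np.ndarray,
    ky: np.ndarray,
) -> np.ndarray:
    """Revolve a boolean (k_z, k_r) mask onto the 3D frequency grid."""
    out = revolve_2d_to_3d(mask2d.astype(float), kr, kz, kx, ky, kz)
    return out > 0.5
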
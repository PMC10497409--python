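"""SIM reconstruction: preprocessing, band separation, parameter
estimation and the generalized Wiener filter.

Four-beam reconstruction is machinery-identical to 3D SIM: the extra axial
frequencies live inside the per-order OTFs, while the number of lateral
bands (m = 0, ±1, ±2) is unchanged.  The pipeline is

1. *Preprocess*: subtract the camera offset, soften edges with a squared
   sine window, normalize every image to the stack-mean total intensity.
2. *Band separation*: the five phase-stepped spectra are unmixed with the
   inverse of the 5×5 phase matrix V[p, m] = exp(i·m·2πp/5).
3. *Parameter estimation*: pattern wave vector, initial phase and
   modulation depths from the complex cross-correlation between the
   OTF-filtered order-0 and shifted order-2 bands; order 1 is pinned to
   half the order-2 frequency.
4. *Generalized Wiener*: all bands of all orientations are shifted to
   their true positions on a laterally 2× upsampled grid and combined as
   S(k) = A(k)·Σ m̄·OTF*·D / (Σ |m|²·|OTF|² + w²), followed by inverse FFT
   and a nonnegativity clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as fft
from pydantic import BaseModel
from scipy.optimize import minimize

from .optics import OpticalModel
from .otf import OTFSet
from .phantoms import RawSIMStack

N_PHASES = 5
ORDERS = (-2, -1, 0, 1, 2)


class EstimationError(RuntimeError):
    """Pattern parameters could not be estimated from the data."""


def separation_matrix() -> np.ndarray:
    """The 5×5 mixing matrix V[p, m] = exp(i·m·φ_p), φ_p = 2πp/5.

    Columns are ordered m = −2..2.  V is √5 times a unitary matrix, so its
    inverse is Vᴴ/5.
    """
    p = np.arange(N_PHASES)[:, None]
    m = np.arange(-2, 3)[None, :]
    return np.exp(2j * math.pi * p * m / N_PHASES)


def squared_sine_window(shape: tuple[int, ...], fraction: float = 0.1) -> np.ndarray:
    """Separable squared-sine edge taper; ``fraction`` of each axis ramps."""
    win = np.ones(shape, dtype=np.float64)
    for ax, n in enumerate(shape):
        edge = max(int(round(fraction * n)), 1)
        w = np.ones(n)
        ramp = np.sin(0.5 * math.pi * (np.arange(edge) + 0.5) / edge) ** 2
        w[:edge] = ramp
        w[-edge:] = ramp[::-1]
        shape_ax = [1] * len(shape)
        shape_ax[ax] = n
        win = win * w.reshape(shape_ax)
    return win


def preprocess(
    stack: RawSIMStack,
    window_fraction: float = 0.1,
    normalize: str = "per_plane",
) -> RawSIMStack:
    """Offset subtraction, edge softening and intensity normalization.

    Each plane is reduced by the camera offset and clipped at zero; a
    squared-sine window softens lateral edges; intensities are rescaled to
    the stack mean to compensate illumination or bleaching fluctuations
    between orientations and depths.  The default ``per_plane`` mode gives
    all five phase images of one (orientation, z) plane a single factor:
    on sparse scenes the genuine phase-to-phase total-intensity modulation
    carries band information, and normalizing it away (``per_image``)
    leaks order 0 into the higher bands.
    """
    data = stack.data.astype(np.float32) - stack.camera_offset
    if np.mean(data < 0) > 0.5:
        import warnings

        warnings.warn(
            "more than half of all pixels are below the camera offset; "
            "clamping to zero",
            stacklevel=2,
        )
    np.clip(data, 0.0, None, out=data)
    win = squared_sine_window(stack.data.shape[-2:], window_fraction).astype(np.float32)
    data *= win
    totals = data.sum(axis=(-2, -1), keepdims=True)
    if normalize == "per_plane":
        totals = np.broadcast_to(totals.mean(axis=1, keepdims=True), totals.shape)
    elif normalize != "per_image":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    mean_total = float(totals.mean())
    if mean_total > 0:
        scale = np.where(totals > 0, mean_total / np.where(totals > 0, totals, 1.0), 1.0)
        data *= scale.astype(np.float32)
    return RawSIMStack(
        data=data,
        pixel_size_nm=stack.pixel_size_nm,
        z_step_nm=stack.z_step_nm,
        modality=stack.modality,
        camera_offset=0.0,
        orientation_angles=stack.orientation_angles,
        initial_phases=stack.initial_phases,
    )


@dataclass
class BandSet:
    """Separated complex bands of one orientation, unshifted FFT layout."""

    bands: dict  # {m: (Z, Y, X) complex64}
    pixel_size_nm: float
    z_step_nm: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bands[0].shape


def separate_bands(
    phase_volumes: np.ndarray,
    pixel_size_nm: float,
    z_step_nm: float,
) -> BandSet:
    """Unmix the 5 phase-stepped volumes of one orientation into bands.

    ``phase_volumes`` has shape (5, Z, Y, X).  The 3D FFTs of the five
    volumes are multiplied with the inverse separation matrix (conjugate
    transpose over 5), yielding the spectra of orders m = −2..2.
    """
    if phase_volumes.shape[0] != N_PHASES:
        raise ValueError("exactly 5 phase volumes are required")
    spectra = np.stack(
        [fft.fftn(np.asarray(v, np.float64), workers=-1) for v in phase_volumes]
    )
    vinv = separation_matrix().conj().T / N_PHASES  # rows m=-2..2
    mixed = np.tensordot(vinv, spectra, axes=(1, 0))
    # float64 input keeps full precision (the unmixing is exactly unitary);
    # float32 acquisitions are stored single precision to halve memory
    out_dtype = (
        np.complex128
        if np.asarray(phase_volumes).dtype == np.float64
        else np.complex64
    )
    bands = {m: mixed[i].astype(out_dtype) for i, m in enumerate(ORDERS)}
    return BandSet(bands=bands, pixel_size_nm=pixel_size_nm, z_step_nm=z_step_nm)


@dataclass
class IlluminationParams:
    """Estimated pattern parameters of one orientation."""

    wave_vector: tuple[float, float]  # order-1 lateral (kx, ky), cycles/µm
    initial_phase: float  # φ₀, radians
    modulation_depth_1: float
    modulation_depth_2: float

    @property
    def order2_vector(self) -> tuple[float, float]:
        return (2.0 * self.wave_vector[0], 2.0 * self.wave_vector[1])


def _pad_lateral(spec: np.ndarray, factor: int = 2) -> np.ndarray:
    """Zero-pad an unshifted spectrum laterally by ``factor``."""
    nz, ny, nx = spec.shape
    out = np.zeros((nz, factor * ny, factor * nx), dtype=spec.dtype)
    s = fft.fftshift(spec, axes=(1, 2))
    y0 = (factor - 1) * ny // 2
    x0 = (factor - 1) * nx // 2
    out_shifted = np.zeros_like(out)
    out_shifted[:, y0 : y0 + ny, x0 : x0 + nx] = s
    out = fft.ifftshift(out_shifted, axes=(1, 2))
    return out


def _flip_spectrum(spec: np.ndarray) -> np.ndarray:
    """Return f(−k) on the unshifted FFT grid."""
    out = spec[::-1, ::-1, ::-1]
    return np.roll(out, (1, 1, 1), axis=(0, 1, 2))


def _filtered_band_real(
    band: np.ndarray, otf3: np.ndarray, factor: int = 2
) -> np.ndarray:
    """OTF-matched-filtered band on the laterally upsampled real-space grid."""
    return fft.ifftn(_pad_lateral(band * np.conj(otf3), factor), workers=-1)


def _order_otf_3d(otfs: OTFSet, m: int, shape, pixel_size_nm, z_step_nm) -> np.ndarray:
    """3D OTF of signed order m on the unshifted raw grid."""
    o = otfs.to_3d(abs(m), shape, pixel_size_nm, z_step_nm)
    o = fft.ifftshift(o)
    if m < 0:
        o = np.conj(_flip_spectrum(o))
    return o.astype(np.complex64)


def _object_frame_otf(
    otfs: OTFSet,
    order: int,
    kx: np.ndarray,
    ky: np.ndarray,
    kz: np.ndarray,
    shift: tuple[float, float],
) -> np.ndarray:
    """Signed-order-m OTF sampled at object frequency ν on an unshifted grid.

    The band of order m detects object frequency ν through O_m(ν + m·p);
    the stored 2D OTF is radially symmetric about k_z in band coordinates,
    so the value is the bilinear interpolation at lateral radius
    |ν_lat + shift| (``shift`` = m·p).  Negative orders use the conjugate
    symmetry O_{−m}(k) = conj(O_{m}(−k)), i.e. rows at −ν_z, conjugated.

    Evaluating the OTF analytically at the shifted coordinate (rather than
    shifting a gridded copy by a fractional-bin phase ramp) keeps the
    Wiener numerator/denominator free of spectral leakage from the OTF's
    sharp DC peak.
    """
    arr = otfs.orders[abs(order)]
    nkz, nkr = arr.shape
    dkr = float(otfs.kr[1] - otfs.kr[0])
    kz_eval = -np.asarray(kz) if order < 0 else np.asarray(kz)
    # Map each requested (unshifted-layout) kz onto the stored ascending axis.
    j_map = np.abs(otfs.kz[:, None] - kz_eval[None, :]).argmin(axis=0)
    rows = arr[j_map]  # (nz, nkr)
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    rad = np.hypot(KX + shift[0], KY + shift[1])
    t = rad.ravel() / dkr
    i0 = np.floor(t).astype(np.int64)
    w = (t - i0).astype(arr.real.dtype)
    valid = i0 < nkr - 1
    i0c = np.clip(i0, 0, nkr - 2)
    out = rows[:, i0c] * (1.0 - w) + rows[:, i0c + 1] * w
    out[:, ~valid] = 0.0
    out = out.reshape((kz_eval.size,) + rad.shape)
    if order < 0:
        out = np.conj(out)
    return out.astype(np.complex64)


def _overlap_correlation(
    band_lo: np.ndarray,
    band_hi: np.ndarray,
    otfs: OTFSet,
    order: int,
    shift: np.ndarray,
    freqs: tuple[np.ndarray, np.ndarray, np.ndarray],
    ramp_xy: tuple[np.ndarray, np.ndarray],
    mask_threshold: float = 0.005,
    reg: float = 1e-3,
):
    """Common-region band-division correlation between order 0 and order m.

    Both bands are divided by their own OTF over the frequency region
    where both OTFs are strong, giving two estimates of the same object
    spectrum whose relative carrier exp(2πi·Δs·ρ) and phase encode the
    residual shift error and the pattern phase.  Returns the lateral
    correlation kernel q(ρ) summed over z, plus the normalization Σ|F₀|².
    """
    kx, ky, kz = freqs
    o0 = _object_frame_otf(otfs, 0, kx, ky, kz, (0.0, 0.0))
    om = _object_frame_otf(otfs, order, kx, ky, kz, (shift[0], shift[1]))
    a0 = np.abs(o0)
    am = np.abs(om)
    # Thresholds are relative to each band's own peak: with side beams at
    # ~92% of the pupil the order-0/order-2 overlap lives near both bands'
    # support edges, where the absolute OTF values are small.
    mask = (a0 > mask_threshold * a0.max()) & (am > mask_threshold * am.max())
    if not mask.any():
        raise EstimationError("order supports do not overlap at this shift")
    reg0 = reg * float(a0.max()) ** 2
    regm = reg * float(am.max()) ** 2
    # Both bands get the *identical* total transfer a0²·am²/((a0²+r)(am²+r)):
    # two copies of the same filtered object then differ only by the
    # residual carrier and the pattern phase, so the correlation kernel is
    # a positive envelope — any one-sided weighting would tilt its phase
    # and bias the shift estimate.
    common = np.where(mask, 1.0 / ((a0**2 + reg0) * (am**2 + regm)), 0.0)
    f0 = band_lo * np.conj(o0) * am**2 * common
    XX, YY = ramp_xy
    ramp = np.exp(-2j * math.pi * (shift[0] * XX + shift[1] * YY)).astype(np.complex64)
    moved = fft.fftn(fft.ifftn(band_hi, workers=-1) * ramp[None], workers=-1)
    fm = moved * np.conj(om) * a0**2 * common
    r0 = fft.ifftn(f0, workers=-1)
    rm = fft.ifftn(fm, workers=-1)
    q2d = np.sum(np.conj(r0) * rm, axis=0)
    norm = float(np.sum(np.abs(r0) ** 2))
    return q2d, norm


def estimate_parameters(
    bands: BandSet,
    otfs: OTFSet,
    guess_kvec: tuple[float, float] | None = None,
    search_radius: float = 3.0,
    min_correlation: float = 1e-4,
    refinement_rounds: int = 2,
) -> IlluminationParams:
    """Estimate the pattern wave vector, initial phase and modulation depths.

    The order-2 shift is found by cross-correlating two estimates of the
    object spectrum: order 0, and order 2 moved by the candidate shift,
    each divided by its own OTF over the common support region.  When both
    estimates see the same object, their correlation kernel is a positive
    envelope times exp(2πi·Δ·ρ); the residual shift Δ is located on the
    correlation grid and refined continuously (simplex, 10⁻⁴-px
    tolerance), and the candidate is updated over ``refinement_rounds``.
    Starting shift: 2× the design ``guess_kvec`` when given, otherwise the
    coarse peak of the matched-filter cross-correlation.  Order 1 is fixed
    at half the order-2 shift; its correlation argument gives the initial
    phase φ₀ and the magnitudes give the modulation depths.  A correlation
    below ``min_correlation`` of the order-0 energy raises
    :class:`EstimationError` (no detectable modulation).
    """
    nz, ny, nx = bands.shape
    dxy = bands.pixel_size_nm * 1e-3  # µm
    shape = bands.shape
    # The overlap region lives at object frequencies below the raw Nyquist,
    # so the whole estimation runs on the raw grid.
    b0 = bands.bands[0]
    b2 = bands.bands[2]
    kx = fft.fftfreq(nx, d=dxy)
    ky = fft.fftfreq(ny, d=dxy)
    kzv = fft.fftfreq(nz, d=bands.z_step_nm * 1e-3)
    dfx = kx[1] - kx[0]
    y_um = np.arange(ny) * dxy
    x_um = np.arange(nx) * dxy
    XX, YY = np.meshgrid(x_um, y_um)

    if guess_kvec is not None:
        s = np.array([2.0 * guess_kvec[0], 2.0 * guess_kvec[1]])
    else:
        o0f = _order_otf_3d(otfs, 0, shape, bands.pixel_size_nm, bands.z_step_nm)
        o2f = _order_otf_3d(otfs, 2, shape, bands.pixel_size_nm, bands.z_step_nm)
        r0 = fft.ifftn(_pad_lateral(bands.bands[0] * np.conj(o0f)), workers=-1)
        r2 = fft.ifftn(_pad_lateral(bands.bands[2] * np.conj(o2f)), workers=-1)
        corr = np.abs(fft.fft2(np.sum(np.conj(r0) * r2, axis=0)))
        FX, FY = np.meshgrid(kx, ky)
        masked = np.where(np.hypot(FX, FY) > 5 * dfx, corr, 0.0)
        iy, ix = np.unravel_index(np.argmax(masked), masked.shape)
        s = np.array([FX[iy, ix], FY[iy, ix]])

    c2 = 0.0 + 0.0j
    norm = 1.0
    for _ in range(refinement_rounds):
        q2d, norm = _overlap_correlation(
            b0, b2, otfs, 2, s, (kx, ky, kzv), (XX, YY)
        )
        corr = np.abs(fft.fft2(q2d))
        FX, FY = np.meshgrid(kx, ky)
        sel = np.hypot(FX, FY) <= search_radius * dfx
        iy, ix = np.unravel_index(np.argmax(np.where(sel, corr, 0.0)), corr.shape)
        d0 = np.array([FX[iy, ix], FY[iy, ix]])

        def corr_at(d):
            ph = np.exp(-2j * math.pi * (d[0] * XX + d[1] * YY))
            return np.sum(q2d * ph)

        res = minimize(
            lambda d: -np.abs(corr_at(d)),
            d0,
            method="Nelder-Mead",
            options={"xatol": 1e-4 * dfx, "fatol": 1e-12, "maxiter": 400},
        )
        s = s + res.x
        c2 = corr_at(res.x)
    if np.abs(c2) < min_correlation * norm:
        raise EstimationError(
            "no detectable modulation (order-2 correlation below threshold)"
        )
    m2 = float(np.abs(c2) / norm)

    # Order 1 pinned to half the order-2 shift; phase and depth from its
    # overlap correlation with order 0.
    b1 = bands.bands[1]
    s1 = s / 2.0
    q1, norm1 = _overlap_correlation(b0, b1, otfs, 1, s1, (kx, ky, kzv), (XX, YY))
    c1 = np.sum(q1)
    if np.abs(c1) < min_correlation * norm1:
        raise EstimationError(
            "no detectable modulation (order-1 correlation below threshold)"
        )
    m1 = float(np.abs(c1) / norm1)
    phi0 = float(np.angle(c1))
    return IlluminationParams(
        wave_vector=(s[0] / 2.0, s[1] / 2.0),
        initial_phase=phi0,
        modulation_depth_1=m1,
        modulation_depth_2=m2,
    )


class WienerConfig(BaseModel):
    """Generalized-Wiener filter settings (w = 0.001 throughout)."""

    wiener_parameter: float = 0.001
    apodization: str = "triangular"
    nonnegative: bool = True
    upsample: int = 2
    model_config = {"arbitrary_types_allowed": True}

    def __init__(self, **kw):
        super().__init__(**kw)
        if self.wiener_parameter <= 0:
            raise ValueError("wiener parameter must be positive")


@dataclass
class ReconVolume:
    """Reconstructed volume with voxel size and estimation log."""

    volume: np.ndarray  # (z, y, x) float32
    pixel_size_nm: float
    z_step_nm: float
    params: list = field(default_factory=list)
    modality: str = "sim3d"


def _apodization(
    shape: tuple[int, int, int],
    pixel_size_nm: float,
    z_step_nm: float,
    kr_cut: float,
    kz_cut: float,
) -> np.ndarray:
    """Triangular apodization A(k) = max(0, 1 − ρ(k)) on the unshifted grid.

    ρ is an ellipsoidal normalized distance reaching 1 at the extended
    lateral/axial cutoffs of the modality.
    """
    nz, ny, nx = shape
    kz = fft.fftfreq(nz, d=z_step_nm * 1e-3)
    ky = fft.fftfreq(ny, d=pixel_size_nm * 1e-3)
    kx = fft.fftfreq(nx, d=pixel_size_nm * 1e-3)
    KZ, KY, KX = np.meshgrid(kz, ky, kx, indexing="ij")
    rho = np.sqrt((KX**2 + KY**2) / kr_cut**2 + KZ**2 / kz_cut**2)
    return np.maximum(0.0, 1.0 - rho).astype(np.float32)


def extended_cutoffs(
    model: OpticalModel, params_list, otfs: OTFSet
) -> tuple[float, float]:
    """Extended (lateral, axial) band limits of the reconstruction."""
    p_mags = [math.hypot(*p.wave_vector) for p in params_list]
    kr_cut = model.detection_lateral_cutoff + 2.0 * max(p_mags)
    kz_nonzero = otfs.kz[np.any(np.abs(otfs.orders[0]) > 0, axis=1)]
    kz_ill = float(np.abs(kz_nonzero).max()) if kz_nonzero.size else 0.0
    kz_cut = max(kz_ill, model.detection_axial_cutoff)
    # order-1 axial extent can exceed order 0's
    kz1 = otfs.kz[np.any(np.abs(otfs.orders[1]) > 0, axis=1)]
    if kz1.size:
        kz_cut = max(kz_cut, float(np.abs(kz1).max()))
    return kr_cut, kz_cut


def wiener_reconstruct(
    band_sets: list[BandSet],
    params_list: list[IlluminationParams],
    otfs: OTFSet,
    model: OpticalModel,
    cfg: WienerConfig | None = None,
) -> ReconVolume:
    """Combine all orientations' bands with a generalized Wiener filter.

    Every band is matched-filtered with its OTF, moved to its true lateral
    position on a 2× upsampled grid via a real-space phase ramp, and the
    accumulated numerator is divided by the accumulated |OTF|² energy plus
    w².  The result is apodized with a triangular ellipsoid, inverse
    transformed, and clamped to nonnegative reals.
    """
    cfg = cfg or WienerConfig()
    if len(band_sets) != len(params_list):
        raise ValueError("one IlluminationParams per orientation is required")
    shape = band_sets[0].shape
    for bs in band_sets:
        if bs.shape != shape:
            raise ValueError("all orientations must share one grid")
    nz, ny, nx = shape
    f = cfg.upsample
    big = (nz, f * ny, f * nx)
    px = band_sets[0].pixel_size_nm
    dz = band_sets[0].z_step_nm
    y_um = np.arange(big[1]) * px * 1e-3 * ny / big[1]
    x_um = np.arange(big[2]) * px * 1e-3 * nx / big[2]
    XX, YY = np.meshgrid(x_um, y_um)
    kxb = fft.fftfreq(big[2], d=px * 1e-3 * nx / big[2])
    kyb = fft.fftfreq(big[1], d=px * 1e-3 * ny / big[1])
    kzb = fft.fftfreq(nz, d=dz * 1e-3)

    num_k = np.zeros(big, dtype=np.complex64)
    den_k = np.zeros(big, dtype=np.float32)
    for bs, pars in zip(band_sets, params_list):
        kvec = pars.wave_vector
        weights = {
            0: 1.0 + 0.0j,
            1: pars.modulation_depth_1 * np.exp(1j * pars.initial_phase),
            2: pars.modulation_depth_2 * np.exp(2j * pars.initial_phase),
        }
        weights[-1] = np.conj(weights[1])
        weights[-2] = np.conj(weights[2])
        for m in ORDERS:
            # Band m stores object frequency ν at position ν + m·p; the
            # −m·p real-space ramp moves the *data* to its true place,
            # while the OTF is evaluated analytically at the shifted
            # coordinate (a gridded-OTF shift would leak its DC spike
            # across the spectrum at fractional-bin shifts).
            o_obj = _object_frame_otf(
                otfs, m, kxb, kyb, kzb, (m * kvec[0], m * kvec[1])
            )
            ramp = np.exp(
                -2j * math.pi * m * (kvec[0] * XX + kvec[1] * YY)
            ).astype(np.complex64)
            bshift = fft.fftn(
                fft.ifftn(_pad_lateral(bs.bands[m], f), workers=-1) * ramp[None],
                workers=-1,
            )
            num_k += np.complex64(np.conj(weights[m])) * np.conj(o_obj) * bshift
            den_k += np.float32(abs(weights[m]) ** 2) * (
                np.abs(o_obj) ** 2
            ).astype(np.float32)

    w2 = cfg.wiener_parameter**2
    s_k = num_k / (den_k + w2)
    kr_cut, kz_cut = extended_cutoffs(model, params_list, otfs)
    if cfg.apodization == "triangular":
        s_k *= _apodization(big, px / f, dz, kr_cut, kz_cut)
    out = fft.ifftn(s_k, workers=-1).real
    if cfg.nonnegative:
        np.clip(out, 0.0, None, out=out)
    return ReconVolume(
        volume=out.astype(np.float32),
        pixel_size_nm=px / f,
        z_step_nm=dz,
        params=list(params_list),
        modality=otfs.modality,
    )


def reconstruct(
    stack: RawSIMStack,
    otfs: OTFSet,
    model: OpticalModel,
    cfg: WienerConfig | None = None,
    guess_kvecs: list[tuple[float, float]] | None = None,
) -> ReconVolume:
    """Full pipeline: preprocess → separate → estimate → Wiener combine.

    ``guess_kvecs`` seeds the per-orientation wave-vector search with the
    design values (recommended); estimation is otherwise global.
    """
    pre = preprocess(stack)
    band_sets, params = [], []
    for d in range(pre.n_orientations):
        bs = separate_bands(pre.data[d], pre.pixel_size_nm, pre.z_step_nm)
        band_sets.append(bs)
        guess = guess_kvecs[d] if guess_kvecs else None
        params.append(estimate_parameters(bs, otfs, guess_kvec=guess))
    return wiener_reconstruct(band_sets, params, otfs, model, cfg)


def design_guess_kvecs(model: OpticalModel, stack: RawSIMStack):
    """Design-value wave vectors (cycles/µm) for each orientation."""
    ks = model.pattern_lateral_frequency
    return [
        (ks * math.cos(math.radians(a)), ks * math.sin(math.radians(a)))
        for a in stack.orientation_angles
    ]
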
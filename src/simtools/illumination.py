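"""SLM pattern design and interference-pattern modelling.

The SLM acts as a binary π phase grating.  Three focused beams (the 0th and
±1st diffraction orders) interfere at the sample to give the 3D SIM pattern;
back-reflecting the central beam off a mirror placed opposite the sample adds
a fourth beam and with it an axial standing wave at frequencies up to
2n/λ_ex.  This module holds the closed-form design calculators (pattern
orientations, grating periods, diffraction-order amplitudes, pinhole-mask
geometry), the pattern-finding algorithm that rasterizes the binary grating,
and the plane-wave interference model used by the forward simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, model_validator

from .optics import BeamSet, OpticalModel

#: The three default SLM orientation vectors (10.3°, 70.3°, 130.2°).
DEFAULT_ORIENTATION_VECTORS: tuple[tuple[int, int], ...] = (
    (2, -11),
    (14, -5),
    (13, 11),
)

N_PHASES = 5


class SLMPatternSpec(BaseModel):
    """One binary grating pattern on the SLM pixel grid."""

    orientation_vector: tuple[int, int]
    period_px: float  # grating period p, SLM pixels
    duty_cycle: float = 0.33  # fraction of pixels in the π state
    phase_index: int = 0  # 0..4; consecutive indices step the phase by p/5
    grid_shape: tuple[int, int] = (512, 512)  # (rows, cols)

    @model_validator(mode="after")
    def _check(self) -> "SLMPatternSpec":
        if self.orientation_vector == (0, 0):
            raise ValueError("orientation_vector must be nonzero")
        if self.period_px < 2.0:
            raise ValueError(
                "period_px below 2 SLM pixels is under the SLM Nyquist limit"
            )
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must lie in [0, 1]")
        if not 0 <= self.phase_index:
            raise ValueError("phase_index must be nonnegative")
        return self

    @property
    def reduced_vector(self) -> tuple[int, int]:
        """gcd-reduced form of the orientation vector."""
        ax, ay = self.orientation_vector
        g = math.gcd(abs(ax), abs(ay))
        return (ax // g, ay // g)


def pattern_angle(a: tuple[int, int]) -> float:
    """Angle of the pattern wave vector, degrees in [0, 180).

    The stripes run parallel to the integer vector A; the pattern normal is
    B = (−A_y, A_x) and the returned angle is that of B from the SLM x axis,
    folded into [0°, 180°).  The default vectors (2,−11), (14,−5), (13,11)
    map to 10.3°, 70.3° and 130.2°.
    """
    ax, ay = a
    if ax == 0 and ay == 0:
        raise ValueError("orientation vector must be nonzero")
    bx, by = -ay, ax
    ang = math.degrees(math.atan2(by, bx)) % 180.0
    return ang


def slm_period(model: OpticalModel) -> tuple[float, float]:
    """SLM grating period P = M·λ_ex/(r·NA).

    Returns ``(period_um, period_px)`` where the pixel value divides by the
    SLM pixel pitch.  M is derived from the relay chain (f3/f_obj)·(f5/f4).
    """
    m = model.demagnification
    lam_um = model.excitation_wavelength * 1e-3
    p_um = m * lam_um / (model.side_beam_fraction * model.numerical_aperture)
    return p_um, p_um / model.slm_pixel


def generate_slm_pattern(spec: SLMPatternSpec) -> np.ndarray:
    """Rasterize a binary π grating; returns a uint8 grid (1 = π state).

    Per pixel (x, y) the scalar projection s on the unit pattern normal B is
    reduced modulo the period p; the pixel is set to the π state iff
    s mod p < duty·p (the boundary s mod p = duty·p falls in the 0 state).
    ``phase_index`` k shifts the pattern origin by k·p/5 along B.
    """
    ax, ay = spec.orientation_vector
    bx, by = float(-ay), float(ax)
    norm = math.hypot(bx, by)
    bx, by = bx / norm, by / norm
    rows, cols = spec.grid_shape
    y, x = np.mgrid[0:rows, 0:cols]
    p = spec.period_px
    shift = spec.phase_index * p / N_PHASES
    s = (x * bx + y * by - shift) % p
    return (s < spec.duty_cycle * p).astype(np.uint8)


def grating_order_amplitudes(duty_cycle: float, orders=(0, 1, 2)) -> dict:
    """Complex diffraction-order amplitudes of an ideal binary π grating.

    The grating transmits +1 over a fraction 1−d of the period and
    e^{iπ} = −1 over a fraction d.  The scalar Fourier series gives
    c_0 = 1 − 2d and c_m = (i/(πm))·(e^{−2πi·m·d} − 1) for m ≠ 0, so
    |c_±1| = 2·sin(πd)/π.  A duty cycle of 0.5 cancels the zero order;
    real SLMs add fill-factor and reflection losses not modelled here.
    """
    if not 0.0 <= duty_cycle <= 1.0:
        raise ValueError("duty cycle must lie in [0, 1]")
    out: dict[int, complex] = {}
    for m in orders:
        for mm in {m, -m}:
            if mm == 0:
                out[0] = complex(1.0 - 2.0 * duty_cycle)
            else:
                out[mm] = (
                    1j / (math.pi * mm)
                    * (np.exp(-2j * math.pi * mm * duty_cycle) - 1.0)
                )
    return out


def pinhole_mask_positions(model: OpticalModel, period_um: float) -> float:
    """Radial offset (mm) of the ±1-order spots at the pinhole mask.

    The mask sits at the focus of the first relay lens, so the spots fall at
    f3·λ_ex/P from the axis (1 central hole + 6 at 60° intervals).
    """
    if period_um <= 0:
        if period_um == math.inf:
            return 0.0
        raise ValueError("period must be positive")
    lam_mm = model.excitation_wavelength * 1e-6
    return model.f3 * lam_mm / (period_um * 1e-3)


# ---------------------------------------------------------------------------
# Interference model


@dataclass(frozen=True)
class OrderComponent:
    """One frequency component of the interference pattern.

    ``m`` is the lateral harmonic order (−2..2), ``kz`` the axial frequency
    (cycles/µm) and ``weight`` the complex amplitude a_j·conj(a_l) of the
    beam pair that produces it.
    """

    m: int
    kz: float
    weight: complex


def order_components(beams: BeamSet) -> list[OrderComponent]:
    """Expand |Σ a_j e^{2πi k_j·r}|² into lateral-order components.

    Every beam pair (j, l) contributes weight a_j·a_l* at frequency
    k_j − k_l.  Pairs are grouped by the projection of the lateral
    difference onto the pattern direction in units of the fundamental;
    components sharing (m, kz) are summed.
    """
    comps = beams.components
    # Pattern direction and fundamental from the most lateral beam.
    lat = [(math.hypot(b.k[0], b.k[1]), b) for b in comps]
    ks, ref = max(lat, key=lambda t: t[0])
    if ks < 1e-12:  # single on-axis beam: DC only
        ux, uy = 1.0, 0.0
    else:
        ux, uy = ref.k[0] / ks, ref.k[1] / ks
    grouped: dict[tuple[int, float], complex] = {}
    for bj in comps:
        for bl in comps:
            dkx = bj.k[0] - bl.k[0]
            dky = bj.k[1] - bl.k[1]
            dkz = bj.k[2] - bl.k[2]
            proj = dkx * ux + dky * uy
            m = int(round(proj / ks)) if ks > 1e-12 else 0
            key = (m, round(dkz, 9))
            w = bj.amplitude * np.conj(bl.amplitude)
            grouped[key] = grouped.get(key, 0.0) + w
    return [
        OrderComponent(m=m, kz=kz, weight=w)
        for (m, kz), w in sorted(grouped.items())
        if abs(w) > 1e-15
    ]


def axial_order_profile(beams: BeamSet, m: int, z_um: np.ndarray) -> np.ndarray:
    """Complex axial modulation J_m(z) of lateral order m.

    J_m(z) = Σ over beam pairs with lateral difference m·p of
    a_j·a_l*·exp(2πi·Δk_z·z).  For three beams order ±1 carries the 3D SIM
    axial beating; the reflected beam adds the ±2n/λ standing wave to order
    0 and two extra axial frequencies to order ±1.
    """
    z = np.asarray(z_um, dtype=np.float64)
    out = np.zeros(z.shape, dtype=np.complex128)
    for c in order_components(beams):
        if c.m == m:
            out += c.weight * np.exp(2j * math.pi * c.kz * z)
    return out


def interference_intensity(
    beams: BeamSet,
    x_um: np.ndarray,
    y_um: np.ndarray,
    z_um: np.ndarray,
) -> np.ndarray:
    """Interference intensity I(r) = |Σ_j a_j e^{2πi k_j·r}|² on a 3D grid.

    ``x_um, y_um, z_um`` are 1-D coordinate vectors in µm; the result is a
    real nonnegative ``(z, y, x)`` array.  The grid must Nyquist-sample the
    highest pairwise difference frequency; an undersampled axis raises a
    ``ValueError`` naming the offending frequency.
    """
    x = np.asarray(x_um, float)
    y = np.asarray(y_um, float)
    z = np.asarray(z_um, float)
    comps = beams.components
    # Nyquist check on pairwise difference frequencies.
    for axis, coord, name in ((0, x, "x"), (1, y, "y"), (2, z, "z")):
        if coord.size < 2:
            continue
        d = float(np.max(np.abs(np.diff(coord))))
        fmax = max(
            abs(bj.k[axis] - bl.k[axis]) for bj in comps for bl in comps
        )
        if fmax > 0 and d > 0.5 / fmax:
            raise ValueError(
                f"grid undersamples the {name} interference frequency "
                f"{fmax:.3f} cycles/µm (spacing {d:.4f} µm > "
                f"{0.5 / fmax:.4f} µm)"
            )
    field = np.zeros((z.size, y.size, x.size), dtype=np.complex128)
    for b in comps:
        phase = (
            2j
            * math.pi
            * (
                b.k[0] * x[None, None, :]
                + b.k[1] * y[None, :, None]
                + b.k[2] * z[:, None, None]
            )
        )
        field += b.amplitude * np.exp(phase)
    return np.abs(field) ** 2


def design_table(model: OpticalModel, duty_cycle: float = 0.33) -> dict:
    """Summary of the pattern design for one optical model.

    Collects the quantities an instrument builder checks: the orientation
    angles of the three default SLM vectors, the grating period in µm and
    SLM pixels, the pinhole-mask spot offset and the zero/first diffraction
    order intensity ratio at the requested duty cycle.
    """
    p_um, p_px = slm_period(model)
    amps = grating_order_amplitudes(duty_cycle)
    ratio = abs(amps[0]) ** 2 / abs(amps[1]) ** 2 if abs(amps[1]) else math.inf
    return {
        "demagnification": model.demagnification,
        "orientation_angles_deg": {
            str(v): pattern_angle(v) for v in DEFAULT_ORIENTATION_VECTORS
        },
        "slm_period_um": p_um,
        "slm_period_px": p_px,
        "pinhole_offset_mm": pinhole_mask_positions(model, p_um),
        "duty_cycle": duty_cycle,
        "zero_to_first_order_intensity_ratio": ratio,
        "pattern_lateral_frequency_cycles_per_um": 2.0
        * model.pattern_lateral_frequency,
    }
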
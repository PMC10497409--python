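"""Optical system model shared by every other module.

The :class:`OpticalModel` is the single source of geometry: wavelengths,
numerical aperture, immersion index, the SLM-to-sample relay chain and the
sampling of the camera and the z piezo.  :class:`BeamSet` describes the
coherent plane waves that interfere at the sample (three beams for 3D SIM,
four when the central beam is back-reflected by the mirror).

Unit conventions used throughout the package:

* lengths in nm unless a field name says otherwise (relay focals in mm,
  SLM pixel in µm),
* spatial frequencies in cycles/µm,
* volumes as ``(z, y, x)`` arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator


class OpticalModel(BaseModel):
    """Geometry and sampling of the SIM instrument.

    Defaults describe the 1.27 NA water-immersion configuration with 488 nm
    excitation; the classmethods provide the two supported lens configurations.
    """

    excitation_wavelength: float = 488.0  # nm
    emission_wavelength: float = 525.0  # nm
    numerical_aperture: float = 1.27
    refractive_index: float = 1.33
    side_beam_fraction: float = 0.92  # r, fraction of pupil radius
    f3: float = 300.0  # mm, relay lens after the SLM
    f4: float = 250.0  # mm
    f5: float = 250.0  # mm
    f6: float = 265.0  # mm, tube lens (detection side, informational)
    f_obj: float = 3.33  # mm
    slm_pixel: float = 9.2  # µm
    camera_sample_pixel: float = 81.8  # nm, image pixel in sample units
    z_step: float = 125.0  # nm

    @model_validator(mode="after")
    def _check(self) -> "OpticalModel":
        if self.numerical_aperture <= 0 or self.refractive_index <= 0:
            raise ValueError("NA and refractive index must be positive")
        if self.numerical_aperture > self.refractive_index:
            raise ValueError(
                "numerical_aperture must not exceed refractive_index "
                "(beam angles must be real)"
            )
        if not 0.0 < self.side_beam_fraction <= 1.0:
            raise ValueError("side_beam_fraction must lie in (0, 1]")
        for name in ("f3", "f4", "f5", "f_obj", "slm_pixel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        m = self.demagnification
        if not math.isfinite(m) or m <= 0:
            raise ValueError("derived demagnification must be positive finite")
        return self

    @property
    def demagnification(self) -> float:
        """SLM-to-sample demagnification M = (f3/f_obj)·(f5/f4)."""
        return (self.f3 / self.f_obj) * (self.f5 / self.f4)

    @property
    def half_angle(self) -> float:
        """Light-gathering half angle alpha (radians), sin(alpha) = NA/n."""
        return math.asin(self.numerical_aperture / self.refractive_index)

    @property
    def detection_lateral_cutoff(self) -> float:
        """Wide-field lateral band limit 2·NA/λ_em, cycles/µm."""
        return 2.0 * self.numerical_aperture / (self.emission_wavelength * 1e-3)

    @property
    def detection_axial_cutoff(self) -> float:
        """Wide-field axial band limit (1−cosα)·n/λ_em, cycles/µm."""
        return (
            (1.0 - math.cos(self.half_angle))
            * self.refractive_index
            / (self.emission_wavelength * 1e-3)
        )

    @property
    def pattern_lateral_frequency(self) -> float:
        """Fundamental lateral frequency of the illumination pattern.

        The ±1-order beams sit at a fraction ``r`` of the pupil radius, so a
        side and the central beam beat at r·NA/λ_ex; the two side beams beat
        at 2·r·NA/λ_ex (cycles/µm).
        """
        return (
            self.side_beam_fraction
            * self.numerical_aperture
            / (self.excitation_wavelength * 1e-3)
        )

    @classmethod
    def silicone_oil(cls) -> "OpticalModel":
        """1.35 NA / ×100 silicone-oil configuration."""
        return cls(
            numerical_aperture=1.35,
            refractive_index=1.406,
            f3=250.0,
            f4=300.0,
            f5=250.0,
            f6=165.0,
            f_obj=1.8,
            camera_sample_pixel=70.9,
        )

    @classmethod
    def water(cls) -> "OpticalModel":
        """1.27 NA / ×60 water-immersion configuration."""
        return cls()


@dataclass(frozen=True)
class PlaneWave:
    """A single coherent plane-wave component.

    ``k`` is the 3D wave vector in cycles/µm with magnitude n/λ_ex;
    polarization is assumed s (unit pattern contrast).
    """

    amplitude: complex
    k: tuple[float, float, float]  # (kx, ky, kz), cycles/µm


@dataclass
class BeamSet:
    """The interfering beams of one pattern orientation.

    Three beams (central + two side beams) give the 3D SIM pattern; adding
    the mirror-reflected central beam (k_z negated, amplitude scaled by
    ``mirror_reflectivity``·exp(i·``mirror_phase``)) gives the four-beam
    pattern.  ``mirror_phase`` maps to physical mirror travel as
    θ_m = 4π·n·Δz_mirror/λ_ex (documented, not enforced).
    """

    beams: list[PlaneWave]
    mirror_phase: float = 0.0  # radians
    mirror_reflectivity: float = 0.0  # ρ in [0, 1]; 0 → pure 3-beam

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("BeamSet requires at least one beam")
        if not 0.0 <= self.mirror_reflectivity <= 1.0:
            raise ValueError("mirror_reflectivity must lie in [0, 1]")
        mags = [math.sqrt(sum(c * c for c in b.k)) for b in self.beams]
        if max(mags) - min(mags) > 1e-6 * max(mags):
            raise ValueError(
                "all wave vectors must share the same magnitude n/λ_ex"
            )

    @property
    def components(self) -> list[PlaneWave]:
        """All interfering components, including the reflected beam if any."""
        out = list(self.beams)
        if self.mirror_reflectivity > 0.0:
            c = self.central_beam
            out.append(
                PlaneWave(
                    amplitude=c.amplitude
                    * self.mirror_reflectivity
                    * np.exp(1j * self.mirror_phase),
                    k=(c.k[0], c.k[1], -c.k[2]),
                )
            )
        return out

    @property
    def central_beam(self) -> PlaneWave:
        """The beam with the smallest lateral wave-vector component."""
        return min(self.beams, key=lambda b: math.hypot(b.k[0], b.k[1]))

    @property
    def n_components(self) -> int:
        return len(self.components)


def make_beams(
    model: OpticalModel,
    orientation_deg: float,
    *,
    four_beam: bool = False,
    mirror_phase: float = 0.0,
    mirror_reflectivity: float = 1.0,
    amplitudes: tuple[complex, complex, complex] = (1.0, 1.0, 1.0),
) -> BeamSet:
    """Build the 3- or 4-beam set for one pattern orientation.

    The side beams sit at a fraction ``model.side_beam_fraction`` of the
    pupil radius, at ``orientation_deg`` from the x axis (the pattern
    wave-vector direction).  ``amplitudes`` are (side−, central, side+).
    """
    n_over_lam = model.refractive_index / (model.excitation_wavelength * 1e-3)
    ks = model.pattern_lateral_frequency  # lateral frequency of a side beam
    kz_side = math.sqrt(max(n_over_lam**2 - ks**2, 0.0))
    th = math.radians(orientation_deg)
    ux, uy = math.cos(th), math.sin(th)
    a_minus, a_c, a_plus = amplitudes
    beams = [
        PlaneWave(a_minus, (-ks * ux, -ks * uy, kz_side)),
        PlaneWave(a_c, (0.0, 0.0, n_over_lam)),
        PlaneWave(a_plus, (ks * ux, ks * uy, kz_side)),
    ]
    return BeamSet(
        beams=beams,
        mirror_phase=mirror_phase,
        mirror_reflectivity=mirror_reflectivity if four_beam else 0.0,
    )
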
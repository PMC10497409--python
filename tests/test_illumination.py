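"""Pattern design calculators and the plane-wave interference model."""

import math

import numpy as np
import pytest
import scipy.fft as fft

from simtools.illumination import (
    SLMPatternSpec,
    design_table,
    generate_slm_pattern,
    grating_order_amplitudes,
    interference_intensity,
    order_components,
    pattern_angle,
    pinhole_mask_positions,
    slm_period,
)
from simtools.optics import BeamSet, PlaneWave, make_beams


@pytest.mark.parametrize(
    "vector, angle",
    [
        ((2, -11), 10.3),
        ((14, -5), 70.3),
        ((13, 11), 130.2),
        ((1, 0), 90.0),
    ],
)
def test_pattern_angle_reproduces_design_orientations(vector, angle):
    assert pattern_angle(vector) == pytest.approx(angle, abs=0.05)


def test_pattern_angle_rejects_zero_vector():
    with pytest.raises(ValueError):
        pattern_angle((0, 0))


def test_pattern_angle_folds_into_half_turn():
    for v in [(3, 5), (-3, -5), (7, -2)]:
        a = pattern_angle(v)
        assert 0.0 <= a < 180.0
        assert pattern_angle((-v[0], -v[1])) == pytest.approx(a)


def test_slm_period_design_values(water, silicone):
    p_sil, _ = slm_period(silicone)
    p_wat, px_wat = slm_period(water)
    assert silicone.demagnification == pytest.approx(115.7, abs=0.05)
    assert water.demagnification == pytest.approx(90.1, abs=0.05)
    assert p_sil == pytest.approx(45.5, abs=0.05)
    assert p_wat == pytest.approx(37.6, abs=0.05)
    assert px_wat == pytest.approx(4.09, abs=0.005)


def test_slm_period_identity_case(water):
    tiny = water.model_copy(
        update=dict(
            excitation_wavelength=1.0,
            side_beam_fraction=1.0,
            numerical_aperture=1.0,
            refractive_index=1.0,
            f3=1.0,
            f4=1.0,
            f5=1.0,
            f_obj=1.0,
        )
    )
    p, _ = slm_period(tiny)
    assert p == pytest.approx(0.001)


def test_generate_slm_pattern_duty_and_periodicity():
    spec = SLMPatternSpec(
        orientation_vector=(2, -11), period_px=4.95, duty_cycle=0.33
    )
    grid = generate_slm_pattern(spec)
    # on-pixel fraction tracks the duty cycle
    assert abs(grid.mean() - 0.33) < 0.02
    # zero duty cycle → empty grid
    empty = generate_slm_pattern(spec.model_copy(update={"duty_cycle": 0.0}))
    assert not empty.any()
    # a full period of phase steps wraps around
    p0 = generate_slm_pattern(spec.model_copy(update={"phase_index": 0}))
    p5 = generate_slm_pattern(spec.model_copy(update={"phase_index": 5}))
    np.testing.assert_array_equal(p0, p5)


def test_generate_slm_pattern_constant_along_stripes():
    # integer A with integer-multiple translation along A leaves the
    # pattern unchanged (stripes run parallel to A)
    spec = SLMPatternSpec(
        orientation_vector=(1, -2), period_px=5.0, duty_cycle=0.4,
        grid_shape=(64, 64),
    )
    grid = generate_slm_pattern(spec)
    shifted = np.roll(np.roll(grid, -2, axis=0), 1, axis=1)  # move by A=(1,-2)
    np.testing.assert_array_equal(grid[4:-4, 4:-4], shifted[4:-4, 4:-4])


def test_pattern_rejects_sub_nyquist_period():
    with pytest.raises(ValueError):
        SLMPatternSpec(orientation_vector=(1, 0), period_px=1.5)


def test_grating_order_amplitudes_against_fft_oracle():
    # oracle: FFT of the densely sampled two-level phase function
    for d in (0.2, 0.33, 0.5):
        n = 20000
        x = np.arange(n) / n
        t = np.where(x < d, -1.0, 1.0)
        coef = np.fft.fft(t) / n
        amps = grating_order_amplitudes(d)
        assert abs(amps[0]) == pytest.approx(abs(coef[0]), abs=1e-3)
        assert abs(amps[1]) == pytest.approx(abs(coef[-1]), abs=1e-3)
        assert abs(amps[1]) == pytest.approx(2 * math.sin(math.pi * d) / math.pi, abs=1e-9)
    assert grating_order_amplitudes(0.5)[0] == pytest.approx(0.0)
    assert grating_order_amplitudes(0.0)[0] == pytest.approx(1.0)
    assert abs(grating_order_amplitudes(0.0)[1]) == pytest.approx(0.0)


def test_zero_to_first_order_ratio_at_third_duty():
    amps = grating_order_amplitudes(0.33)
    ratio = abs(amps[0]) ** 2 / abs(amps[1]) ** 2
    assert ratio == pytest.approx(0.385, abs=0.001)


def test_pinhole_mask_positions(silicone):
    # f3·λ/P with f3 = 250 mm, λ = 488 nm, P = 45.5 µm
    assert pinhole_mask_positions(silicone, 45.5) == pytest.approx(2.68, abs=0.01)
    assert pinhole_mask_positions(silicone, math.inf) == 0.0
    one = pinhole_mask_positions(silicone, 40.0)
    assert pinhole_mask_positions(silicone, 80.0) == pytest.approx(one / 2)


def test_single_beam_intensity_is_constant():
    b = BeamSet([PlaneWave(1.0, (0.0, 0.0, 2.7))])
    grid = np.linspace(0.0, 2.0, 32)
    intensity = interference_intensity(b, grid, grid, grid)
    assert intensity.std() < 1e-10 * intensity.mean()


def test_three_beam_spectrum_has_seven_components(water, beams3):
    assert len(order_components(beams3)) == 7


def test_four_beam_spectrum_has_thirteen_components(beams4):
    comps = order_components(beams4)
    assert len(comps) == 13
    sw = 2 * 1.33 / 0.488
    assert any(c.m == 0 and abs(abs(c.kz) - sw) < 1e-6 for c in comps)


def test_standing_wave_axial_period(water):
    # central + reflected beam only: pure standing wave with period λ/2n
    b = make_beams(water, 0.0, four_beam=True, amplitudes=(0.0, 1.0, 0.0))
    z = np.linspace(0.0, 8.0, 4096, endpoint=False)
    intensity = interference_intensity(b, np.array([0.0]), np.array([0.0]), z)
    prof = intensity[:, 0, 0]
    spec = np.abs(np.fft.rfft(prof - prof.mean()))
    freqs = np.fft.rfftfreq(4096, d=z[1] - z[0])
    peak = freqs[np.argmax(spec)]
    assert peak == pytest.approx(2 * 1.33 / 0.488, rel=0.012)


def test_four_beam_reduces_to_three_beam_at_zero_reflectivity(water):
    b3 = make_beams(water, 25.0)
    b4 = make_beams(water, 25.0, four_beam=True, mirror_reflectivity=0.0)
    grid = np.linspace(0.0, 1.0, 24)
    i3 = interference_intensity(b3, grid, grid, grid)
    i4 = interference_intensity(b4, grid, grid, grid)
    np.testing.assert_allclose(i3, i4)


def test_intensity_gauge_invariances(water):
    grid = np.linspace(0.0, 1.0, 24)
    base = make_beams(water, 0.0)
    ref = interference_intensity(base, grid, grid, grid)
    phased = BeamSet(
        [PlaneWave(b.amplitude * np.exp(0.7j), b.k) for b in base.beams]
    )
    np.testing.assert_allclose(
        interference_intensity(phased, grid, grid, grid), ref, rtol=1e-10
    )
    scaled = BeamSet([PlaneWave(b.amplitude * 2.0, b.k) for b in base.beams])
    np.testing.assert_allclose(
        interference_intensity(scaled, grid, grid, grid), 4.0 * ref, rtol=1e-10
    )


def test_undersampled_grid_raises_naming_frequency(water, beams3):
    coarse = np.linspace(0.0, 10.0, 8)
    with pytest.raises(ValueError, match="cycles/µm"):
        interference_intensity(beams3, coarse, np.array([0.0]), np.array([0.0]))


def test_lateral_fundamental_matches_design(water):
    # the axially averaged pattern keeps only the pure-lateral components
    # (the order-±1 beats carry axial frequencies and average out), so the
    # FFT peak of the averaged profile sits at 2·r·NA/λ_ex
    beams = make_beams(water, 0.0)
    n = 256
    x = np.arange(n) * 0.02  # 20-nm sampling
    z = np.linspace(0.0, 7.0, 128, endpoint=False)
    intensity = interference_intensity(beams, x, np.array([0.0]), z)
    prof = intensity[:, 0, :].mean(axis=0)
    spec = np.abs(fft.rfft(prof - prof.mean()))
    freqs = fft.rfftfreq(n, d=0.02)
    expected = 2 * water.pattern_lateral_frequency
    assert abs(freqs[np.argmax(spec)] - expected) < freqs[1] - freqs[0]


def test_grating_energy_conservation_property():
    # unit-modulus phase gratings conserve energy: Σ|c_m|² = 1 for the
    # full series; check via dense FFT across duty cycles
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def check(d):
        n = 4096
        x = np.arange(n) / n
        t = np.where(x < d, -1.0, 1.0)
        coef = np.fft.fft(t) / n
        assert np.sum(np.abs(coef) ** 2) == pytest.approx(1.0, abs=1e-9)
        amps = grating_order_amplitudes(d)
        assert abs(amps[0]) == pytest.approx(abs(coef[0]), abs=1e-3)

    check()


def test_pattern_angle_rotation_property():
    # rotating A by 90° rotates the pattern normal by 90° (mod 180°)
    from hypothesis import given, settings
    from hypothesis import strategies as st

    ints = st.integers(min_value=-20, max_value=20)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(ints, ints)
    def check(ax, ay):
        if (ax, ay) == (0, 0):
            return
        a = pattern_angle((ax, ay))
        b = pattern_angle((-ay, ax))
        assert min(abs(a - b), 180 - abs(a - b)) == pytest.approx(90.0, abs=1e-9)

    check()


def test_design_table_is_complete(water):
    table = design_table(water)
    assert table["demagnification"] == pytest.approx(90.1, abs=0.05)
    assert set(table["orientation_angles_deg"]) == {
        "(2, -11)", "(14, -5)", "(13, 11)"
    }
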
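import numpy as np
import pytest

from simtools.optics import OpticalModel, make_beams


@pytest.fixture(scope="session")
def water():
    return OpticalModel.water()


@pytest.fixture(scope="session")
def silicone():
    return OpticalModel.silicone_oil()


@pytest.fixture(scope="session")
def beams3(water):
    return make_beams(water, 0.0)


@pytest.fixture(scope="session")
def beams4(water):
    return make_beams(water, 0.0, four_beam=True)


@pytest.fixture(scope="session")
def bead_stack_3beam(water):
    """Noiseless single-bead 5-phase stack (orientation 0) plus geometry."""
    from simtools.phantoms import AcquisitionConfig, simulate_bead_stack

    acq = AcquisitionConfig(
        modality="3-beam",
        z_step_nm=125.0,
        pixel_size_nm=80.0,
        noise=False,
        camera_offset=0.0,
    )
    stack = simulate_bead_stack(
        [(32.3, 32.1, 31.8)], water, acq, shape=(64, 64, 64), bead_diameter_nm=100.0
    )
    return {
        "stack": stack,
        "position": (32.3, 32.1, 31.8),
        "pixel_size_nm": 80.0,
        "z_step_nm": 125.0,
    }


@pytest.fixture(scope="session")
def dense_bead_scene(water):
    """Noiseless 3-orientation acquisition of a dense bead field at 64³."""
    from simtools.phantoms import (
        AcquisitionConfig,
        bead_volume,
        simulate_acquisition,
    )

    rng = np.random.default_rng(1)
    shape = (64, 64, 64)
    pos = [
        (rng.uniform(8, 56), rng.uniform(6, 58), rng.uniform(6, 58))
        for _ in range(60)
    ]
    vol = bead_volume(shape, pos, 100.0, 80.0, 125.0)
    acq = AcquisitionConfig(
        modality="3-beam",
        z_step_nm=125.0,
        pixel_size_nm=80.0,
        noise=False,
        camera_offset=0.0,
    )
    phases = (0.3, 0.0, -0.7)
    stack = simulate_acquisition(vol, water, acq, initial_phases=phases)
    return {"stack": stack, "volume": vol, "positions": pos, "phases": phases}


@pytest.fixture(scope="session")
def model_otfs_3beam(water, beams3):
    from simtools.otf import model_otfs

    return model_otfs(
        water, beams3, shape=(64, 64, 64), pixel_size_nm=80.0, z_step_nm=125.0
    )
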
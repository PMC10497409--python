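"""TIFF + JSON-sidecar interchange for raw stacks, OTFs and volumes.

Raw acquisitions travel as 32-bit multi-page TIFFs in XYPAZ page order
(phase fastest, then orientation, then z) with a JSON sidecar carrying the
:class:`StackHeader`; OTF sets are multi-page TIFFs with real/imaginary
parts interleaved per order.  Sidecars, not proprietary tags, keep every
file readable by standard tooling.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
from pydantic import BaseModel

from . import __version__
from .illumination import N_PHASES
from .otf import OTFSet
from .phantoms import RawSIMStack


class StackHeader(BaseModel):
    """Metadata of one raw acquisition file."""

    axis_order: str = "XYPAZ"
    n_phases: int = N_PHASES
    n_orientations: int = 3
    n_z: int = 0
    shape_yx: tuple[int, int] = (0, 0)
    pixel_size_nm: float = 80.0
    z_step_nm: float = 125.0
    modality: str = "3-beam"
    excitation_wavelength: float = 488.0
    emission_wavelength: float = 525.0
    camera_offset: float = 0.0
    orientation_angles: tuple[float, ...] = (10.3, 70.3, 130.2)
    seed: int | None = None
    software_version: str = ""

    def __init__(self, **kw):
        super().__init__(**kw)
        if self.n_phases != N_PHASES:
            raise ValueError("phases must be 5")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: RawSIMStack, path: str | Path) -> Path:
    """Write a RawSIMStack as XYPAZ multi-page TIFF + JSON sidecar."""
    path = Path(path)
    n_or, n_ph, nz, ny, nx = stack.data.shape
    header = StackHeader(
        n_orientations=n_or,
        n_z=nz,
        shape_yx=(ny, nx),
        pixel_size_nm=stack.pixel_size_nm,
        z_step_nm=stack.z_step_nm,
        modality=stack.modality,
        camera_offset=stack.camera_offset,
        orientation_angles=stack.orientation_angles,
        software_version=__version__,
    )
    # page order: phase fastest, then orientation, then z
    pages = np.transpose(stack.data, (2, 0, 1, 3, 4)).reshape(-1, ny, nx)
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps(header.model_dump(), indent=1))
    return path


def read_stack(
    path: str | Path,
    n_orientations: int | None = None,
    n_z: int | None = None,
) -> RawSIMStack:
    """Read an XYPAZ TIFF back into a RawSIMStack.

    The JSON sidecar is authoritative; a legacy file without one is
    accepted (with a warning) when explicit ``n_orientations``/``n_z``
    shape flags are supplied.  Declared counts that contradict the page
    count raise an error listing the conflict.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    side = _sidecar(path)
    if side.exists():
        header = StackHeader(**json.loads(side.read_text()))
    else:
        if n_orientations is None or n_z is None:
            raise ValueError(
                f"{path} has no sidecar; pass n_orientations and n_z explicitly"
            )
        warnings.warn(f"{path}: no sidecar; using explicit shape flags", stacklevel=2)
        header = StackHeader(
            n_orientations=n_orientations,
            n_z=n_z,
            shape_yx=pages.shape[-2:],
        )
    expected = header.n_z * header.n_orientations * header.n_phases
    if pages.shape[0] != expected:
        raise ValueError(
            f"{path}: header declares {header.n_z}·{header.n_orientations}·"
            f"{header.n_phases} = {expected} pages but the file holds "
            f"{pages.shape[0]}"
        )
    ny, nx = pages.shape[-2:]
    data = pages.reshape(header.n_z, header.n_orientations, header.n_phases, ny, nx)
    data = np.transpose(data, (1, 2, 0, 3, 4))
    return RawSIMStack(
        data=np.ascontiguousarray(data),
        pixel_size_nm=header.pixel_size_nm,
        z_step_nm=header.z_step_nm,
        modality=header.modality,
        camera_offset=header.camera_offset,
        orientation_angles=tuple(header.orientation_angles),
    )


def write_otf(otfs: OTFSet, path: str | Path) -> Path:
    """Write an OTFSet: pages = (order 0 re, order 0 im, order 1 re, ...)."""
    path = Path(path)
    pages = []
    for m in sorted(otfs.orders):
        pages.append(otfs.orders[m].real.astype(np.float32))
        pages.append(otfs.orders[m].imag.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    meta = {
        "orders": sorted(int(m) for m in otfs.orders),
        "kr": otfs.kr.tolist(),
        "kz": otfs.kz.tolist(),
        "modality": otfs.modality,
        "excitation_wavelength": otfs.excitation_wavelength,
        "emission_wavelength": otfs.emission_wavelength,
        "software_version": __version__,
    }
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_otf(path: str | Path) -> OTFSet:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    orders = {}
    for i, m in enumerate(meta["orders"]):
        orders[m] = pages[2 * i] + 1j * pages[2 * i + 1]
    return OTFSet(
        orders=orders,
        kr=np.asarray(meta["kr"]),
        kz=np.asarray(meta["kz"]),
        modality=meta["modality"],
        excitation_wavelength=meta["excitation_wavelength"],
        emission_wavelength=meta["emission_wavelength"],
    )


def write_volume(volume: np.ndarray, path: str | Path, **meta) -> Path:
    """Write a (z, y, x) volume as 32-bit TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume, np.float32), photometric="minisblack")
    meta.setdefault("software_version", __version__)
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    vol = tifffile.imread(path)
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return vol, meta
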
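"""Bead-based axial phase and drift estimation for four-beam SIM.

Four-beam reconstruction requires the maxima of the axial interference
pattern to coincide with the detection focal plane; even a ~40-nm mismatch
produces axial ringing.  The alignment loop estimates two quantities from a
fine z-stack of a single 100-nm fiducial bead:

* **PSF offset** — the focal-plane position, from the symmetric minimum of
  the per-plane lateral FWHM curve;
* **SW peak** — the position of the standing-wave maximum nearest the PSF
  offset, from a 1-D Gaussian fit to the bead's axial intensity profile.

Their difference drives piezo feedback (stage for drift, mirror for the
pattern phase) until it falls below a set tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel
from scipy.optimize import curve_fit

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class AlignmentConfig(BaseModel):
    """Tunables of the bead-based alignment loop.

    The FWHM interpolation interval selects the defocus range used for the
    focal-plane estimate (300–500 nm suits the yellow-green channel;
    400–600 nm the red channel).
    """

    tolerance_nm: float = 10.0
    fwhm_interval_nm: tuple[float, float] = (300.0, 500.0)
    interpolation_points: int = 100
    crop_half_width_px: int = 25
    disk_radius_px: int = 3
    isolation_radius_px: int = 50
    max_iterations: int = 10

    def __init__(self, **kw):
        super().__init__(**kw)
        if self.tolerance_nm <= 0:
            raise ValueError("tolerance must be positive")
        if self.fwhm_interval_nm[1] <= self.fwhm_interval_nm[0]:
            raise ValueError("FWHM interval is empty")


@dataclass
class AlignmentState:
    """Trajectory of one feedback run."""

    psf_offset_nm: float
    sw_peak_nm: float
    difference_nm: float
    iterations: int
    converged: bool
    history: list = field(default_factory=list)


class NoIsolatedBeadError(ValueError):
    """No sufficiently bright and isolated fiducial bead was found."""


def _gauss2d(xy, amp, x0, y0, sx, sy, off):
    x, y = xy
    return (
        amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2)))
        + off
    )


def _fit_gauss2d(img: np.ndarray, fix_center: tuple[float, float] | None = None):
    """2D Gaussian fit; returns (amp, x0, y0, sx, sy, offset).

    With ``fix_center`` the center is held and only amplitude, widths and
    offset are fitted.  Initialization from image moments.
    """
    ny, nx = img.shape
    y, x = np.mgrid[0:ny, 0:nx]
    off0 = float(np.percentile(img, 10))
    w = np.clip(img - off0, 0, None)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("image has no signal above background")
    cx = float((w * x).sum() / tot)
    cy = float((w * y).sum() / tot)
    sx0 = math.sqrt(max(float((w * (x - cx) ** 2).sum() / tot), 0.25))
    sy0 = math.sqrt(max(float((w * (y - cy) ** 2).sum() / tot), 0.25))
    amp0 = float(img.max() - off0)
    xy = (x.ravel(), y.ravel())
    if fix_center is None:
        p0 = [amp0, cx, cy, sx0, sy0, off0]
        popt, _ = curve_fit(_gauss2d, xy, img.ravel(), p0=p0, maxfev=5000)
        return tuple(popt)
    fx, fy = fix_center

    def model(xy, amp, sx, sy, off):
        return _gauss2d(xy, amp, fx, fy, sx, sy, off)

    p0 = [amp0, sx0, sy0, off0]
    popt, _ = curve_fit(model, xy, img.ravel(), p0=p0, maxfev=5000)
    amp, sx, sy, off = popt
    return amp, fx, fy, sx, sy, off


def locate_fiducial(
    image: np.ndarray, cfg: AlignmentConfig | None = None
) -> tuple[tuple[int, int], tuple[float, float]]:
    """Find the brightest isolated bead; integer then sub-pixel center.

    ``image`` is a wide-field snap (2D) or stack (3D; the maximum-intensity
    projection is used).  A candidate is rejected when another candidate
    lies within the isolation radius.  The 50×50 crop around the winner is
    fitted with a 2D Gaussian for the sub-pixel center (x₁, y₁).
    Raises :class:`NoIsolatedBeadError` when nothing qualifies.
    """
    cfg = cfg or AlignmentConfig()
    img = np.asarray(image, float)
    if img.ndim == 3:
        img = img.max(axis=0)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise NoIsolatedBeadError("uniform image: no bead found")
    thresh = lo + 0.2 * (hi - lo)
    from scipy.ndimage import maximum_filter

    local_max = (img == maximum_filter(img, size=5)) & (img > thresh)
    cand = np.argwhere(local_max)
    if cand.size == 0:
        raise NoIsolatedBeadError("no local maximum above threshold")
    order = np.argsort(img[cand[:, 0], cand[:, 1]])[::-1]
    cand = cand[order]
    winner = None
    for i, (cy, cx) in enumerate(cand):
        d = np.hypot(cand[:, 0] - cy, cand[:, 1] - cx)
        d[i] = np.inf
        if np.all(d > cfg.isolation_radius_px):
            winner = (int(cy), int(cx))
            break
    if winner is None:
        raise NoIsolatedBeadError(
            "no bead isolated by the required radius "
            f"({cfg.isolation_radius_px} px)"
        )
    y0, x0 = winner
    h = cfg.crop_half_width_px
    ys, xs = max(y0 - h, 0), max(x0 - h, 0)
    crop = img[ys : y0 + h, xs : x0 + h]
    _, fx, fy, _, _, _ = _fit_gauss2d(crop)
    return (x0, y0), (xs + fx, ys + fy)


def _crop_stack(stack: np.ndarray, center_xy: tuple[float, float], half: int):
    x1, y1 = center_xy
    xi, yi = int(round(x1)), int(round(y1))
    nz, ny, nx = stack.shape
    ys, ye = max(yi - half, 0), min(yi + half, ny)
    xs, xe = max(xi - half, 0), min(xi + half, nx)
    return stack[:, ys:ye, xs:xe], (x1 - xs, y1 - ys)


def psf_offset(
    stack: np.ndarray,
    center_xy: tuple[float, float],
    z_step_nm: float,
    pixel_size_nm: float = 80.0,
    cfg: AlignmentConfig | None = None,
) -> float:
    """Focal-plane position (nm, relative to the stack center).

    Each lateral plane of the 50×50 crop is fitted with a 2D Gaussian with
    fixed center; the mean of FWHM(x) and FWHM(y) forms a defocus curve
    whose two branches are resampled at 100 evenly spaced FWHM values
    within the configured interval; the unweighted mean of the resampled
    axial positions is the focal plane (exact for a symmetric curve).
    """
    cfg = cfg or AlignmentConfig()
    crop, (fx, fy) = _crop_stack(stack, center_xy, cfg.crop_half_width_px)
    nz = crop.shape[0]
    z_nm = (np.arange(nz) - nz // 2) * z_step_nm
    fwhm = np.full(nz, np.nan)
    for iz in range(nz):
        try:
            _, _, _, sx, sy, _ = _fit_gauss2d(crop[iz], fix_center=(fx, fy))
        except (RuntimeError, ValueError):
            continue
        fwhm[iz] = 0.5 * (abs(sx) + abs(sy)) * FWHM_FACTOR * pixel_size_nm
    lo, hi = cfg.fwhm_interval_nm
    good = np.isfinite(fwhm)
    if good.sum() < 3:
        raise ValueError("too few usable planes for the focus estimate")
    # 3-plane moving average: per-plane width estimates jitter at low
    # photon counts and the branch inversion below keeps only running
    # maxima, so unsmoothed noise feeds straight into the focus estimate.
    k = 3
    sm = np.convolve(
        np.pad(fwhm[good], (k // 2, k // 2), mode="edge"), np.ones(k) / k, "valid"
    )
    fwhm[good] = sm
    imin = int(np.nanargmin(np.where(good, fwhm, np.inf)))
    branches = []
    for branch in (slice(imin, None, -1), slice(imin, None, 1)):
        f = fwhm[branch]
        z = z_nm[branch]
        ok = np.isfinite(f)
        f, z = f[ok], z[ok]
        if f.size < 2:
            continue
        branches.append((np.maximum.accumulate(f), z))
    if not branches:
        raise ValueError("defocus curve has no usable branches")
    # Sample both branches at the *same* FWHM values so that, for a
    # symmetric defocus curve, paired positions average exactly to the
    # focal plane; per-branch sampling ranges would bias the mean.
    blo = max([lo] + [float(f.min()) for f, _ in branches])
    bhi = min([hi] + [float(f.max()) for f, _ in branches])
    if bhi <= blo:
        raise ValueError(
            "no plane has FWHM inside the configured interval "
            f"[{lo:.0f}, {hi:.0f}] nm"
        )
    samples = np.linspace(blo, bhi, cfg.interpolation_points)
    positions = [np.interp(samples, f, z) for f, z in branches]
    return float(np.mean(np.concatenate(positions)))


def sw_peak(
    stack: np.ndarray,
    center_xy: tuple[float, float],
    psf_offset_nm: float,
    z_step_nm: float,
    cfg: AlignmentConfig | None = None,
    sw_period_nm: float = 183.0,
) -> float:
    """Position (nm) of the axial pattern maximum nearest the PSF offset.

    The axial profile sums each plane over a 3-px-radius disk at the bead
    center; the local maximum nearest ``psf_offset_nm`` seeds a 1-D
    Gaussian fit whose center is returned.  A contrast statistic below 5%
    triggers a low-modulation warning (e.g. 3-beam data).
    """
    cfg = cfg or AlignmentConfig()
    nz, ny, nx = stack.shape
    x1, y1 = center_xy
    y, x = np.mgrid[0:ny, 0:nx]
    disk = (x - x1) ** 2 + (y - y1) ** 2 <= cfg.disk_radius_px**2
    profile = stack[:, disk].sum(axis=1).astype(float)
    z_nm = (np.arange(nz) - nz // 2) * z_step_nm

    interior = profile[1:-1]
    is_max = (interior >= profile[:-2]) & (interior >= profile[2:])
    peaks = np.nonzero(is_max)[0] + 1
    # Keep maxima that stand above the local background.
    strong = peaks[profile[peaks] > profile.min() + 0.1 * (profile.max() - profile.min())]
    if strong.size == 0:
        raise ValueError("no axial local maximum found")
    # Oscillation check around the focal region: subtract a moving average
    # over one standing-wave period so the smooth defocus envelope does
    # not masquerade as modulation (3-beam stacks have the envelope only).
    half = max(int(round(600.0 / z_step_nm)), 3)
    c0 = int(np.argmin(np.abs(z_nm - psf_offset_nm)))
    seg = profile[max(c0 - half, 0) : c0 + half + 1]
    w_period = max(int(round(sw_period_nm / z_step_nm)), 2)
    from scipy.ndimage import uniform_filter1d

    resid = seg - uniform_filter1d(seg, w_period, mode="nearest")
    osc = resid.std() / (seg.max() + 1e-30)
    if osc < 0.02:
        warnings.warn(
            "axial modulation contrast is low; standing-wave peak estimate "
            "is unreliable (3-beam data?)",
            stacklevel=2,
        )
    ipk = strong[np.argmin(np.abs(z_nm[strong] - psf_offset_nm))]
    w = max(2, int(round(0.35 * (sw_period_nm / z_step_nm))))
    s = slice(max(ipk - w, 0), min(ipk + w + 1, nz))
    zz, yyv = z_nm[s], profile[s]

    def g(z, amp, z0, sig, off):
        return amp * np.exp(-((z - z0) ** 2) / (2 * sig**2)) + off

    p0 = [float(yyv.max() - yyv.min()), float(z_nm[ipk]), 2.0 * z_step_nm, float(yyv.min())]
    try:
        popt, _ = curve_fit(g, zz, yyv, p0=p0, maxfev=5000)
        return float(popt[1])
    except RuntimeError:
        return float(z_nm[ipk])


def align_feedback(simulator, cfg: AlignmentConfig | None = None) -> AlignmentState:
    """Closed-loop alignment against a simulator with piezo actuators.

    Iterates acquire → estimate → correct: the stage absorbs the PSF
    offset (drift), the mirror absorbs the PSF-offset/SW-peak difference
    (pattern phase), until |difference| ≤ tolerance or the iteration limit
    is reached (then ``converged`` is False, no exception).
    """
    cfg = cfg or AlignmentConfig()
    history = []
    po = sw = diff = float("nan")
    model = simulator.model
    period = model.excitation_wavelength / (2.0 * model.refractive_index)
    for it in range(1, cfg.max_iterations + 1):
        phases = simulator.acquire()
        wf = phases.sum(axis=0)
        _, sub = locate_fiducial(wf, cfg)
        po = psf_offset(wf, sub, simulator.z_step_nm, simulator.pixel_size_nm, cfg)
        sw = sw_peak(wf, sub, po, simulator.z_step_nm, cfg, sw_period_nm=period)
        diff = sw - po
        history.append(
            {"iteration": it, "psf_offset": po, "sw_peak": sw, "difference": diff}
        )
        if abs(diff) <= cfg.tolerance_nm:
            return AlignmentState(po, sw, diff, it, True, history)
        simulator.move_stage(-po)
        simulator.move_mirror(diff)
    return AlignmentState(po, sw, diff, cfg.max_iterations, False, history)
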
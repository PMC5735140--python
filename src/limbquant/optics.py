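"""PSF characterization from bead stacks and signal-to-noise QC.

The point spread function is estimated per bead by least-squares
fitting an axially symmetric 3D Gaussian plus constant background;
resolution is reported as FWHM = 2*sqrt(2 ln 2) * sigma per axis, with
the lateral value shared between x and y (the endoscopic optics are
rotationally symmetric about the optical axis).  The signal-to-noise
ratio is defined as foreground mean divided by background standard
deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .containers import TimeLapseVolume
from .synth._render import FWHM_PER_SIGMA

logger = logging.getLogger(__name__)


@dataclass
class BeadFit:
    """A single bead's fitted PSF parameters (all lengths in µm)."""

    centroid: tuple[float, float, float]  # (x, y, z)
    fwhm_lateral: float
    fwhm_axial: float
    amplitude: float
    background: float
    residual_rms: float

    def __post_init__(self):
        if self.fwhm_lateral <= 0 or self.fwhm_axial <= 0:
            raise ValueError("FWHM values must be strictly positive")
        if self.residual_rms < 0:
            raise ValueError("residual must be non-negative")


@dataclass
class PSFEstimate:
    """Aggregate resolution estimate over accepted bead fits."""

    n_beads: int
    fwhm_lateral_mean: float
    fwhm_lateral_sd: float
    fwhm_axial_mean: float
    fwhm_axial_sd: float
    depth_range: tuple[float, float]  # µm, min/max bead z


@dataclass
class SNRReport:
    foreground_mean: float
    background_sd: float

    @property
    def snr(self) -> float:
        return self.foreground_mean / self.background_sd


class FitRejected(RuntimeError):
    """Raised when a bead fit fails its quality gates."""


def detect_beads(
    stack: TimeLapseVolume,
    min_separation: float = 3.0,
    intensity_percentile: float = 99.5,
) -> np.ndarray:
    """Find candidate bead centroids in a single-frame 3D stack.

    Local maxima above the given intensity percentile are non-maximum
    suppressed at ``min_separation`` µm (brightest kept), then refined
    to sub-voxel precision by centre of mass over a 3x3x3
    neighbourhood.  Returns an ``(n, 3)`` array of ``(x, y, z)`` µm.
    """
    data = np.asarray(stack.frame(0), dtype=float)
    if data.size == 0 or np.ptp(data) == 0:
        return np.empty((0, 3))
    vx, vy, vz = stack.voxel_size
    # the percentile alone can land inside the noise floor when beads are
    # sparse; guard with a robust (median + 6 MAD) noise estimate
    med = float(np.median(data))
    mad = float(np.median(np.abs(data - med)))
    threshold = max(
        np.percentile(data, intensity_percentile), med + 6.0 * 1.4826 * mad
    )
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = data == ndimage.maximum_filter(data, footprint=footprint, mode="nearest")
    cand = np.argwhere(local_max & (data > threshold))
    if len(cand) == 0:
        return np.empty((0, 3))
    # flag saturated plateaus wider than the suppression radius
    plateau = local_max & (data >= data.max())
    if plateau.sum() > 1:
        idx = np.argwhere(plateau)
        span = (idx.max(axis=0) - idx.min(axis=0)) * np.array([vz, vy, vx])
        if np.any(span > min_separation):
            logger.warning(
                "saturated plateau wider than min_separation (%.1f µm); "
                "centroids there are unreliable",
                min_separation,
            )
    order = np.argsort(data[tuple(cand.T)])[::-1]
    cand = cand[order]
    scale = np.array([vz, vy, vx])
    kept: list[np.ndarray] = []
    for c in cand:
        pos = (c + 0.5) * scale
        if all(np.linalg.norm(pos - k) >= min_separation for k in kept):
            kept.append(pos)
    # sub-voxel refinement: centre of mass in a 3^3 neighbourhood
    out = []
    nz, ny, nx = data.shape
    for pos in kept:
        k, j, i = (pos / scale - 0.5).round().astype(int)
        k0, k1 = max(k - 1, 0), min(k + 2, nz)
        j0, j1 = max(j - 1, 0), min(j + 2, ny)
        i0, i1 = max(i - 1, 0), min(i + 2, nx)
        block = data[k0:k1, j0:j1, i0:i1]
        block = block - block.min()
        if block.sum() <= 0:
            com = np.array([k, j, i], dtype=float)
        else:
            com = np.array(ndimage.center_of_mass(block)) + np.array([k0, j0, i0])
        zc, yc, xc = (com + 0.5) * scale
        out.append((xc, yc, zc))
    return np.array(out) if out else np.empty((0, 3))


def _gauss3d(coords, amp, bg, x0, y0, z0, s_lat, s_ax):
    z, y, x = coords
    return bg + amp * np.exp(
        -((x - x0) ** 2 + (y - y0) ** 2) / (2 * s_lat**2)
        - ((z - z0) ** 2) / (2 * s_ax**2)
    )


def fit_bead(
    stack: TimeLapseVolume,
    centroid,
    window: tuple[float, float] = (2.5, 13.0),
    *,
    max_residual_frac: float = 0.2,
    max_centroid_shift_voxels: float = 1.0,
) -> BeadFit:
    """Least-squares fit of an axially symmetric 3D Gaussian to one bead.

    Parameters
    ----------
    stack : TimeLapseVolume
        Single-frame 3D bead stack.
    centroid : tuple
        Seed position ``(x, y, z)`` in µm (e.g. from :func:`detect_beads`).
    window : tuple
        Half-extent ``(lateral, axial)`` of the fit window, µm; must
        contain the full bead image.
    max_residual_frac, max_centroid_shift_voxels : float
        Quality gates: the fit is rejected when the residual RMS exceeds
        this fraction of the fitted amplitude, when the fitted centre
        moves more than this many voxels from the seed, or when a fitted
        FWHM reaches the window boundary.

    Raises
    ------
    FitRejected
        If the fit does not converge or fails a quality gate.
    """
    data = np.asarray(stack.frame(0), dtype=float)
    vx, vy, vz = stack.voxel_size
    cx, cy, cz = centroid
    nz, ny, nx = data.shape
    i0 = max(int((cx - window[0]) / vx), 0)
    i1 = min(int((cx + window[0]) / vx) + 1, nx)
    j0 = max(int((cy - window[0]) / vy), 0)
    j1 = min(int((cy + window[0]) / vy) + 1, ny)
    k0 = max(int((cz - window[1]) / vz), 0)
    k1 = min(int((cz + window[1]) / vz) + 1, nz)
    block = data[k0:k1, j0:j1, i0:i1]
    if block.size < 8:
        raise FitRejected("fit window contains too few voxels")
    zc = (np.arange(k0, k1) + 0.5) * vz
    yc = (np.arange(j0, j1) + 0.5) * vy
    xc = (np.arange(i0, i1) + 0.5) * vx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    coords = (Z.ravel(), Y.ravel(), X.ravel())
    values = block.ravel()

    bg0 = float(values.min())
    amp0 = float(values.max() - bg0)
    if amp0 <= 0:
        raise FitRejected("no signal above background in window")
    p0 = [amp0, bg0, cx, cy, cz, max(vx, 0.3), max(vz, 1.0)]
    lo = [0.0, -np.inf, xc[0], yc[0], zc[0], 1e-3, 1e-3]
    hi = [np.inf, np.inf, xc[-1], yc[-1], zc[-1], window[0], window[1]]
    try:
        popt, _ = optimize.curve_fit(
            _gauss3d, coords, values, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitRejected(f"fit did not converge: {exc}") from exc
    amp, bg, x0, y0, z0, s_lat, s_ax = popt
    resid = values - _gauss3d(coords, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if amp <= 0 or rms > max_residual_frac * amp:
        raise FitRejected(f"residual RMS {rms:.3g} exceeds {max_residual_frac:.0%} of amplitude")
    shift = np.abs(np.array([x0 - cx, y0 - cy, z0 - cz]) / np.array([vx, vy, vz]))
    if np.any(shift > max_centroid_shift_voxels):
        raise FitRejected("fitted centre drifted more than one voxel from the seed")
    fwhm_lat = float(FWHM_PER_SIGMA * s_lat)
    fwhm_ax = float(FWHM_PER_SIGMA * s_ax)
    if s_lat >= 0.98 * window[0] or s_ax >= 0.98 * window[1]:
        raise FitRejected("fitted width pinned at the window boundary")
    return BeadFit(
        centroid=(float(x0), float(y0), float(z0)),
        fwhm_lateral=fwhm_lat,
        fwhm_axial=fwhm_ax,
        amplitude=float(amp),
        background=float(bg),
        residual_rms=rms,
    )


def summarize_psf(fits: list[BeadFit]) -> PSFEstimate:
    """Mean and sample s.d. (n-1 denominator) of FWHM over accepted fits."""
    if len(fits) == 0:
        raise ValueError("summarize_psf requires at least one accepted fit")
    lat = np.array([f.fwhm_lateral for f in fits])
    ax = np.array([f.fwhm_axial for f in fits])
    depths = np.array([f.centroid[2] for f in fits])
    if len(fits) == 1:
        logger.warning("single bead fit: s.d. reported as 0")
        sd_lat = sd_ax = 0.0
    else:
        sd_lat = float(np.std(lat, ddof=1))
        sd_ax = float(np.std(ax, ddof=1))
    return PSFEstimate(
        n_beads=len(fits),
        fwhm_lateral_mean=float(lat.mean()),
        fwhm_lateral_sd=sd_lat,
        fwhm_axial_mean=float(ax.mean()),
        fwhm_axial_sd=sd_ax,
        depth_range=(float(depths.min()), float(depths.max())),
    )


def measure_psf(
    stack: TimeLapseVolume,
    min_separation: float = 3.0,
    intensity_percentile: float = 99.5,
    window: tuple[float, float] = (2.5, 13.0),
) -> tuple[PSFEstimate, list[BeadFit]]:
    """Detect, fit, and summarize beads in one call (rejected fits dropped)."""
    centroids = detect_beads(stack, min_separation, intensity_percentile)
    fits = []
    for c in centroids:
        try:
            fits.append(fit_bead(stack, c, window))
        except FitRejected as exc:
            logger.info("bead at %s rejected: %s", np.round(c, 2), exc)
    return summarize_psf(fits), fits


def compute_snr(
    stack: TimeLapseVolume,
    foreground_mask: np.ndarray,
    background_mask: np.ndarray | None = None,
    *,
    background_percentile: float = 20.0,
) -> SNRReport:
    """Signal-to-noise ratio: foreground mean over background s.d.

    If ``background_mask`` is omitted, background voxels are taken as
    those outside the foreground mask with intensity below the given
    percentile of the non-foreground voxels (a conservative estimate of
    the signal-free floor).
    """
    data = np.asarray(stack.frame(0), dtype=float)
    fg = np.asarray(foreground_mask, dtype=bool)
    if fg.shape != data.shape:
        raise ValueError("foreground mask shape must match the stack")
    if not fg.any():
        raise ValueError("foreground mask is empty")
    if background_mask is None:
        outside = ~fg
        if not outside.any():
            raise ValueError("no background voxels outside the foreground mask")
        cut = np.percentile(data[outside], background_percentile)
        bg = outside & (data <= cut)
    else:
        bg = np.asarray(background_mask, dtype=bool)
        if bg.shape != data.shape:
            raise ValueError("background mask shape must match the stack")
        if (bg & fg).any():
            raise ValueError("foreground and background masks must be disjoint")
    if not bg.any():
        raise ValueError("background mask is empty")
    sd = float(np.std(data[bg]))
    if sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    return SNRReport(foreground_mean=float(data[fg].mean()), background_sd=sd)
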
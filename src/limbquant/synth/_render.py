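"""Voxel rendering primitives and the image-formation model.

Shapes are voxelized with the centre-inside convention.  The imaging
model is: binary label field -> scaled signal + background -> separable
anisotropic Gaussian PSF blur -> circular field-of-view mask -> Poisson
shot noise -> additive Gaussian read noise.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from ..config import SceneConfig

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_PER_SIGMA


def render_ball(
    grid: np.ndarray, voxel_size, center, radius: float
) -> None:
    """OR a solid ball (µm coordinates) into a boolean ``(z, y, x)`` grid."""
    vx, vy, vz = voxel_size
    cx, cy, cz = center
    nz, ny, nx = grid.shape
    i0 = max(int((cx - radius) / vx) - 1, 0)
    i1 = min(int((cx + radius) / vx) + 2, nx)
    j0 = max(int((cy - radius) / vy) - 1, 0)
    j1 = min(int((cy + radius) / vy) + 2, ny)
    k0 = max(int((cz - radius) / vz) - 1, 0)
    k1 = min(int((cz + radius) / vz) + 2, nz)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return
    xs = (np.arange(i0, i1) + 0.5) * vx - cx
    ys = (np.arange(j0, j1) + 0.5) * vy - cy
    zs = (np.arange(k0, k1) + 0.5) * vz - cz
    d2 = (
        zs[:, None, None] ** 2
        + ys[None, :, None] ** 2
        + xs[None, None, :] ** 2
    )
    grid[k0:k1, j0:j1, i0:i1] |= d2 <= radius * radius


def _render_capsule(grid, voxel_size, a, b, radius):
    """OR a capsule (cylinder with hemispherical caps) from ``a`` to ``b``."""
    vx, vy, vz = voxel_size
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    length = float(np.linalg.norm(ab))
    if length == 0.0:
        render_ball(grid, voxel_size, a, radius)
        return
    u = ab / length
    nz, ny, nx = grid.shape
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    i0 = max(int(lo[0] / vx) - 1, 0)
    i1 = min(int(hi[0] / vx) + 2, nx)
    j0 = max(int(lo[1] / vy) - 1, 0)
    j1 = min(int(hi[1] / vy) + 2, ny)
    k0 = max(int(lo[2] / vz) - 1, 0)
    k1 = min(int(hi[2] / vz) + 2, nz)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return
    xs = (np.arange(i0, i1) + 0.5) * vx - a[0]
    ys = (np.arange(j0, j1) + 0.5) * vy - a[1]
    zs = (np.arange(k0, k1) + 0.5) * vz - a[2]
    # axial coordinate t (clamped to the segment) and squared distance
    t = (
        zs[:, None, None] * u[2]
        + ys[None, :, None] * u[1]
        + xs[None, None, :] * u[0]
    )
    tc = np.clip(t, 0.0, length)
    p2 = zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
    d2 = p2 - 2.0 * t * tc + tc**2
    grid[k0:k1, j0:j1, i0:i1] |= d2 <= radius * radius


def _carve_end(grid, voxel_size, center, outward, radius):
    """Clear the hemisphere beyond the flat end cap at ``center``."""
    vx, vy, vz = voxel_size
    c = np.asarray(center, dtype=float)
    u = np.asarray(outward, dtype=float)
    u = u / np.linalg.norm(u)
    nz, ny, nx = grid.shape
    i0 = max(int((c[0] - radius) / vx) - 1, 0)
    i1 = min(int((c[0] + radius) / vx) + 2, nx)
    j0 = max(int((c[1] - radius) / vy) - 1, 0)
    j1 = min(int((c[1] + radius) / vy) + 2, ny)
    k0 = max(int((c[2] - radius) / vz) - 1, 0)
    k1 = min(int((c[2] + radius) / vz) + 2, nz)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return
    xs = (np.arange(i0, i1) + 0.5) * vx - c[0]
    ys = (np.arange(j0, j1) + 0.5) * vy - c[1]
    zs = (np.arange(k0, k1) + 0.5) * vz - c[2]
    d2 = zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
    t = (
        zs[:, None, None] * u[2]
        + ys[None, :, None] * u[1]
        + xs[None, None, :] * u[0]
    )
    grid[k0:k1, j0:j1, i0:i1] &= ~((d2 <= radius * radius) & (t > 0.0))


def render_tube(
    shape, voxel_size, polyline, diameter: float, grid: np.ndarray | None = None
) -> np.ndarray:
    """Voxelize a tube of constant ``diameter`` around a centreline.

    Segments are rendered as capsules, so bends are smoothly bridged by
    spherical joints; the two tube ends are then carved flat.  A single
    straight segment of length ``L`` therefore encloses a volume of
    ``pi * (d/2)**2 * L`` exactly (up to voxelization).  Note the flat
    carve at an end also trims any joint sphere closer than one radius
    to that end, so centreline vertices should keep at least one radius
    of arc length from the endpoints.

    Parameters
    ----------
    shape : tuple
        Grid shape ``(z, y, x)``.
    voxel_size : tuple
        Voxel size ``(x, y, z)``, µm.
    polyline : array-like, shape (n, 3)
        Centreline vertices ``(x, y, z)`` in µm.
    diameter : float
        Tube diameter, µm.
    grid : ndarray of bool, optional
        Existing grid to OR into; a new one is allocated if omitted.
        The flat-end carve only applies cleanly to a fresh grid.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("polyline must be an (n >= 2, 3) array of (x, y, z) µm points")
    if diameter <= 0:
        raise ValueError("diameter must be strictly positive")
    if grid is None:
        grid = np.zeros(shape, dtype=bool)
    radius = diameter / 2.0
    for a, b in zip(pts[:-1], pts[1:]):
        _render_capsule(grid, voxel_size, a, b, radius)
    head_dir = pts[0] - pts[1]
    tail_dir = pts[-1] - pts[-2]
    _carve_end(grid, voxel_size, pts[0], head_dir, radius)
    _carve_end(grid, voxel_size, pts[-1], tail_dir, radius)
    return grid


def fov_mask(shape, voxel_size, fov_diameter: float) -> np.ndarray:
    """Boolean ``(y, x)`` mask of the circular endoscopic field of view,
    centred in the lateral plane."""
    _, ny, nx = shape
    vx, vy, _ = voxel_size
    cy = ny * vy / 2.0
    cx = nx * vx / 2.0
    ys = (np.arange(ny) + 0.5) * vy - cy
    xs = (np.arange(nx) + 0.5) * vx - cx
    r2 = ys[:, None] ** 2 + xs[None, :] ** 2
    return r2 <= (fov_diameter / 2.0) ** 2


def apply_psf(field: np.ndarray, voxel_size, psf_fwhm) -> np.ndarray:
    """Blur a ``(z, y, x)`` field with a separable anisotropic Gaussian PSF."""
    vx, vy, vz = voxel_size
    s_lat = fwhm_to_sigma(psf_fwhm[0])
    s_ax = fwhm_to_sigma(psf_fwhm[1])
    sigmas = (s_ax / vz, s_lat / vy, s_lat / vx)
    return ndimage.gaussian_filter(field.astype(np.float64), sigma=sigmas)


def apply_noise(
    field: np.ndarray, rng: np.random.Generator, read_noise_sd: float
) -> np.ndarray:
    """Poisson shot noise on the expected counts plus Gaussian read noise."""
    counts = rng.poisson(np.clip(field, 0.0, None)).astype(np.float64)
    if read_noise_sd > 0:
        counts += rng.normal(0.0, read_noise_sd, size=field.shape)
    return counts


def signal_amplitude(config: SceneConfig) -> float:
    """Signal amplitude (counts) that realizes ``snr_target``.

    With background level ``b`` and read noise ``r`` the background
    standard deviation is ``sqrt(b + r**2)`` (Poisson + read), so the
    foreground mean ``A + b`` hits the target when
    ``A = snr_target * sqrt(b + r**2) - b``.
    """
    bg_sd = math.sqrt(config.background + config.read_noise_sd**2)
    amp = config.snr_target * bg_sd - config.background
    if amp <= 0:
        raise ValueError("snr_target too low for the configured background")
    return amp


def form_image(
    labels: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
    *,
    degrade: bool = True,
) -> np.ndarray:
    """Run the full image-formation model on a binary ``(z, y, x)`` label field.

    With ``degrade=False`` the ideal (unblurred, noiseless,
    background-free) scaled label field is returned, restricted to the
    circular field of view.
    """
    amp = signal_amplitude(config)
    signal = labels.astype(np.float64) * amp
    mask = fov_mask(labels.shape, config.voxel_size, config.fov_diameter)
    if not degrade:
        return signal * mask[None, :, :]
    signal = apply_psf(signal, config.voxel_size, config.psf_fwhm)
    signal *= mask[None, :, :]
    expected = signal + config.background
    return apply_noise(expected, rng, config.read_noise_sd)
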
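"""Synthetic sub-resolution bead stacks for PSF characterization.

A 100 nm bead is far below the diffraction limit, so its image is the
point spread function itself: an anisotropic Gaussian of the configured
lateral/axial FWHM sampled at the voxel centres.  The default voxel
size is finer than the live-imaging rasters because PSF calibration
stacks are acquired at Nyquist-ish sampling in agarose, not in tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..config import SceneConfig, stage_rng
from ..containers import TimeLapseVolume
from . import _render

BEAD_VOXEL = (0.3, 0.3, 0.6)  # µm, calibration-stack sampling


@dataclass
class BeadFieldTruth:
    centroids: np.ndarray  # (n, 3) of (x, y, z) µm
    fwhm_lateral: float
    fwhm_axial: float
    amplitude: float
    background: float


def generate_bead_stack(
    n_beads: int = 23,
    *,
    extent: tuple[float, float, float] = (60.0, 60.0, 36.0),
    voxel_size: tuple[float, float, float] = BEAD_VOXEL,
    psf_fwhm: tuple[float, float] = (0.8, 5.2),
    amplitude: float = 1000.0,
    background: float = 10.0,
    min_separation: float = 6.0,
    noise: bool = False,
    read_noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[TimeLapseVolume, BeadFieldTruth]:
    """Render ``n_beads`` non-overlapping point sources imaged by the PSF.

    Bead positions are drawn uniformly with rejection sampling so that
    every pair is at least ``min_separation`` µm apart and each bead
    keeps a 3-sigma margin from the stack faces.  With ``noise=True``
    the stack carries Poisson shot noise plus Gaussian read noise.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be non-negative")
    rng = np.random.default_rng(seed)
    ex, ey, ez = extent
    s_lat = _render.fwhm_to_sigma(psf_fwhm[0])
    s_ax = _render.fwhm_to_sigma(psf_fwhm[1])
    margin = np.array([3 * s_lat, 3 * s_lat, 3 * s_ax]) + np.asarray(voxel_size)
    lo = margin
    hi = np.array([ex, ey, ez]) - margin
    if np.any(hi <= lo):
        raise ValueError("extent too small for the PSF margin")

    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_beads:
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 10000 * max(n_beads, 1):
            raise RuntimeError("could not place beads at the requested separation")
    centroids = np.array(centers) if centers else np.empty((0, 3))

    nz = int(round(ez / voxel_size[2]))
    ny = int(round(ey / voxel_size[1]))
    nx = int(round(ex / voxel_size[0]))
    field = np.full((nz, ny, nx), float(background))
    zc = (np.arange(nz) + 0.5) * voxel_size[2]
    yc = (np.arange(ny) + 0.5) * voxel_size[1]
    xc = (np.arange(nx) + 0.5) * voxel_size[0]
    for cx, cy, cz in centroids:
        # local window of +/- 4 sigma per axis
        wi = int(np.ceil(4 * s_lat / voxel_size[0]))
        wj = int(np.ceil(4 * s_lat / voxel_size[1]))
        wk = int(np.ceil(4 * s_ax / voxel_size[2]))
        i = int(cx / voxel_size[0])
        j = int(cy / voxel_size[1])
        k = int(cz / voxel_size[2])
        i0, i1 = max(i - wi, 0), min(i + wi + 1, nx)
        j0, j1 = max(j - wj, 0), min(j + wj + 1, ny)
        k0, k1 = max(k - wk, 0), min(k + wk + 1, nz)
        gx = np.exp(-((xc[i0:i1] - cx) ** 2) / (2 * s_lat**2))
        gy = np.exp(-((yc[j0:j1] - cy) ** 2) / (2 * s_lat**2))
        gz = np.exp(-((zc[k0:k1] - cz) ** 2) / (2 * s_ax**2))
        field[k0:k1, j0:j1, i0:i1] += (
            amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    if noise:
        field = _render.apply_noise(field, rng, read_noise_sd)

    stack = TimeLapseVolume(
        data=field.astype(np.float32),
        voxel_size=tuple(voxel_size),
        channel="beads",
    )
    truth = BeadFieldTruth(
        centroids=centroids,
        fwhm_lateral=float(psf_fwhm[0]),
        fwhm_axial=float(psf_fwhm[1]),
        amplitude=float(amplitude),
        background=float(background),
    )
    return stack, truth
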
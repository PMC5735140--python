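"""Synthetic µCT phantoms: two cortical walls and simple digital solids.

The cortical phantom reproduces the measurement geometry used for bone
thickness: a line crossing the two cortices of a long-bone shaft sees
an intensity profile that is the sum of two Gaussian peaks, one per
wall, whose full widths at half maximum are the wall thicknesses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _render

DEFAULT_CT_VOXEL = 10.5  # µm, isotropic


@dataclass
class CTPhantomTruth:
    wall_fwhm: tuple[float, float]  # µm
    wall_centers: tuple[float, float]  # µm along x
    amplitudes: tuple[float, float]
    voxel: float
    noise_sd: float


def generate_ct_phantom(
    wall_thicknesses: tuple[float, float] = (200.0, 250.0),
    wall_separation: float = 1500.0,
    voxel: float = DEFAULT_CT_VOXEL,
    noise_sd: float = 0.0,
    *,
    amplitudes: tuple[float, float] = (1000.0, 800.0),
    cross_section: int = 24,
    seed: int = 0,
) -> tuple[np.ndarray, CTPhantomTruth]:
    """Generate an isotropic µCT grid containing two parallel cortical walls.

    The walls are perpendicular to ``x``; every line along ``x`` sees
    ``A1 * G(x; c1, w1) + A2 * G(x; c2, w2)`` where ``G`` is a Gaussian
    of FWHM ``w`` and the centres are ``wall_separation`` apart.

    Parameters
    ----------
    wall_thicknesses : tuple
        FWHM of the two walls, µm.
    wall_separation : float
        Centre-to-centre distance of the walls, µm; must exceed the sum
        of the thicknesses so the walls are resolvable.
    voxel : float
        Isotropic voxel size, µm; refused if coarser than half the
        thinnest wall (unsampleable profile).
    noise_sd : float
        Additive Gaussian noise s.d. (intensity units).

    Returns
    -------
    (ndarray, CTPhantomTruth)
        A ``(z, y, x)`` float grid and the generating parameters.
    """
    w1, w2 = wall_thicknesses
    if w1 <= 0 or w2 <= 0:
        raise ValueError("wall thicknesses must be strictly positive")
    if wall_separation <= w1 + w2:
        raise ValueError("wall_separation must exceed the sum of wall thicknesses")
    if voxel > min(w1, w2) / 2.0:
        raise ValueError(
            f"voxel {voxel} µm too coarse for the thinnest wall "
            f"{min(w1, w2)} µm (need voxel <= thickness / 2)"
        )
    margin = 2.0 * (w1 + w2)
    nx = int(round((wall_separation + 2 * margin) / voxel))
    c1 = margin
    c2 = margin + wall_separation
    s1 = _render.fwhm_to_sigma(w1)
    s2 = _render.fwhm_to_sigma(w2)
    x = (np.arange(nx) + 0.5) * voxel
    profile = amplitudes[0] * np.exp(-((x - c1) ** 2) / (2 * s1**2)) + amplitudes[
        1
    ] * np.exp(-((x - c2) ** 2) / (2 * s2**2))
    grid = np.broadcast_to(
        profile[None, None, :], (cross_section, cross_section, nx)
    ).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
    truth = CTPhantomTruth(
        wall_fwhm=(float(w1), float(w2)),
        wall_centers=(float(c1), float(c2)),
        amplitudes=tuple(float(a) for a in amplitudes),
        voxel=float(voxel),
        noise_sd=float(noise_sd),
    )
    return grid.astype(np.float64), truth


def digital_cube(
    edge_voxels: int = 10, pad: int = 4, voxel: float = DEFAULT_CT_VOXEL
) -> np.ndarray:
    """A solid digital cube embedded in an empty grid (boolean mask).

    A cube of ``n³`` voxels has volume ``n³`` voxel volumes and surface
    ``6 n²`` voxel faces — the face-counting oracle for morphometry.
    """
    n = edge_voxels + 2 * pad
    grid = np.zeros((n, n, n), dtype=bool)
    grid[pad : pad + edge_voxels, pad : pad + edge_voxels, pad : pad + edge_voxels] = True
    return grid
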
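"""Scene configuration and deterministic seed fan-out.

The defaults mirror the acquisition geometry of a single-GRIN-lens
femoral microendoscope: a circular 280 µm field of view, 70 µm z-stacks
with a 6 µm z-step, 0.7 µm lateral pixels (350 µm scanned onto ~507
pixels), frames every 30 s over 45 min, and a point spread function of
0.8 µm FWHM laterally and 5.2 µm axially.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics, and noise settings shared by all generators.

    Attributes
    ----------
    fov_diameter : float
        Diameter of the circular endoscopic field of view, µm.
    volume_extent : tuple
        Physical extent ``(x, y, z)`` of the imaged volume, µm.
    voxel_size : tuple
        Voxel size ``(x, y, z)``, µm.
    frame_interval : float
        Time between frames, seconds.
    n_frames : int
        Number of frames in a time-lapse scene.
    psf_fwhm : tuple
        Point-spread-function FWHM ``(lateral, axial)``, µm.
    snr_target : float
        Desired foreground-mean / background-s.d. ratio; the generator
        scales the signal amplitude accordingly.
    background : float
        Mean background level in detector counts.
    read_noise_sd : float
        Standard deviation of the additive Gaussian read noise, counts.
    seed : int
        Master seed; identical config + seed gives bit-identical output.
    """

    fov_diameter: float = 280.0
    volume_extent: tuple[float, float, float] = (280.0, 280.0, 70.0)
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 6.0)
    frame_interval: float = 30.0
    n_frames: int = 90
    psf_fwhm: tuple[float, float] = (0.8, 5.2)
    snr_target: float = 10.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.volume_extent):
            raise ValueError("volume_extent must be strictly positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.fov_diameter <= 0:
            raise ValueError("fov_diameter must be strictly positive")
        if self.fov_diameter > min(self.volume_extent[0], self.volume_extent[1]) + 1e-9:
            raise ValueError("fov_diameter must not exceed the lateral volume extent")
        if self.frame_interval <= 0 or self.n_frames < 1:
            raise ValueError("frame_interval must be > 0 and n_frames >= 1")
        if any(f <= 0 for f in self.psf_fwhm):
            raise ValueError("psf_fwhm must be strictly positive")
        if self.snr_target <= 0:
            raise ValueError("snr_target must be strictly positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Voxel grid shape ``(z, y, x)``."""
        ex, ey, ez = self.volume_extent
        vx, vy, vz = self.voxel_size
        return (int(round(ez / vz)), int(round(ey / vy)), int(round(ex / vx)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key in ("volume_extent", "voxel_size", "psf_fwhm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def derive_seed(seed: int, label: str) -> int:
    """Derive a per-stage seed from a master seed and a stage label.

    Stable across processes and platforms (CRC32 of the label mixed into
    a :class:`numpy.random.SeedSequence`), so any stage can be rerun in
    isolation yet reproduce the pipeline run exactly.
    """
    tag = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for one named pipeline stage."""
    return np.random.default_rng(derive_seed(seed, label))
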
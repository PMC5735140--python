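"""Core in-memory containers shared by every pipeline stage.

All physical coordinates are micrometres with the origin at the stack
corner; ``z`` runs along the optical axis.  Arrays are indexed
``(z, y, x)`` (single volume) or ``(t, z, y, x)`` (time lapse), while
voxel sizes and point coordinates are always given in ``(x, y, z)``
order to match how acquisition metadata is written.  A voxel with index
``(k, j, i)`` has its centre at ``((i + 0.5) * vx, (j + 0.5) * vy,
(k + 0.5) * vz)``; a voxel belongs to a shape if its centre is inside
(half-open convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class StackMetadata:
    """Acquisition metadata that must accompany every stack on disk.

    Parameters
    ----------
    voxel_size : tuple of float
        Physical voxel size ``(x, y, z)`` in µm.  Mandatory: every
        downstream statistic is reported in physical units.
    channel_names : list of str
        Channel labels (e.g. ``["vessels"]``).
    frame_interval : float or None
        Time between frames, in the unit given by ``time_unit``.
    timestamps : list of float or None
        Per-frame acquisition times; must be strictly increasing.
    time_unit : str
        ``"s"`` for time-lapse movies, ``"h"`` for multi-session series.
    provenance : str
        Free-text acquisition note (instrument, seed, generator config).
    """

    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=lambda: ["channel0"])
    frame_interval: float | None = None
    timestamps: list[float] | None = None
    time_unit: str = "s"
    provenance: str = ""

    def __post_init__(self) -> None:
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.voxel_size = vs
        if self.timestamps is not None:
            ts = [float(t) for t in self.timestamps]
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("timestamps must be strictly increasing")
            self.timestamps = ts

    def to_dict(self) -> dict:
        return {
            "voxel_size_um": list(self.voxel_size),
            "channel_names": list(self.channel_names),
            "frame_interval": self.frame_interval,
            "timestamps": self.timestamps,
            "time_unit": self.time_unit,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StackMetadata":
        return cls(
            voxel_size=tuple(d["voxel_size_um"]),
            channel_names=list(d.get("channel_names", ["channel0"])),
            frame_interval=d.get("frame_interval"),
            timestamps=d.get("timestamps"),
            time_unit=d.get("time_unit", "s"),
            provenance=d.get("provenance", ""),
        )


@dataclass
class TimeLapseVolume:
    """A single-channel voxel grid, possibly with a time axis.

    ``data`` has shape ``(z, y, x)`` or ``(t, z, y, x)``.  Multi-channel
    scenes are represented as one :class:`TimeLapseVolume` per channel.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    timestamps: np.ndarray | None = None
    time_unit: str = "s"
    channel: str = "channel0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"data must be 3D (z,y,x) or 4D (t,z,y,x), got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be strictly positive")
        self.voxel_size = vs
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.data.ndim == 4 and len(self.timestamps) != self.data.shape[0]:
                raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    def frame(self, t: int) -> np.ndarray:
        """Return frame ``t`` as a 3D ``(z, y, x)`` array."""
        if self.data.ndim == 3:
            if t != 0:
                raise IndexError("single-volume stack has only frame 0")
            return self.data
        return self.data[t]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent ``(x, y, z)`` in µm."""
        nz, ny, nx = self.data.shape[-3:]
        vx, vy, vz = self.voxel_size
        return (nx * vx, ny * vy, nz * vz)

    def metadata(self, **extra) -> StackMetadata:
        return StackMetadata(
            voxel_size=self.voxel_size,
            channel_names=[self.channel],
            timestamps=None if self.timestamps is None else list(self.timestamps),
            time_unit=self.time_unit,
            **extra,
        )


def voxel_centers(shape: Sequence[int], voxel_size: Sequence[float]):
    """Open-grid physical coordinates of voxel centres.

    Returns ``(zc, yc, xc)`` broadcastable arrays (µm) for a ``(z, y, x)``
    shaped grid.
    """
    nz, ny, nx = shape
    vx, vy, vz = voxel_size
    zc = (np.arange(nz, dtype=float) + 0.5) * vz
    yc = (np.arange(ny, dtype=float) + 0.5) * vy
    xc = (np.arange(nx, dtype=float) + 0.5) * vx
    return (
        zc[:, None, None],
        yc[None, :, None],
        xc[None, None, :],
    )


def grid_shape(volume_extent: Sequence[float], voxel_size: Sequence[float]) -> tuple[int, int, int]:
    """Number of voxels ``(z, y, x)`` covering the physical extent ``(x, y, z)``."""
    ex, ey, ez = volume_extent
    vx, vy, vz = voxel_size
    return (int(round(ez / vz)), int(round(ey / vy)), int(round(ex / vx)))
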
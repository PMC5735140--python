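"""Synthetic photoactivation series with known decay and drift.

Emulates photoactivatable-GFP experiments: before activation the label
is dim (baseline only); two-photon activation of a rectangular ROI in
the centre of the field of view multiplies the ROI intensity by a
configurable fold increase, after which the signal decays exponentially
through protein turnover and through emigration of motile labelled
cells out of the region.  The implant keeps the imaging frame fixed, so
an optional per-session translation models (absent) positional drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..config import SceneConfig, stage_rng
from ..containers import TimeLapseVolume
from . import _render

DEFAULT_ROI_EXTENT = (75.0, 75.0, 30.0)  # µm, centred in the field of view
DEFAULT_SESSION_HOURS = (0.0, 12.0, 24.0, 36.0)


@dataclass
class PhotoactivationTruth:
    roi_slices: tuple[slice, slice, slice]  # (z, y, x) voxel slices
    roi_extent: tuple[float, float, float]
    fold_increase: float
    decay_rate: float  # per hour (turnover + emigration)
    baseline: float
    session_hours: tuple[float, ...]  # post-activation sessions
    pre_frame_index: int = 0


def _roi_slices(shape, voxel_size, roi_extent):
    nz, ny, nx = shape
    vx, vy, vz = voxel_size
    half = [roi_extent[0] / 2.0, roi_extent[1] / 2.0, roi_extent[2] / 2.0]
    cx, cy, cz = nx * vx / 2.0, ny * vy / 2.0, nz * vz / 2.0
    i0 = int(round((cx - half[0]) / vx))
    i1 = int(round((cx + half[0]) / vx))
    j0 = int(round((cy - half[1]) / vy))
    j1 = int(round((cy + half[1]) / vy))
    k0 = int(round((cz - half[2]) / vz))
    k1 = int(round((cz + half[2]) / vz))
    if i0 < 0 or j0 < 0 or k0 < 0 or i1 > nx or j1 > ny or k1 > nz:
        raise ValueError("ROI does not fit inside the volume")
    if i1 <= i0 or j1 <= j0 or k1 <= k0:
        raise ValueError("ROI collapses to zero voxels at this voxel size")
    return (slice(k0, k1), slice(j0, j1), slice(i0, i1))


def generate_photoactivation_scene(
    config: SceneConfig,
    roi_extent: tuple[float, float, float] = DEFAULT_ROI_EXTENT,
    fold_increase: float = 100.0,
    turnover_rate: float = np.log(2) / 24.0,
    emigration_rate: float = 0.0,
    *,
    session_hours: tuple[float, ...] = DEFAULT_SESSION_HOURS,
    degrade: bool = True,
) -> tuple[TimeLapseVolume, PhotoactivationTruth]:
    """Generate a pre-activation frame plus post-activation sessions.

    Frame 0 is the pre-activation baseline; frame ``i + 1`` is acquired
    ``session_hours[i]`` hours after activation, with ROI intensity
    ``baseline * fold_increase * exp(-(turnover + emigration) * t)``.
    ``turnover_rate`` and ``emigration_rate`` are per hour.  The default
    turnover (half-life 24 h) keeps the signal detectable through 36 h.

    Timestamps are in hours; the pre-activation frame is stamped 1 h
    before activation.
    """
    if fold_increase < 1.0:
        raise ValueError("fold_increase must be >= 1 (activation brightens the label)")
    if turnover_rate < 0 or emigration_rate < 0:
        raise ValueError("decay rates must be non-negative")
    hours = tuple(float(h) for h in session_hours)
    if any(b <= a for a, b in zip(hours, hours[1:])) or hours[0] < 0:
        raise ValueError("session_hours must be non-negative and strictly increasing")
    shape = config.grid_shape
    roi = _roi_slices(shape, config.voxel_size, roi_extent)
    rng = stage_rng(config.seed, "synth.photoact")
    baseline = config.background
    rate = turnover_rate + emigration_rate

    mask = _render.fov_mask(shape, config.voxel_size, config.fov_diameter)
    frames = []
    pre = np.full(shape, baseline, dtype=np.float64)
    frames.append(pre)
    for t in hours:
        f = np.full(shape, baseline, dtype=np.float64)
        f[roi] = baseline * fold_increase * np.exp(-rate * t)
        frames.append(f)
    out = []
    for f in frames:
        f = f * mask[None, :, :]
        if degrade:
            f = _render.apply_psf(f, config.voxel_size, config.psf_fwhm)
            f = _render.apply_noise(f, rng, config.read_noise_sd)
        out.append(f.astype(np.float32))

    timestamps = np.concatenate([[hours[0] - 1.0], hours])
    stack = TimeLapseVolume(
        data=np.stack(out),
        voxel_size=config.voxel_size,
        timestamps=timestamps,
        time_unit="h",
        channel="paGFP",
    )
    truth = PhotoactivationTruth(
        roi_slices=roi,
        roi_extent=tuple(roi_extent),
        fold_increase=float(fold_increase),
        decay_rate=float(rate),
        baseline=float(baseline),
        session_hours=hours,
    )
    return stack, truth
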
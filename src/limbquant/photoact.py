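"""ROI quantification of photoactivated fluorescence across sessions,
label-decay fitting, and positional-stability reporting.

The photoactivated region is a fixed axis-aligned box in stack
coordinates (the implant keeps the imaging frame fixed, so the ROI is
not tracked).  The label decays through protein turnover and through
emigration of motile labelled cells; a single-exponential model above
a fitted baseline captures the combined loss, and a two-component
variant is available for series where the two pools separate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import TimeLapseVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned box, µm: ``origin`` (x, y, z) corner + ``extent``."""

    origin: tuple[float, float, float]
    extent: tuple[float, float, float]

    def __post_init__(self):
        if any(e <= 0 for e in self.extent):
            raise ValueError("ROI extent must be strictly positive")

    @classmethod
    def centered(cls, volume_extent, extent=(75.0, 75.0, 30.0)) -> "ROI":
        """ROI of the given extent centred in the volume."""
        origin = tuple((v - e) / 2.0 for v, e in zip(volume_extent, extent))
        if any(o < 0 for o in origin):
            raise ValueError("ROI does not fit inside the volume")
        return cls(origin=origin, extent=tuple(extent))

    def slices(self, voxel_size) -> tuple[slice, slice, slice]:
        vx, vy, vz = voxel_size
        ox, oy, oz = self.origin
        ex, ey, ez = self.extent
        i0, i1 = int(round(ox / vx)), int(round((ox + ex) / vx))
        j0, j1 = int(round(oy / vy)), int(round((oy + ey) / vy))
        k0, k1 = int(round(oz / vz)), int(round((oz + ez) / vz))
        return (slice(k0, k1), slice(j0, j1), slice(i0, i1))


@dataclass
class PhotoactSeries:
    """Per-session ROI quantification of a photoactivation experiment."""

    roi: ROI
    table: pd.DataFrame  # columns: time_h, mean_intensity, volume_um3, cx, cy, cz
    signal_threshold: float

    @property
    def times(self) -> np.ndarray:
        return self.table["time_h"].to_numpy()

    @property
    def means(self) -> np.ndarray:
        return self.table["mean_intensity"].to_numpy()


@dataclass
class DecayFit:
    amplitude: float
    baseline: float
    rate_per_h: float

    @property
    def half_life_h(self) -> float:
        return math.inf if self.rate_per_h <= 0 else math.log(2.0) / self.rate_per_h


@dataclass
class StabilityReport:
    """Per-session centroid drift and signal persistence."""

    drift_um: np.ndarray  # per session, Euclidean distance from session 0
    max_drift_um: float
    persistence_horizon_h: float  # last time with above-threshold ROI volume
    within_tolerance: bool


def quantify_roi(
    stack: TimeLapseVolume,
    roi: ROI,
    signal_threshold: float | None = None,
) -> PhotoactSeries:
    """Quantify ROI mean intensity, fluorescent volume, and centroid per frame.

    ``signal_threshold`` separates "fluorescent" voxels from background
    inside the ROI; by default it is twice the global median of the
    first frame (the pre-activation baseline).  Sessions with no
    above-threshold voxel get volume 0 and an undefined (NaN) centroid.
    """
    if stack.timestamps is None:
        raise ValueError("quantify_roi requires per-frame timestamps")
    if stack.time_unit != "h":
        raise ValueError("photoactivation series timestamps must be in hours")
    vx, vy, vz = stack.voxel_size
    sl = roi.slices(stack.voxel_size)
    shape = stack.frame(0).shape
    if (
        sl[0].stop > shape[0]
        or sl[1].stop > shape[1]
        or sl[2].stop > shape[2]
        or min(s.start for s in sl) < 0
    ):
        raise ValueError("ROI does not fit inside the stack")
    if signal_threshold is None:
        signal_threshold = 2.0 * float(np.median(stack.frame(0)))
    vox_vol = vx * vy * vz
    rows = []
    for t in range(stack.n_frames):
        block = np.asarray(stack.frame(t), dtype=float)[sl]
        above = block > signal_threshold
        if above.any():
            w = np.where(above, block, 0.0)
            total = w.sum()
            kk, jj, ii = np.indices(block.shape)
            cz = (np.sum(kk * w) / total + sl[0].start + 0.5) * vz
            cy = (np.sum(jj * w) / total + sl[1].start + 0.5) * vy
            cx = (np.sum(ii * w) / total + sl[2].start + 0.5) * vx
        else:
            cx = cy = cz = np.nan
        rows.append(
            {
                "time_h": float(stack.timestamps[t]),
                "mean_intensity": float(block.mean()),
                "volume_um3": float(above.sum()) * vox_vol,
                "cx": cx,
                "cy": cy,
                "cz": cz,
            }
        )
    return PhotoactSeries(
        roi=roi, table=pd.DataFrame(rows), signal_threshold=float(signal_threshold)
    )


def activation_ratio(series: PhotoactSeries, pre_index: int = 0) -> float:
    """Ratio of the first post-activation ROI mean to the pre-activation mean."""
    means = series.means
    if len(means) < 2:
        raise ValueError("need a pre- and at least one post-activation session")
    if means[pre_index] <= 0:
        raise ValueError("pre-activation ROI mean must be positive")
    return float(means[pre_index + 1] / means[pre_index])


def _exp_model(t, amp, rate, baseline):
    return baseline + amp * np.exp(-rate * t)


def _exp2_model(t, a1, r1, a2, r2, baseline):
    return baseline + a1 * np.exp(-r1 * t) + a2 * np.exp(-r2 * t)


def fit_decay(
    series: PhotoactSeries,
    *,
    skip_pre: int = 1,
    two_component: bool = False,
) -> DecayFit | tuple[DecayFit, DecayFit]:
    """Least-squares fit of exponential decay above a fitted baseline.

    The first ``skip_pre`` sessions (the pre-activation frames) are
    excluded.  A non-decreasing series is reported with rate <= 0 and a
    warning rather than an error.  With ``two_component=True`` the sum
    of two exponentials is fitted and both components returned (fast
    first).
    """
    t = series.times[skip_pre:]
    y = series.means[skip_pre:]
    if len(t) < 3:
        raise ValueError("fit_decay needs at least 3 post-activation sessions")
    t = t - t[0]
    span = float(y.max() - y.min())
    if span == 0:
        logger.warning("constant series: decay rate 0")
        return DecayFit(amplitude=0.0, baseline=float(y[0]), rate_per_h=0.0)
    if y[-1] >= y[0]:
        logger.warning("series is non-decreasing; fitted rate will be <= 0")
    # crude rate guess from the endpoints
    rate0 = 0.05
    if y[0] > y[-1] > 0 and t[-1] > 0:
        hi = max(y[0] - y[-1], 1e-12)
        rate0 = max(1e-3, -math.log(max(y[-1] / y[0], 1e-6)) / t[-1])
    if not two_component:
        p0 = [span, rate0, float(y.min())]
        popt, _ = optimize.curve_fit(
            _exp_model,
            t,
            y,
            p0=p0,
            bounds=([0.0, -1.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        return DecayFit(amplitude=float(popt[0]), rate_per_h=float(popt[1]), baseline=float(popt[2]))
    p0 = [span / 2, rate0 * 3, span / 2, rate0 / 3, float(y.min())]
    popt, _ = optimize.curve_fit(
        _exp2_model,
        t,
        y,
        p0=p0,
        bounds=([0, 0, 0, 0, -np.inf], [np.inf] * 5),
        maxfev=40000,
    )
    a1, r1, a2, r2, baseline = popt
    comps = sorted([(r1, a1), (r2, a2)], reverse=True)
    return (
        DecayFit(amplitude=float(comps[0][1]), rate_per_h=float(comps[0][0]), baseline=float(baseline)),
        DecayFit(amplitude=float(comps[1][1]), rate_per_h=float(comps[1][0]), baseline=float(baseline)),
    )


def stability(
    series: PhotoactSeries,
    drift_tolerance: float = 10.0,
    *,
    skip_pre: int = 1,
) -> StabilityReport:
    """Positional stability of the photoactivated region.

    Per-session Euclidean centroid drift relative to the first
    post-activation session, a pass/fail against ``drift_tolerance``
    (µm), and the persistence horizon: the last timestamp with
    above-threshold fluorescent volume in the ROI.
    """
    tab = series.table.iloc[skip_pre:]
    cents = tab[["cx", "cy", "cz"]].to_numpy()
    times = tab["time_h"].to_numpy()
    vols = tab["volume_um3"].to_numpy()
    if len(tab) == 0 or not np.all(np.isfinite(cents[0])):
        raise ValueError("reference session has no defined centroid")
    drifts = np.full(len(tab), np.nan)
    for i, c in enumerate(cents):
        if np.all(np.isfinite(c)):
            drifts[i] = float(np.linalg.norm(c - cents[0]))
        else:
            logger.warning("session at %.1f h has no centroid; skipped", times[i])
    horizon = times[vols > 0][-1] if np.any(vols > 0) else times[0]
    max_drift = float(np.nanmax(drifts))
    return StabilityReport(
        drift_um=drifts,
        max_drift_um=max_drift,
        persistence_horizon_h=float(horizon),
        within_tolerance=bool(max_drift <= drift_tolerance),
    )
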
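"""Vessel segmentation, local diameter mapping, and the longitudinal
remodeling statistic.

The remodeling statistic for a vessel observed at two sessions is the
normalized volume change

    delta_norm = (V_appear + V_disappear) / V_t1

where ``V_appear`` is the volume present only at the later session,
``V_disappear`` the volume present only at the earlier one, and
``V_t1`` the vessel's total volume at the later session.  Vessels are
stratified by local diameter into small [5, 15), mid [15, 35) and
large [35, inf) µm classes, and class means are compared with a
one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .containers import TimeLapseVolume
from .synth._render import fwhm_to_sigma

logger = logging.getLogger(__name__)

DEFAULT_CLASS_EDGES = (5.0, 15.0, 35.0)
CLASS_NAMES = ("small", "mid", "large")

#: 26-connectivity in 3D
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VesselMask:
    """A binary vessel mask with physical voxel size and session time."""

    mask: np.ndarray  # boolean (z, y, x)
    voxel_size: tuple[float, float, float]
    session_hours: float = 0.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("vessel mask must be 3D (z, y, x)")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def volume(self) -> float:
        """Total foreground volume, µm³."""
        return float(self.mask.sum()) * self.voxel_volume


@dataclass
class VesselSnapshotPair:
    """Two registered session masks and their appearance/disappearance split."""

    mask_t0: VesselMask
    mask_t1: VesselMask
    shift_voxels: tuple[int, int, int] = (0, 0, 0)  # applied to t1 (z, y, x)

    @property
    def appearance(self) -> np.ndarray:
        """Voxels present at t1 but not t0."""
        return self.mask_t1.mask & ~self.mask_t0.mask

    @property
    def disappearance(self) -> np.ndarray:
        """Voxels present at t0 but not t1."""
        return self.mask_t0.mask & ~self.mask_t1.mask

    @property
    def union(self) -> np.ndarray:
        return self.mask_t0.mask | self.mask_t1.mask


@dataclass
class RemodelingRecord:
    """Per-vessel-component remodeling statistic."""

    component_id: int
    class_label: str | None
    median_diameter: float  # µm, at the later session
    volume_t1: float  # µm³
    volume_appear: float
    volume_disappear: float

    @property
    def delta_norm(self) -> float:
        """Normalized volume change (symmetric difference / V_t1)."""
        if self.volume_t1 <= 0:
            return np.nan
        return (self.volume_appear + self.volume_disappear) / self.volume_t1

    @property
    def delta_signed(self) -> float:
        """Signed variant: (V_appear - V_disappear) / V_t1."""
        if self.volume_t1 <= 0:
            return np.nan
        return (self.volume_appear - self.volume_disappear) / self.volume_t1

    @property
    def fully_disappeared(self) -> bool:
        return self.volume_t1 <= 0


def segment_vessels(
    stack: TimeLapseVolume,
    frame: int = 0,
    smoothing_fwhm: float = 2.0,
    threshold: float | None = None,
    min_component: float = 500.0,
) -> VesselMask:
    """Segment the vessel channel of one session.

    Gaussian smoothing (``smoothing_fwhm`` µm, anisotropy-aware), global
    Otsu threshold (or a fixed ``threshold``), removal of connected
    components smaller than ``min_component`` µm³, and filling of fully
    enclosed holes.
    """
    data = np.asarray(stack.frame(frame), dtype=float)
    vx, vy, vz = stack.voxel_size
    if smoothing_fwhm > 0:
        s = fwhm_to_sigma(smoothing_fwhm)
        data = ndimage.gaussian_filter(data, sigma=(s / vz, s / vy, s / vx))
    if np.ptp(data) == 0:
        logger.warning("constant stack: returning empty vessel mask")
        mask = np.zeros(data.shape, dtype=bool)
    else:
        thr = threshold_otsu(data) if threshold is None else threshold
        mask = data > thr
    if mask.any():
        lbl, n = ndimage.label(mask, structure=_STRUCT26)
        vox_vol = vx * vy * vz
        min_vox = int(np.ceil(min_component / vox_vol))
        counts = np.bincount(lbl.ravel())
        keep = np.flatnonzero(counts >= min_vox)
        keep = keep[keep != 0]
        mask = np.isin(lbl, keep)
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        logger.warning("vessel segmentation produced an all-background mask")
    ts = stack.timestamps[frame] if stack.timestamps is not None else 0.0
    hours = float(ts) if stack.time_unit == "h" else float(ts) / 3600.0
    return VesselMask(mask=mask, voxel_size=stack.voxel_size, session_hours=hours)


def local_diameter(mask: VesselMask) -> np.ndarray:
    """Local-thickness diameter map (µm) over the foreground.

    Per-voxel diameter is twice the Euclidean distance-to-background
    evaluated on the medial skeleton and propagated to every foreground
    voxel from its nearest skeleton point, honouring anisotropic voxel
    sizes in all distances.  Background voxels are NaN.  Structures
    thinner than one voxel are clamped to the voxel size (with a
    warning).
    """
    m = mask.mask
    if not m.any():
        raise ValueError("local_diameter requires a non-empty mask")
    vx, vy, vz = mask.voxel_size
    v0 = min(vx, vy, vz)
    factors = (vz / v0, vy / v0, vx / v0)
    # skeletonization assumes isotropic voxels; resample when anisotropic
    if max(factors) / min(factors) > 1.01:
        iso = ndimage.zoom(m.astype(np.uint8), factors, order=0).astype(bool)
    else:
        iso = m
    edt = ndimage.distance_transform_edt(iso) * v0
    skel = skeletonize(iso)
    if not skel.any():
        # single voxels / structures below skeletonization support
        skel = iso & (edt == ndimage.maximum_filter(edt, size=3))
    # nearest skeleton voxel for every foreground voxel; the +v0 term
    # corrects the centre-to-centre EDT to the physical surface (the
    # boundary lies about half a voxel beyond the last foreground
    # centre on each side)
    _, idx = ndimage.distance_transform_edt(~skel, return_indices=True)
    dmap_iso = 2.0 * edt[idx[0], idx[1], idx[2]] + v0
    if iso is m:
        dmap = np.where(m, dmap_iso, np.nan)
    else:
        # map original voxel centres onto the isotropic grid
        zi = np.minimum(
            ((np.arange(m.shape[0]) + 0.5) * factors[0]).astype(int), iso.shape[0] - 1
        )
        yi = np.minimum(
            ((np.arange(m.shape[1]) + 0.5) * factors[1]).astype(int), iso.shape[1] - 1
        )
        xi = np.minimum(
            ((np.arange(m.shape[2]) + 0.5) * factors[2]).astype(int), iso.shape[2] - 1
        )
        dmap = np.where(m, dmap_iso[np.ix_(zi, yi, xi)], np.nan)
    # components one voxel thick along some axis: the EDT convention
    # cannot see sub-voxel widths, so clamp to the voxel size
    lbl, n = ndimage.label(m, structure=_STRUCT26)
    clamped = 0
    for comp, sl in enumerate(ndimage.find_objects(lbl), start=1):
        extents = [s.stop - s.start for s in sl]  # (z, y, x) voxels
        thin_axes = [ax for ax, e in enumerate(extents) if e == 1]
        if thin_axes:
            vox_zyx = (mask.voxel_size[2], mask.voxel_size[1], mask.voxel_size[0])
            clamp = min(vox_zyx[ax] for ax in thin_axes)
            sel = lbl == comp
            dmap[sel] = clamp
            clamped += int(sel.sum())
    if clamped:
        logger.warning(
            "%d voxels in one-voxel-thin components; diameter clamped to the voxel size",
            clamped,
        )
    min_vox = min(mask.voxel_size)
    dmap[m & (dmap < min_vox)] = min_vox
    return dmap


def pair_sessions(
    mask_t0: VesselMask,
    mask_t1: VesselMask,
    registration: str = "none",
    max_shift: int = 10,
) -> VesselSnapshotPair:
    """Pair two session masks, optionally registering by integer translation.

    ``registration="translation"`` finds the integer-voxel shift of t1
    (within ``max_shift`` voxels per axis) maximizing the overlap with
    t0 via FFT cross-correlation, and applies it to t1.  The implant
    normally keeps the frame fixed, so ``"none"`` is the default.
    """
    if mask_t0.mask.shape != mask_t1.mask.shape:
        raise ValueError("session masks must share the same grid shape")
    if mask_t0.voxel_size != mask_t1.voxel_size:
        raise ValueError("session masks must share the same voxel size")
    if registration not in ("none", "translation"):
        raise ValueError(f"unknown registration mode {registration!r}")
    shift = (0, 0, 0)
    m1 = mask_t1.mask
    if registration == "translation" and mask_t0.mask.any() and m1.any():
        a = mask_t0.mask.astype(np.float64)
        b = m1.astype(np.float64)
        corr = np.fft.irfftn(
            np.fft.rfftn(a) * np.conj(np.fft.rfftn(b)), s=a.shape, axes=(0, 1, 2)
        )
        # restrict to shifts within +/- max_shift per axis
        grids = np.meshgrid(
            *[np.fft.fftfreq(n, 1.0 / n).astype(int) for n in a.shape],
            indexing="ij",
        )
        allowed = np.ones(a.shape, dtype=bool)
        for g in grids:
            allowed &= np.abs(g) <= max_shift
        corr_masked = np.where(allowed, corr, -np.inf)
        best = np.unravel_index(np.argmax(corr_masked), corr.shape)
        shift = tuple(int(g[best]) for g in grids)
        if any(shift):
            m1 = np.roll(m1, shift, axis=(0, 1, 2))
            # voxels rolled across the boundary are invalid; zero them
            for ax, s in enumerate(shift):
                if s > 0:
                    sl = [slice(None)] * 3
                    sl[ax] = slice(0, s)
                    m1[tuple(sl)] = False
                elif s < 0:
                    sl = [slice(None)] * 3
                    sl[ax] = slice(s, None)
                    m1[tuple(sl)] = False
    registered_t1 = VesselMask(
        mask=m1, voxel_size=mask_t1.voxel_size, session_hours=mask_t1.session_hours
    )
    return VesselSnapshotPair(mask_t0=mask_t0, mask_t1=registered_t1, shift_voxels=shift)


def remodeling_statistic(
    pair: VesselSnapshotPair,
    dmap_t1: np.ndarray | None = None,
    class_edges: tuple[float, float, float] = DEFAULT_CLASS_EDGES,
) -> tuple[list[RemodelingRecord], pd.DataFrame]:
    """Per-vessel normalized volume change, stratified by diameter class.

    Vessel instances are the 26-connected components of the union of
    the two sessions' masks.  Each component is classified by the
    median local diameter over its later-session voxels (half-open bins
    ``[e0, e1)``, ``[e1, e2)``, ``[e2, inf)``); components with median
    diameter below ``e0`` are excluded.  Components absent at t1 are
    recorded as fully disappeared and excluded from class means.

    Returns the per-component records and a per-class summary table
    (mean, s.d., n of ``delta_norm``).
    """
    union = pair.union
    if not union.any():
        return [], _summary_table([])
    if dmap_t1 is None:
        dmap_t1 = local_diameter(pair.mask_t1) if pair.mask_t1.mask.any() else None
    vox_vol = pair.mask_t1.voxel_volume
    lbl, n = ndimage.label(union, structure=_STRUCT26)
    records: list[RemodelingRecord] = []
    e0, e1, e2 = class_edges
    for comp in range(1, n + 1):
        sel = lbl == comp
        in_t1 = sel & pair.mask_t1.mask
        v_t1 = float(in_t1.sum()) * vox_vol
        v_app = float((sel & pair.appearance).sum()) * vox_vol
        v_dis = float((sel & pair.disappearance).sum()) * vox_vol
        if in_t1.any() and dmap_t1 is not None:
            med = float(np.nanmedian(dmap_t1[in_t1]))
        else:
            med = np.nan
        label = _classify(med, class_edges)
        records.append(
            RemodelingRecord(
                component_id=comp,
                class_label=label,
                median_diameter=med,
                volume_t1=v_t1,
                volume_appear=v_app,
                volume_disappear=v_dis,
            )
        )
    n_gone = sum(r.fully_disappeared for r in records)
    if n_gone:
        logger.info("%d component(s) fully disappeared by t1", n_gone)
    return records, _summary_table(records)


def _classify(median_diameter: float, class_edges) -> str | None:
    e0, e1, e2 = class_edges
    if not np.isfinite(median_diameter) or median_diameter < e0:
        return None
    if median_diameter < e1:
        return "small"
    if median_diameter < e2:
        return "mid"
    return "large"


def _summary_table(records) -> pd.DataFrame:
    rows = []
    for cls in CLASS_NAMES:
        vals = [
            r.delta_norm
            for r in records
            if r.class_label == cls and not r.fully_disappeared
        ]
        rows.append(
            {
                "class": cls,
                "n": len(vals),
                "delta_norm_mean": float(np.mean(vals)) if vals else np.nan,
                "delta_norm_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: list[RemodelingRecord]) -> pd.DataFrame:
    """Flatten remodeling records into a tidy table."""
    return pd.DataFrame(
        {
            "component_id": [r.component_id for r in records],
            "class": [r.class_label for r in records],
            "median_diameter_um": [r.median_diameter for r in records],
            "volume_t1_um3": [r.volume_t1 for r in records],
            "volume_appear_um3": [r.volume_appear for r in records],
            "volume_disappear_um3": [r.volume_disappear for r in records],
            "delta_norm": [r.delta_norm for r in records],
            "delta_signed": [r.delta_signed for r in records],
        }
    )


@dataclass
class ClassComparison:
    """One-way ANOVA across diameter classes plus pairwise follow-ups."""

    f_statistic: float
    p_value: float
    group_sizes: dict
    pairwise: pd.DataFrame  # Welch t per pair, Bonferroni-adjusted


def compare_classes(records: list[RemodelingRecord]) -> ClassComparison:
    """One-way ANOVA of ``delta_norm`` across diameter classes.

    Classes with fewer than two usable records are dropped with a
    warning; at least two such classes are required.  Pairwise Welch
    t-tests with Bonferroni correction are reported as follow-ups.
    """
    groups: dict[str, list[float]] = {}
    for r in records:
        if r.class_label is None or r.fully_disappeared:
            continue
        groups.setdefault(r.class_label, []).append(r.delta_norm)
    usable = {}
    for cls, vals in groups.items():
        if len(vals) < 2:
            logger.warning("class %r has < 2 records; dropped from ANOVA", cls)
        else:
            usable[cls] = np.asarray(vals, dtype=float)
    if len(usable) < 2:
        raise ValueError("compare_classes needs >= 2 classes with >= 2 records each")
    order = [c for c in CLASS_NAMES if c in usable]
    f, p = stats.f_oneway(*[usable[c] for c in order])
    rows = []
    n_pairs = len(order) * (len(order) - 1) // 2
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            t, pp = stats.ttest_ind(usable[order[i]], usable[order[j]], equal_var=False)
            rows.append(
                {
                    "class_a": order[i],
                    "class_b": order[j],
                    "t": float(t),
                    "p_raw": float(pp),
                    "p_bonferroni": float(min(1.0, pp * n_pairs)),
                }
            )
    return ClassComparison(
        f_statistic=float(f),
        p_value=float(p),
        group_sizes={c: len(usable[c]) for c in order},
        pairwise=pd.DataFrame(rows),
    )
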
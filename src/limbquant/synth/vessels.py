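"""Synthetic two-session vessel scenes with known remodeling ground truth.

The generator emulates a Qdot-labelled marrow vasculature imaged twice,
24 h apart.  Each vessel is a tube around a random, gently curving
centreline; between the sessions a diameter-class-dependent fraction of
its volume turns over.  Remodeling is realized by sliding the vessel's
arc-length window along a fixed mother curve: a vessel of class rate
``r`` (fraction of volume per 24 h) retracts ``r/2`` of its length at
one end and grows ``r/2`` of new length at the other, so the
symmetric-difference volume is close to ``r`` times the later-session
volume — the regime in which small vessels remodel more rapidly than
large ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..config import SceneConfig, stage_rng
from ..containers import TimeLapseVolume
from . import _render

logger = logging.getLogger(__name__)

#: volume-turnover rate per 24 h for each diameter class
DEFAULT_REMODEL_RATES = {"small": 0.4, "mid": 0.15, "large": 0.05}

#: diameter draw range (µm) per class; kept >= ~1 voxel inside the class
#: bins [5, 15), [15, 35), [35, inf) because local-thickness estimates
#: carry a downward quantization bias of about one (axial) voxel, and a
#: validation phantom should not place objects on a decision edge
DEFAULT_DIAMETER_RANGES = {
    "small": (9.0, 14.0),
    "mid": (19.0, 31.0),
    "large": (39.0, 49.0),
}

DEFAULT_VESSELS_PER_CLASS = {"small": 4, "mid": 3, "large": 2}


@dataclass
class VesselTruth:
    """Ground truth for one generated vessel."""

    vessel_id: int
    class_label: str
    diameter: float
    centerlines: dict  # session index -> (n, 3) polyline, µm
    rate: float
    true_delta_norm: float = np.nan
    volume_t1: float = np.nan


@dataclass
class VesselGroundTruth:
    """Ground truth for a two-session vessel scene."""

    vessels: list[VesselTruth]
    label_fields: list[np.ndarray]  # per-session boolean (z, y, x) grids
    remodel_rates: dict
    session_hours: tuple[float, ...]
    voxel_size: tuple[float, float, float]

    def class_mean_delta(self) -> dict:
        """Mean true normalized volume change per diameter class."""
        out: dict[str, float] = {}
        for cls in sorted({v.class_label for v in self.vessels}):
            vals = [v.true_delta_norm for v in self.vessels if v.class_label == cls]
            out[cls] = float(np.mean(vals))
        return out


def _vertex_arcs(total, shift, base_len, radius, target_seg=15.0):
    """Arc positions of polyline vertices along the mother curve.

    Interior vertices (where spherical joints sit) keep at least one
    tube radius of arc length away from the session cut points (arcs
    ``shift`` and ``base_len``) and from both curve ends, so the flat
    end carve of either session window never clips a joint sphere.
    """
    a0 = shift + radius + 1.0
    a1 = base_len - radius - 1.0
    if a1 <= a0:
        return np.array([0.0, total])
    n_mid = max(1, int(round((a1 - a0) / target_seg)))
    interior = np.linspace(a0, a1, n_mid + 1)
    return np.concatenate([[0.0], interior, [total]])


def _random_centerline(rng, extent, diameter, seg_lengths):
    """Gently curving polyline, mostly lateral (the stack is shallow in z)."""
    ex, ey, ez = extent
    margin = diameter / 2.0 + 2.0
    theta = rng.uniform(0, 2 * np.pi)
    d = np.array([np.cos(theta), np.sin(theta), 0.0])
    # start away from the walls so most of the tube stays in view
    z_lo, z_hi = max(margin, 0.1 * ez), min(ez - margin, 0.9 * ez)
    if z_hi <= z_lo:  # vessel thicker than the stack: centre it in z
        z_lo = z_hi = ez / 2.0
    start = np.array(
        [
            rng.uniform(0.2 * ex, 0.8 * ex),
            rng.uniform(0.2 * ey, 0.8 * ey),
            rng.uniform(z_lo, z_hi) if z_hi > z_lo else z_lo,
        ]
    )
    pts = [start]
    for seg in seg_lengths:
        turn = rng.normal(0.0, 0.25)
        c, s = np.cos(turn), np.sin(turn)
        d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1], 0.0])
        d[2] = np.clip(rng.normal(0.0, 0.05), -0.1, 0.1)
        d /= np.linalg.norm(d)
        nxt = pts[-1] + d * seg
        # reflect off the lateral walls; clamp z softly
        for ax, e in ((0, ex), (1, ey)):
            if nxt[ax] < margin or nxt[ax] > e - margin:
                d[ax] = -d[ax]
                nxt = pts[-1] + d * seg
        if ez > 2 * margin:
            nxt[2] = np.clip(nxt[2], margin, ez - margin)
        else:
            nxt[2] = ez / 2.0
        pts.append(nxt)
    return np.array(pts)


def _arc_lengths(poly):
    return np.linalg.norm(np.diff(poly, axis=0), axis=1)


def _point_at(poly, s):
    """Point at arc length ``s`` along the polyline."""
    seg = _arc_lengths(poly)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    f = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return poly[i] + f * (poly[i + 1] - poly[i])


def _sample_curve(poly, spacing=2.0):
    """Points every ~``spacing`` µm of arc length (for separation tests)."""
    total = float(_arc_lengths(poly).sum())
    n = max(int(total / spacing), 2)
    return np.array([_point_at(poly, s) for s in np.linspace(0.0, total, n)])


def _min_curve_distance(pts_a, pts_b):
    d2 = ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def _self_avoiding(pts, spacing, radius, slack=2.0):
    """True when non-adjacent curve portions stay > 2 * radius apart.

    Wall reflections can fold a curve back onto itself; such hairpins
    merge the tube with itself and put remote arc portions inside the
    flat end carve, so they are rejected at placement time.
    """
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    gap = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) * spacing
    nonlocal_pairs = gap > (2.0 * radius + 2.0 * spacing)
    if not nonlocal_pairs.any():
        return True
    return bool(d[nonlocal_pairs].min() > 2.0 * radius + slack)


def _subcurve(poly, s0, s1):
    """Polyline between arc lengths ``s0`` and ``s1`` (interpolated ends)."""
    seg = _arc_lengths(poly)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s0 = float(np.clip(s0, 0.0, cum[-1]))
    s1 = float(np.clip(s1, s0, cum[-1]))
    a = _point_at(poly, s0)
    b = _point_at(poly, s1)
    inner = poly[(cum > s0 + 1e-9) & (cum < s1 - 1e-9)]
    pts = np.vstack([a, inner, b]) if len(inner) else np.vstack([a, b])
    return pts


def classify_diameter(diameter: float, class_edges=(5.0, 15.0, 35.0)) -> str | None:
    """Diameter class with half-open bins [5, 15), [15, 35), [35, inf);
    below the first edge returns ``None`` (excluded from the analysis)."""
    lo, mid, hi = class_edges
    if diameter < lo:
        return None
    if diameter < mid:
        return "small"
    if diameter < hi:
        return "mid"
    return "large"


def generate_vessel_scene(
    config: SceneConfig,
    remodel_rates: dict | None = None,
    *,
    n_per_class: dict | None = None,
    diameter_ranges: dict | None = None,
    session_hours: tuple[float, float] = (0.0, 24.0),
    vessel_length: float | None = None,
    min_clearance: float = 8.0,
    degrade: bool = True,
) -> tuple[TimeLapseVolume, VesselGroundTruth]:
    """Generate a two-session vessel-channel scene with remodeling truth.

    Parameters
    ----------
    config : SceneConfig
        Geometry / optics / noise; ``config.seed`` drives everything.
    remodel_rates : dict, optional
        Volume-turnover rate per 24 h for ``small``, ``mid``, ``large``.
    n_per_class, diameter_ranges : dict, optional
        How many vessels to draw per class and from which diameter range.
    session_hours : tuple
        Timestamps (h) of the two sessions.
    degrade : bool
        Apply PSF blur and noise; ``False`` returns the ideal signal.

    Returns
    -------
    (TimeLapseVolume, VesselGroundTruth)
        A two-frame stack (one frame per session) and the ground truth;
        each vessel's ``true_delta_norm`` is the symmetric-difference
        volume of its rendered noiseless masks divided by its
        later-session volume.
    """
    rates = dict(DEFAULT_REMODEL_RATES if remodel_rates is None else remodel_rates)
    npc = dict(DEFAULT_VESSELS_PER_CLASS if n_per_class is None else n_per_class)
    dr = dict(DEFAULT_DIAMETER_RANGES if diameter_ranges is None else diameter_ranges)
    missing = set(npc) - set(rates)
    if missing:
        raise ValueError(f"remodel_rates missing classes: {sorted(missing)}")
    min_diameter = min(lo for cls, (lo, _) in dr.items() if npc.get(cls, 0) > 0)
    if max(config.voxel_size) > min_diameter:
        raise ValueError(
            f"voxel size {max(config.voxel_size)} µm exceeds the smallest "
            f"requested vessel diameter {min_diameter} µm (undersampled scene)"
        )
    dt_days = (session_hours[1] - session_hours[0]) / 24.0
    rng = stage_rng(config.seed, "synth.vessels")
    shape = config.grid_shape

    vessels: list[VesselTruth] = []
    placed: list[tuple[np.ndarray, float]] = []  # (sampled curve, radius)
    vid = 0
    # place thick vessels first: they are hardest to fit without contact
    for cls in ("large", "mid", "small"):
        for _ in range(npc.get(cls, 0)):
            lo, hi = dr[cls]
            diameter = float(rng.uniform(lo, hi))
            p = float(np.clip(rates[cls] * dt_days, 0.0, 1.0))
            full_len = (
                vessel_length
                if vessel_length is not None
                else 0.5 * min(config.volume_extent[0], config.volume_extent[1])
            )
            # one mother curve; each session occupies an arc-length window
            # of length base_len, shifted by (rate/2) * base_len between
            # sessions, so the symmetric difference is the two end pieces
            # and delta_norm is independent of the vessel's length.
            # Curves are rejection-sampled so distinct vessels never touch
            # (union components must stay per-vessel); when a crowded
            # scene leaves no room, the vessel is retried shorter.
            mother = best = None
            best_clearance = -np.inf
            for length_factor in (1.0, 0.75, 0.55, 0.4):
                base_len = full_len * length_factor
                shift = p / 2.0 * base_len
                arcs = _vertex_arcs(base_len + shift, shift, base_len, diameter / 2.0)
                seg_lengths = np.diff(arcs)
                for _try in range(100):
                    cand = _random_centerline(
                        rng, config.volume_extent, diameter, seg_lengths
                    )
                    pts = _sample_curve(cand)
                    if not _self_avoiding(pts, 2.0, diameter / 2.0):
                        continue
                    clearance = min(
                        (
                            _min_curve_distance(pts, q) - diameter / 2.0 - r_other
                            for q, r_other in placed
                        ),
                        default=np.inf,
                    )
                    if clearance > min_clearance:
                        mother = cand
                        break
                    if clearance > best_clearance:
                        best_clearance, best = clearance, cand
                if mother is not None:
                    break
            if mother is None:
                logger.warning(
                    "could not place a %s vessel without contact; "
                    "using the best-clearance candidate (%.1f µm)",
                    cls,
                    best_clearance,
                )
                mother = best
                base_len = full_len
                shift = p / 2.0 * base_len
            placed.append((_sample_curve(mother), diameter / 2.0))
            total = float(_arc_lengths(mother).sum())
            shift = min(shift, max(total - base_len, 0.0))
            poly0 = _subcurve(mother, 0.0, base_len)
            poly1 = _subcurve(mother, shift, base_len + shift)
            vessels.append(
                VesselTruth(
                    vessel_id=vid,
                    class_label=cls,
                    diameter=diameter,
                    centerlines={0: poly0, 1: poly1},
                    rate=rates[cls],
                )
            )
            vid += 1

    label_fields = []
    per_vessel_masks: list[dict[int, np.ndarray]] = [dict() for _ in vessels]
    for s in (0, 1):
        labels = np.zeros(shape, dtype=bool)
        for v in vessels:
            m = _render.render_tube(shape, config.voxel_size, v.centerlines[s], v.diameter)
            per_vessel_masks[v.vessel_id][s] = m
            labels |= m
        label_fields.append(labels)

    vox_vol = float(np.prod(config.voxel_size))
    for v in vessels:
        m0, m1 = per_vessel_masks[v.vessel_id][0], per_vessel_masks[v.vessel_id][1]
        v1 = int(m1.sum())
        sym = int(np.logical_xor(m0, m1).sum())
        v.volume_t1 = v1 * vox_vol
        v.true_delta_norm = sym / v1 if v1 > 0 else np.nan

    frames = np.stack(
        [
            _render.form_image(lbl, config, rng, degrade=degrade)
            for lbl in label_fields
        ]
    )
    stack = TimeLapseVolume(
        data=frames.astype(np.float32),
        voxel_size=config.voxel_size,
        timestamps=np.asarray(session_hours, dtype=float),
        time_unit="h",
        channel="vessels",
    )
    truth = VesselGroundTruth(
        vessels=vessels,
        label_fields=label_fields,
        remodel_rates=rates,
        session_hours=tuple(session_hours),
        voxel_size=config.voxel_size,
    )
    return stack, truth
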
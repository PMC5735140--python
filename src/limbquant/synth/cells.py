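"""Synthetic B-lineage cell movies with known trajectories.

Two motion regimes: B cells perform a persistent random walk with a
fixed per-frame step length (speed × frame interval), while plasma
cells — sessile residents of marrow niches — jitter inside a small
confinement radius around an anchor point.  Cells are rendered as
spheres of their configured volume; volumes are drawn strictly below
(B cells) or above (plasma cells) the 500 µm³ boundary that separates
the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import SceneConfig, stage_rng
from ..containers import TimeLapseVolume
from . import _render


@dataclass(frozen=True)
class MotionParams:
    """Motion model parameters.

    ``b_speed`` is the B-cell speed in µm/min (per-frame step length is
    ``b_speed * frame_interval / 60``); ``persistence`` in [0, 1) blends
    the previous step direction into the next one.  Plasma cells take
    Ornstein-Uhlenbeck-like jitter steps of s.d. ``pc_jitter_sd`` µm,
    confined within ``pc_confinement_radius`` µm of their anchor.
    """

    b_speed: float = 4.0
    persistence: float = 0.7
    pc_jitter_sd: float = 0.3
    pc_confinement_radius: float = 2.0

    def __post_init__(self):
        if self.b_speed < 0 or not (0 <= self.persistence < 1):
            raise ValueError("b_speed must be >= 0 and persistence in [0, 1)")


@dataclass
class CellTruth:
    """Ground truth for one generated cell."""

    cell_id: int
    class_label: str  # "B cell" | "plasma cell"
    volume: float  # µm³
    trajectory: np.ndarray  # (n_frames, 3) of (x, y, z) µm


@dataclass
class CellGroundTruth:
    cells: list[CellTruth]
    frame_interval: float  # s
    voxel_size: tuple[float, float, float]

    @property
    def n_b(self) -> int:
        return sum(1 for c in self.cells if c.class_label == "B cell")

    @property
    def n_pc(self) -> int:
        return sum(1 for c in self.cells if c.class_label == "plasma cell")


def _random_unit(rng):
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _reflect(pos, lo, hi):
    """Reflect a point into the axis-aligned box [lo, hi]."""
    pos = np.array(pos, dtype=float)
    for ax in range(3):
        span = hi[ax] - lo[ax]
        if span <= 0:
            pos[ax] = (lo[ax] + hi[ax]) / 2.0
            continue
        p = (pos[ax] - lo[ax]) % (2 * span)
        pos[ax] = lo[ax] + (p if p <= span else 2 * span - p)
    return pos


def _b_cell_walk(rng, start, step, n_frames, persistence, lo, hi):
    pts = [np.asarray(start, dtype=float)]
    d = _random_unit(rng)
    for _ in range(n_frames - 1):
        d = persistence * d + (1.0 - persistence) * _random_unit(rng)
        n = np.linalg.norm(d)
        d = d / n if n > 1e-12 else _random_unit(rng)
        nxt = _reflect(pts[-1] + d * step, lo, hi)
        d = (nxt - pts[-1]) / step if step > 0 else d
        pts.append(nxt)
    return np.array(pts)


def _plasma_jitter(rng, anchor, n_frames, sd, radius):
    anchor = np.asarray(anchor, dtype=float)
    pts = [anchor.copy()]
    for _ in range(n_frames - 1):
        nxt = 0.7 * (pts[-1] - anchor) + rng.normal(0.0, sd, size=3) + anchor
        off = nxt - anchor
        r = np.linalg.norm(off)
        if r > radius:
            nxt = anchor + off * (radius / r)
        pts.append(nxt)
    return np.array(pts)


def generate_cell_scene(
    config: SceneConfig,
    n_b: int = 20,
    n_pc: int = 10,
    motion: MotionParams | None = None,
    *,
    b_volume_range: tuple[float, float] = (150.0, 450.0),
    pc_volume_range: tuple[float, float] = (600.0, 1500.0),
    degrade: bool = True,
) -> tuple[TimeLapseVolume, CellGroundTruth]:
    """Generate a cell-channel time lapse with known trajectories.

    Returns a ``(t, z, y, x)`` stack (``config.n_frames`` frames spaced
    ``config.frame_interval`` seconds apart) plus ground truth with one
    trajectory per cell.  B-cell volumes are drawn below 500 µm³ and
    plasma-cell volumes above it.
    """
    if n_b < 0 or n_pc < 0:
        raise ValueError("cell counts must be non-negative")
    motion = motion or MotionParams()
    step = motion.b_speed * config.frame_interval / 60.0  # µm per frame
    if step > min(config.volume_extent) / 2.0:
        raise ValueError(
            "per-frame step exceeds half the volume extent; "
            "reduce speed or frame interval"
        )
    if b_volume_range[1] >= 500.0 or pc_volume_range[0] <= 500.0:
        raise ValueError("volume ranges must respect the 500 µm³ class boundary")
    rng = stage_rng(config.seed, "synth.cells")
    ex, ey, ez = config.volume_extent
    shape = config.grid_shape
    # keep cells visible: motion is confined to the square inscribed in
    # the circular field of view (cells outside the FOV render to nothing)
    half_side = config.fov_diameter / (2.0 * np.sqrt(2.0))
    cx, cy = ex / 2.0, ey / 2.0

    cells: list[CellTruth] = []
    starts: list[np.ndarray] = []
    radii: list[float] = []
    cid = 0
    for cls, n, vol_range in (
        ("B cell", n_b, b_volume_range),
        ("plasma cell", n_pc, pc_volume_range),
    ):
        for _ in range(n):
            volume = float(rng.uniform(*vol_range))
            radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
            lo = np.array([cx - half_side + radius, cy - half_side + radius, radius])
            hi = np.array([cx + half_side - radius, cy + half_side - radius, ez - radius])
            hi = np.maximum(hi, lo)  # degenerate thin stacks
            # rejection-sample a start that does not touch earlier cells
            start = None
            for _try in range(200):
                cand = np.array(
                    [rng.uniform(l, h) if h > l else l for l, h in zip(lo, hi)]
                )
                if all(
                    np.linalg.norm(cand - s) > radius + r0 + 2.0
                    for s, r0 in zip(starts, radii)
                ):
                    start = cand
                    break
            if start is None:
                start = np.array(
                    [rng.uniform(l, h) if h > l else l for l, h in zip(lo, hi)]
                )
            starts.append(start)
            radii.append(radius)
            if cls == "B cell":
                traj = _b_cell_walk(
                    rng, start, step, config.n_frames, motion.persistence, lo, hi
                )
            else:
                traj = _plasma_jitter(
                    rng,
                    start,
                    config.n_frames,
                    motion.pc_jitter_sd,
                    motion.pc_confinement_radius,
                )
                traj = np.array([_reflect(p, lo, hi) for p in traj])
            cells.append(CellTruth(cid, cls, volume, traj))
            cid += 1

    frames = np.empty((config.n_frames, *shape), dtype=np.float32)
    for t in range(config.n_frames):
        labels = np.zeros(shape, dtype=bool)
        for c in cells:
            radius = (3.0 * c.volume / (4.0 * np.pi)) ** (1.0 / 3.0)
            _render.render_ball(labels, config.voxel_size, c.trajectory[t], radius)
        frames[t] = _render.form_image(labels, config, rng, degrade=degrade)

    stack = TimeLapseVolume(
        data=frames,
        voxel_size=config.voxel_size,
        timestamps=np.arange(config.n_frames) * config.frame_interval,
        time_unit="s",
        channel="cells",
    )
    return stack, CellGroundTruth(cells, config.frame_interval, config.voxel_size)
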
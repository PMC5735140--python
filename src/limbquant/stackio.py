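"""TIFF stack I/O with mandatory physical metadata.

Stacks are written as multi-page TIFF plus a JSON sidecar
(``<stack>.json``) carrying voxel size, timestamps, and provenance.
Physical units pervade every downstream statistic, so a stack without
voxel-size metadata (sidecar or TIFF resolution tags) is refused
loudly rather than given a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import StackMetadata, TimeLapseVolume


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, volume: TimeLapseVolume, provenance: str = "") -> Path:
    """Write a stack as multi-page TIFF with a JSON metadata sidecar.

    4D stacks are written with TZYX page ordering; the sidecar records
    the frame count so the time axis can be reconstructed on read.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    meta = volume.metadata(provenance=provenance)
    pages = data.reshape(-1, *data.shape[-2:])
    vx, vy, _ = volume.voxel_size
    tifffile.imwrite(
        path,
        pages,
        resolution=(1.0 / vx, 1.0 / vy),
        photometric="minisblack",
        metadata=None,
    )
    sidecar = meta.to_dict()
    sidecar["shape"] = list(data.shape)
    sidecar["dtype"] = str(data.dtype)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path) -> tuple[TimeLapseVolume, StackMetadata]:
    """Read a multi-page TIFF stack and its metadata.

    Requires the JSON sidecar written by :func:`write_stack` (or one
    with the same schema).  Raises if the file is missing, the page
    shapes are inconsistent with the recorded shape, or no voxel-size
    metadata can be found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"no metadata sidecar {sidecar.name}: voxel size unknown; "
            "refusing to guess physical units"
        )
    meta_dict = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta_dict:
        raise ValueError(f"sidecar {sidecar.name} lacks voxel_size_um")
    meta = StackMetadata.from_dict(meta_dict)
    pages = tifffile.imread(path)
    shape = meta_dict.get("shape")
    if shape is not None:
        expected_pages = int(np.prod(shape[:-2]))
        got_pages = pages.shape[0] if pages.ndim > 2 else 1
        if got_pages != expected_pages or list(pages.shape[-2:]) != shape[-2:]:
            raise ValueError(
                f"TIFF pages {pages.shape} inconsistent with recorded shape {shape}"
            )
        data = pages.reshape(shape)
    else:
        data = pages
    volume = TimeLapseVolume(
        data=data,
        voxel_size=meta.voxel_size,
        timestamps=None if meta.timestamps is None else np.asarray(meta.timestamps),
        time_unit=meta.time_unit,
        channel=meta.channel_names[0] if meta.channel_names else "channel0",
    )
    return volume, meta
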
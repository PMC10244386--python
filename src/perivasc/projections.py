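"""Partial and shifting maximum intensity projections (pMIP / spMIP).

Thin bright tubes are hard to see in single slices and are occluded by the
bright ventricles in a full-volume MIP, so projections are taken through a
slab of consecutive slices (default 30).  A partial MIP (pMIP) projects
one fixed slab; a shifting MIP (spMIP) slides the slab one slice at a time
so a continuous structure can be followed along the projection axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ImageVolume

__all__ = ["AXIS_NAMES", "ProjectionRequest", "partial_mip", "shifting_mip", "save_stack"]

# Anatomical axis names mapped onto array axes, assuming RAS-like ordering
# (x: left-right, y: posterior-anterior, z: inferior-superior).  Projecting
# along y collapses the posterior-anterior direction -> coronal view, etc.
AXIS_NAMES = {"sagittal": 0, "coronal": 1, "transverse": 2}


def _resolve_axis(axis: int | str) -> int:
    if isinstance(axis, str):
        try:
            return AXIS_NAMES[axis.lower()]
        except KeyError:
            raise ValueError(f"axis must be one of {sorted(AXIS_NAMES)} or 0..2, got {axis!r}")
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index must be 0, 1 or 2, got {axis}")
    return int(axis)


@dataclass
class ProjectionRequest:
    axis: int | str = "coronal"
    start_index: int = 0
    thickness: int = 30
    mode: str = "partial"  # "partial" | "shifting"

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")
        if self.mode not in ("partial", "shifting"):
            raise ValueError(f"mode must be 'partial' or 'shifting', got {self.mode!r}")


def partial_mip(volume: ImageVolume, req: ProjectionRequest) -> np.ndarray:
    """Maximum over ``thickness`` slices starting at ``start_index`` along ``axis``."""
    ax = _resolve_axis(req.axis)
    extent = volume.shape[ax]
    if req.start_index + req.thickness > extent:
        raise IndexError(
            f"projection window [{req.start_index}, {req.start_index + req.thickness}) "
            f"exceeds axis extent {extent}"
        )
    sl = [slice(None)] * 3
    sl[ax] = slice(req.start_index, req.start_index + req.thickness)
    return np.max(volume.data[tuple(sl)], axis=ax)


def shifting_mip(volume: ImageVolume, axis: int | str, thickness: int = 30) -> np.ndarray:
    """Stack of pMIPs whose window shifts by one slice per frame.

    Returns an array of ``extent - thickness + 1`` frames; frame ``i``
    equals ``partial_mip`` with ``start_index=i``.
    """
    ax = _resolve_axis(axis)
    extent = volume.shape[ax]
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    if extent < thickness:
        raise IndexError(f"axis extent {extent} smaller than window thickness {thickness}")
    frames = [
        partial_mip(volume, ProjectionRequest(axis=ax, start_index=i, thickness=thickness))
        for i in range(extent - thickness + 1)
    ]
    return np.stack(frames, axis=0)


def save_stack(frames: np.ndarray, outdir: str | Path, axis: int | str, thickness: int,
               prefix: str = "spmip") -> Path:
    """Write frames as numbered PNGs plus a JSON manifest of window indices."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = np.atleast_3d(frames)
    lo, hi = float(frames.min()), float(frames.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    names = []
    for i, frame in enumerate(frames):
        img8 = np.clip((frame - lo) * scale, 0, 255).astype(np.uint8)
        name = f"{prefix}_{i:04d}.png"
        iio.imwrite(outdir / name, img8.T[::-1])  # row-major display orientation
        names.append(name)
    manifest = {
        "axis": axis if isinstance(axis, str) else int(axis),
        "thickness": int(thickness),
        "windows": [[i, i + thickness] for i in range(len(names))],
        "frames": names,
        "intensity_range": [lo, hi],
    }
    mpath = outdir / f"{prefix}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
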
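"""Shared volumetric containers and NIfTI input/output.

All volumes in this package are plain 3D scalar grids on an axis-aligned
lattice with known physical voxel spacing.  Physical coordinates follow a
single convention throughout: voxel ``(i, j, k)`` has its *center* at
``((i + 0.5) * sx, (j + 0.5) * sy, (k + 0.5) * sz)`` and all lengths are
in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "GeometryError",
    "read_volume",
    "write_volume",
    "write_mask",
    "voxel_centers",
]


class GeometryError(ValueError):
    """Raised when volumes or masks that must share a grid do not."""


@dataclass
class ImageVolume:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.  Boolean arrays represent segmentation masks,
        floats represent intensities, tubeness scores or distance maps.
    spacing : tuple of float
        Physical voxel size per axis in mm.  Must be positive.
    meta : dict
        Free-form provenance (config used, scale factors, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_geometry(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def check_geometry(self, other: "ImageVolume", what: str = "volume") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} geometry mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def astype(self, dtype) -> "ImageVolume":
        return ImageVolume(self.data.astype(dtype), self.spacing, dict(self.meta))


def voxel_centers(shape: tuple[int, int, int], spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical center coordinates (mm) of every voxel, as a sparse meshgrid."""
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with the spacing in the header."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: ImageVolume, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI-1."""
    write_volume(ImageVolume(mask.data.astype(np.uint8), mask.spacing), path)


def read_volume(path: str | Path, as_mask: bool = False) -> ImageVolume:
    """Read a NIfTI volume; spacing is taken from the header zooms (mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D NIfTI, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if as_mask:
        data = data > 0
    return ImageVolume(data, spacing, {"source": str(path)})
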
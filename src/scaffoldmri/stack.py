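"""Core in-memory containers shared across the pipeline.

An :class:`ImageStack` is the universal carrier: a ``(n_slices, ny, nx)``
array of non-negative intensities plus the physical voxel metadata needed to
express meshes in millimetres.  A :class:`CircularROI` is the slice-plane
circle (scaffold plus surrounding liquid) inside which all pixel counting
happens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = ["ImageStack", "CircularROI"]

BitDepth = Union[int, str]  # 8 | 16 | "float"


@dataclass
class ImageStack:
    """A 3D grayscale image stack with physical voxel metadata.

    Parameters
    ----------
    data:
        ``(n_slices, ny, nx)`` array of finite, non-negative intensities.
        Slice index 0 is the first TIFF page (scaffold top by convention).
    pixel_size:
        In-plane pixel edge length in mm (square pixels).
    slice_thickness:
        Slice-to-slice spacing in mm (no inter-slice gap).
    bit_depth:
        8, 16 or ``"float"``; governs the dtype used when writing TIFF.
    """

    data: np.ndarray
    pixel_size: float
    slice_thickness: float
    bit_depth: BitDepth = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3D (n_slices, ny, nx), got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_size and slice_thickness must be positive (mm)")
        if self.bit_depth not in (8, 16, "float"):
            raise ValueError(f"bit_depth must be 8, 16 or 'float', got {self.bit_depth!r}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> tuple:
        """(dz, dy, dx) voxel spacing in mm, slice axis first."""
        return (self.slice_thickness, self.pixel_size, self.pixel_size)

    def with_data(self, data: np.ndarray, bit_depth: BitDepth | None = None) -> "ImageStack":
        """Copy of this stack with new voxel data (metadata preserved)."""
        return replace(self, data=data, bit_depth=bit_depth or self.bit_depth)


@dataclass(frozen=True)
class CircularROI:
    """Circle in the slice plane, in pixel coordinates (pixel-centered).

    ``center_x`` indexes columns, ``center_y`` rows; a pixel ``(row, col)``
    belongs to the ROI when its center lies within ``radius`` of the circle
    center.
    """

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be > 0")

    def mask(self, shape: tuple) -> np.ndarray:
        """Boolean 2D mask of the ROI on an image of ``shape`` (ny, nx)."""
        ny, nx = shape[-2], shape[-1]
        yy, xx = np.mgrid[0:ny, 0:nx]
        m = (xx - self.center_x) ** 2 + (yy - self.center_y) ** 2 <= self.radius**2
        if not m.any():
            raise ValueError(
                f"ROI (cx={self.center_x}, cy={self.center_y}, r={self.radius}) "
                f"does not intersect a {ny}x{nx} image"
            )
        return m
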
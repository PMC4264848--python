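"""Shared grayscale/binary morphology with one disk discretization.

Every morphological step in the pipeline (background estimation at radius 9,
mask smoothing at radius 2) uses the same structuring element — the set of
pixels whose center distance from the origin is <= radius — and the same
reflective border rule, so a single brute-force oracle covers all of them.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "disk_footprint",
    "grey_erosion",
    "grey_dilation",
    "grey_opening",
    "binary_opening",
]


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean (2r+1, 2r+1) disk: pixels with center distance <= radius."""
    r = int(radius)
    if r < 1:
        raise ValueError("structuring-element radius must be >= 1")
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def grey_erosion(image: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.grey_erosion(image, footprint=disk_footprint(radius), mode="reflect")


def grey_dilation(image: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.grey_dilation(image, footprint=disk_footprint(radius), mode="reflect")


def grey_opening(image: np.ndarray, radius: int) -> np.ndarray:
    """Erosion followed by dilation with the shared disk (anti-extensive,
    idempotent, monotone); removes bright features smaller than the disk."""
    return grey_dilation(grey_erosion(image, radius), radius)


def binary_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary opening via the grayscale operator on a 0/1 image, so binary
    and grayscale morphology share one discretization and border rule."""
    opened = grey_opening(np.asarray(mask, dtype=np.uint8), radius)
    return opened.astype(bool)
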
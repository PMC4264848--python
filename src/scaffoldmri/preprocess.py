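"""Background-intensity correction and denoising.

The correction sequence estimates the non-uniform background from a
reference slice that contains only liquid (top or bottom of the stack) by
grayscale morphological opening with a disk of radius 9 — large enough to
erase any bright structure narrower than the disk while following the
smooth intensity bias.  That single 2D background image is subtracted from
every slice of the stack, then a 2D median filter (disk radius 2) suppresses
remaining noise.  After correction only tissue remains bright; liquid and
scaffold sit near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphology import disk_footprint, grey_opening
from .stack import ImageStack

__all__ = [
    "BackgroundModel",
    "approximate_background",
    "subtract_background",
    "median_denoise",
    "correct_stack",
]


@dataclass
class BackgroundModel:
    """A 2D background estimate tied to the reference slice it came from."""

    reference_slice_index: int
    structuring_radius: int
    background_image: np.ndarray


def approximate_background(
    stack: ImageStack,
    reference_slice_index: int = -1,
    structuring_radius: int = 9,
    dark_fraction_warn: float = 0.1,
) -> BackgroundModel:
    """Estimate the background by opening the reference slice.

    The reference slice should contain only liquid; the opening removes
    bright features smaller than the structuring disk and is anti-extensive
    (background <= slice everywhere) and idempotent.  If a substantial
    fraction of the slice *center* is far darker than the local median — a
    hint that scaffold material is present — a warning is emitted.  (The
    heuristic looks only at the central inscribed disk because the frame
    corners outside the sample tube are legitimately dark.)
    """
    if structuring_radius < 1:
        raise ValueError("structuring_radius must be >= 1")
    n = stack.n_slices
    idx = reference_slice_index if reference_slice_index >= 0 else n + reference_slice_index
    if not 0 <= idx < n:
        raise IndexError(f"reference slice {reference_slice_index} out of range for {n} slices")
    ref = np.asarray(stack.data[idx], dtype=float)
    ny, nx = ref.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    center = ((yy - (ny - 1) / 2) ** 2 + (xx - (nx - 1) / 2) ** 2) <= (0.4 * min(ny, nx)) ** 2
    vals = ref[center]
    med = float(np.median(vals))
    if med > 0:
        dark = float(np.mean(vals < 0.5 * med))
        if dark > dark_fraction_warn:
            warnings.warn(
                f"reference slice {idx}: {dark:.0%} of central pixels are far below "
                "the local median; it may contain scaffold material",
                stacklevel=2,
            )
    return BackgroundModel(
        reference_slice_index=idx,
        structuring_radius=int(structuring_radius),
        background_image=grey_opening(ref, structuring_radius),
    )


def subtract_background(stack: ImageStack, background: BackgroundModel) -> ImageStack:
    """Subtract the 2D background from every slice, clipping at zero.

    Output is float so integer wraparound cannot occur; downstream
    thresholding assumes non-negative intensities, hence the clip.
    """
    bg = background.background_image
    if bg.shape != stack.shape[1:]:
        raise ValueError(
            f"background shape {bg.shape} does not match slice shape {stack.shape[1:]}"
        )
    corrected = np.clip(stack.data.astype(float) - bg[None, :, :], 0.0, None)
    return stack.with_data(corrected, bit_depth="float")


def median_denoise(stack: ImageStack, radius: int = 2) -> ImageStack:
    """Per-slice 2D median filter over a disk neighborhood (reflective border)."""
    if radius < 1:
        raise ValueError("median radius must be >= 1")
    fp = disk_footprint(radius)
    out = np.empty_like(stack.data, dtype=float)
    for i in range(stack.n_slices):
        out[i] = ndimage.median_filter(stack.data[i].astype(float), footprint=fp, mode="reflect")
    return stack.with_data(out, bit_depth="float")


def correct_stack(
    stack: ImageStack,
    reference_slice_index: int = -1,
    se_radius: int = 9,
    median_radius: int = 2,
) -> tuple[ImageStack, BackgroundModel]:
    """Full correction sequence: background estimate, subtraction, median."""
    bg = approximate_background(stack, reference_slice_index, se_radius)
    corrected = subtract_background(stack, bg)
    return median_denoise(corrected, median_radius), bg
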
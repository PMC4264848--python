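"""Threshold segmentation of tissue and scaffold inside a circular ROI.

Tissue is the bright class of the *corrected* stack: a single global
intensity threshold inside the ROI followed by binary opening (disk radius
2) to smooth objects and drop outliers.  Scaffold is the dark class of the
raw stack, identified by a low threshold.  The tissue threshold is not a
free parameter: it is calibrated per experiment so that a bare (cell-free)
scaffold scan shows at most a configured fraction of false-positive tissue
signal in its pore space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .morphology import binary_opening
from .stack import CircularROI, ImageStack

__all__ = [
    "SegmentationMasks",
    "segment_tissue",
    "segment_scaffold",
    "calibrate_threshold",
    "false_positive_fraction",
    "fit_roi",
    "mask_f1",
]


@dataclass
class SegmentationMasks:
    """Co-registered binary tissue and scaffold volumes plus bookkeeping.

    ``tissue_threshold`` applies to the corrected stack and
    ``scaffold_threshold`` to the raw stack, so the two are on different
    intensity scales; the enforced contract is mask disjointness inside the
    ROI.
    """

    tissue_mask: np.ndarray
    scaffold_mask: np.ndarray
    roi_mask: np.ndarray  # 2D, broadcast over slices
    tissue_threshold: float
    scaffold_threshold: float

    def __post_init__(self) -> None:
        inside = self.roi_mask[None, :, :]
        if (self.tissue_mask & self.scaffold_mask & inside).any():
            raise ValueError("tissue and scaffold masks overlap inside the ROI")

    def pore_mask(self) -> np.ndarray:
        return self.roi_mask[None, :, :] & ~self.scaffold_mask


def segment_tissue(
    corrected: ImageStack,
    roi: CircularROI,
    threshold: float,
    opening_radius: int = 2,
    apply_opening: bool = True,
) -> np.ndarray:
    """Bright-class segmentation: ``intensity >= threshold`` inside the ROI,
    then per-slice binary opening to remove sub-disk outliers."""
    if threshold <= 0:
        raise ValueError("tissue threshold must be > 0")
    roi2d = roi.mask(corrected.shape[1:])
    mask = (corrected.data >= threshold) & roi2d[None, :, :]
    if apply_opening and opening_radius >= 1:
        for i in range(mask.shape[0]):
            mask[i] = binary_opening(mask[i], opening_radius)
    return mask


def segment_scaffold(
    stack: ImageStack,
    roi: CircularROI,
    low_threshold: float,
    closure_warn_fraction: float = 0.9,
) -> np.ndarray:
    """Dark-class segmentation: ``intensity <= low_threshold`` inside the ROI.

    Warns when the scaffold class floods the ROI (pore closure) — the
    failure mode seen when a contrast agent erases the scaffold–liquid
    contrast.
    """
    roi2d = roi.mask(stack.shape[1:])
    mask = (stack.data.astype(float) <= low_threshold) & roi2d[None, :, :]
    frac = mask[:, roi2d].mean() if roi2d.any() else 0.0
    if frac > closure_warn_fraction:
        warnings.warn(
            f"scaffold segmentation covers {frac:.0%} of the ROI: probable pore "
            "closure (threshold too high or scaffold-liquid contrast lost)",
            stacklevel=2,
        )
    return mask


def false_positive_fraction(
    stack: ImageStack,
    roi: CircularROI,
    scaffold_mask: np.ndarray,
    threshold: float,
    opening_radius: int = 2,
    apply_opening: bool = True,
) -> float:
    """Worst per-slice fraction of pore pixels classified tissue.

    The slice-wise maximum (rather than the stack aggregate) is used so
    that a calibrated threshold bounds the false-positive signal of *every*
    slice record, not just their average.
    """
    roi2d = roi.mask(stack.shape[1:])
    pore = roi2d[None, :, :] & ~scaffold_mask
    return _fp_fraction(stack.data, threshold, roi2d, pore, opening_radius, apply_opening)


def _fp_fraction(
    data: np.ndarray,
    threshold: float,
    roi2d: np.ndarray,
    pore: np.ndarray,
    opening_radius: int,
    apply_opening: bool,
) -> float:
    mask = (data >= threshold) & roi2d[None, :, :]
    if apply_opening and opening_radius >= 1:
        for i in range(mask.shape[0]):
            if mask[i].any():
                mask[i] = binary_opening(mask[i], opening_radius)
    pore_per_slice = pore.reshape(pore.shape[0], -1).sum(axis=1)
    if not pore_per_slice.any():
        raise ValueError("no pore pixels inside the ROI")
    fp_per_slice = (mask & pore).reshape(pore.shape[0], -1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(pore_per_slice > 0, fp_per_slice / pore_per_slice, 0.0)
    return float(frac.max())


def calibrate_threshold(
    bare_corrected: ImageStack,
    roi: CircularROI,
    scaffold_mask: np.ndarray,
    fp_tolerance: float = 0.001,
    opening_radius: int = 2,
    count_before_opening: bool = False,
) -> float:
    """Smallest threshold whose false-positive tissue fraction on a bare
    scaffold stack is within tolerance on every slice.

    False positives are pore pixels (ROI minus scaffold) classified as
    tissue, counted after binary opening by default because post-opening
    masks are what enters quantification, and bounded slice-wise so every
    per-slice record of a tissue-free scan respects the tolerance.  The
    false-positive fraction is non-increasing in the threshold, so a binary
    search over the observed intensity values finds the exact smallest
    admissible threshold.
    """
    if not 0.0 < fp_tolerance <= 1.0:
        raise ValueError("fp_tolerance must be in (0, 1]")
    roi2d = roi.mask(bare_corrected.shape[1:])
    pore = roi2d[None, :, :] & ~scaffold_mask
    data = bare_corrected.data
    candidates = np.unique(data[pore])
    candidates = candidates[candidates > 0]
    # a threshold above the maximum always yields zero false positives
    top = float(data[pore].max()) + 1.0
    candidates = np.append(candidates.astype(float), top)

    def fp(t: float) -> float:
        return _fp_fraction(
            data, t, roi2d, pore, opening_radius, apply_opening=not count_before_opening
        )

    if fp(candidates[-1]) > fp_tolerance:  # pragma: no cover - guarded impossibility
        raise RuntimeError("false-positive tolerance unreachable even above the maximum")
    lo, hi = 0, len(candidates) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if fp(float(candidates[mid])) <= fp_tolerance:
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def fit_roi(
    stack: ImageStack,
    roi: CircularROI | None = None,
    min_area_fraction: float = 0.1,
) -> CircularROI:
    """Fit a circle to the liquid-filled tube on a mid-stack slice.

    A user-supplied ROI always wins (the original workflow draws the ROI by
    hand).  Otherwise the largest connected non-dark region, with interior
    holes (scaffold fibers) filled, is treated as the tube disk: its
    centroid gives the center and its area the radius.
    """
    if roi is not None:
        return roi
    mid = np.asarray(stack.data[stack.n_slices // 2], dtype=float)
    if mid.max() <= 0:
        raise ValueError("blank slice: supply the ROI manually")
    bright = mid > threshold_otsu(mid)
    labels, n = ndimage.label(bright)
    if n == 0:
        raise ValueError("no connected bright region found: supply the ROI manually")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    disk = ndimage.binary_fill_holes(labels == biggest)
    area = float(disk.sum())
    if area < min_area_fraction * mid.size:
        raise ValueError(
            "largest bright region covers "
            f"{area / mid.size:.1%} of the image (< {min_area_fraction:.0%}): "
            "supply the ROI manually"
        )
    ys, xs = np.nonzero(disk)
    return CircularROI(
        center_x=float(xs.mean()),
        center_y=float(ys.mean()),
        radius=float(np.sqrt(area / np.pi)),
    )


def mask_f1(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Pixelwise F1 score of a binary mask against ground truth."""
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0
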
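"""Multi-page TIFF I/O with sidecar metadata.

Stacks travel as 8/16-bit (or float, for corrected intermediates) grayscale
multi-page TIFFs.  Physical voxel metadata, which TIFF does not reliably
carry, lives in a small JSON sidecar next to the file; when absent, the
pixel size defaults to a 10 mm field of view divided by the matrix size.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .stack import ImageStack

__all__ = ["read_stack", "write_stack", "read_mask", "write_mask", "sha256_of_file"]

DEFAULT_FOV_MM = 10.0
DEFAULT_SLICE_THICKNESS_MM = 0.07

_DTYPES = {8: np.uint8, 16: np.uint16, "float": np.float32}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path, sidecar: bool = True) -> Path:
    """Write a stack as multi-page grayscale TIFF (+ JSON metadata sidecar)."""
    path = Path(path)
    data = np.asarray(stack.data)
    dtype = _DTYPES[stack.bit_depth]
    if stack.bit_depth != "float":
        maxv = float(np.iinfo(dtype).max)
        if data.max(initial=0) > maxv:
            raise ValueError(f"intensities exceed the {stack.bit_depth}-bit range")
        data = np.round(data).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    if sidecar:
        meta = {
            "pixel_size_mm": stack.pixel_size,
            "slice_thickness_mm": stack.slice_thickness,
            "bit_depth": stack.bit_depth,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_stack(
    path,
    pixel_size: float | None = None,
    slice_thickness: float | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Explicit arguments override the sidecar, which overrides the defaults
    (FOV 10 mm / matrix size in-plane, 0.07 mm slices).  RGB or otherwise
    non-grayscale files are rejected; truncated files raise rather than
    yielding a partial stack.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            samples = tf.pages[0].samplesperpixel
            arr = tf.asarray() if samples == 1 else None
    except Exception as exc:
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    if arr is None:
        raise ValueError(
            f"{path}: expected a grayscale multi-page TIFF, got {samples} samples "
            "per pixel (RGB/multichannel files are not supported)"
        )
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale multi-page TIFF, got array shape {arr.shape}"
        )
    if arr.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
        raise ValueError(f"{path}: unsupported TIFF sample type {arr.dtype}")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size or meta.get("pixel_size_mm") or DEFAULT_FOV_MM / arr.shape[-1]
    dz = slice_thickness or meta.get("slice_thickness_mm") or DEFAULT_SLICE_THICKNESS_MM
    bit_depth = {np.uint8: 8, np.uint16: 16}.get(arr.dtype.type, "float")
    return ImageStack(data=arr, pixel_size=px, slice_thickness=dz, bit_depth=bit_depth)


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a binary volume as an 8-bit 0/255 multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)), photometric="minisblack")
    return path


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return arr > 0


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
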
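"""Synthetic micro-MRI phantoms of cell-seeded woodpile scaffolds.

The generator emulates what the real scans contain, with known ground truth:

* a cylindrical 0/90° woodpile fiber scaffold (fused-deposition layout:
  fiber-to-fiber spacing 1.0 mm, fiber diameter ~0.2 mm, layer thickness
  0.15 mm, cylinder 8 mm diameter x 3 mm height) immersed in liquid inside a
  glass tube;
* bright "tissue" structures (strings / sheets / blobs) occupying a known
  fraction of the pore volume per scaffold section;
* a smooth multiplicative intensity bias field (coil inhomogeneity scales
  the MR signal multiplicatively) plus Gaussian or Rician noise;
* empty first and last slices containing only liquid, so a reference slice
  for background estimation always exists.

Intensity classes are phenomenological (dark scaffold, grey liquid, bright
tissue); no relaxation physics is simulated.  In ``native`` contrast the
tissue–liquid contrast is deliberately smaller than the bias swing at the
default amplitude — the regime that motivates background correction.  In
``agent`` contrast (emulating a T2 contrast agent in the liquid) the
tissue–liquid contrast is larger but the scaffold–liquid contrast collapses,
which makes low-threshold scaffold segmentation close the pores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage

from .stack import CircularROI, ImageStack

__all__ = [
    "ScaffoldGeometry",
    "TissueModel",
    "AcquisitionModel",
    "PhantomResult",
    "generate_scaffold_mask",
    "generate_tissue_mask",
    "render_stack",
    "bias_field",
    "generate_phantom",
    "section_ranges",
    "split_into_sections",
    "scaffold_roi",
    "tube_roi",
]

SECTION_ORDER = ("top", "middle", "bottom")

NATIVE_LEVELS = {"scaffold": 15.0, "liquid": 100.0, "tissue": 120.0}
AGENT_LEVELS = {"scaffold": 85.0, "liquid": 100.0, "tissue": 160.0}

# independent deterministic sub-streams derived from one user seed
_BIAS_STREAM = 101
_NOISE_STREAM = 202
_TISSUE_STREAM = 303


@dataclass(frozen=True)
class ScaffoldGeometry:
    """Woodpile scaffold geometry in mm (fused-deposition layout)."""

    cylinder_diameter: float = 8.0
    cylinder_height: float = 3.0
    fiber_spacing: float = 1.0
    fiber_diameter: float = 0.2
    layer_thickness: float = 0.15
    lay_down_pattern: Tuple[float, ...] = (0.0, 90.0)

    def __post_init__(self) -> None:
        for name in ("cylinder_diameter", "cylinder_height", "fiber_spacing", "layer_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fiber_diameter < 0:
            raise ValueError("fiber_diameter must be >= 0")
        if self.fiber_diameter >= self.fiber_spacing:
            raise ValueError("fiber_diameter must be smaller than fiber_spacing")
        for angle in self.lay_down_pattern:
            if angle % 90.0 != 0.0:
                raise ValueError("only 0/90 degree lay-down patterns are supported")


@dataclass(frozen=True)
class TissueModel:
    """Ground-truth tissue content: per-section pore-volume occupancy and shape.

    ``component_scale`` is the characteristic diameter (mm) of one tissue
    structure (string tube, blob sphere, sheet thickness).
    """

    target_occupancy_by_section: Mapping[str, float] = field(
        default_factory=lambda: {"top": 0.02, "middle": 0.01, "bottom": 0.04}
    )
    morphology: str = "sheet"
    component_scale: float = 0.4

    def __post_init__(self) -> None:
        if self.morphology not in ("sheet", "string", "blob"):
            raise ValueError("morphology must be one of 'sheet', 'string', 'blob'")
        if self.component_scale <= 0:
            raise ValueError("component_scale must be > 0 (mm)")
        for name, f in self.target_occupancy_by_section.items():
            if name not in SECTION_ORDER:
                raise ValueError(f"unknown section {name!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError("occupancies must be in [0, 1]")


@dataclass(frozen=True)
class AcquisitionModel:
    """Image-formation parameters of the synthetic scan."""

    matrix_size: int = 128
    field_of_view: float = 10.0  # mm
    slice_thickness: float = 0.07  # mm
    n_slices: int = 45
    tube_diameter: float = 9.0  # mm, glass tube holding liquid + scaffold
    intensity_levels: Optional[Mapping[str, float]] = None
    background_level: float = 5.0  # air/glass outside the tube
    bias_amplitude: float = 0.2  # fraction of the class level
    bias_length_scale: float = 4.0  # mm, >= 2 mm (smooth vs fiber scale)
    bias_grf_weight: float = 0.0  # optional 3D Gaussian-random-field part
    noise_sigma: float = 5.0  # intensity units (5% of the liquid level)
    noise_model: str = "gaussian"
    contrast_mode: str = "native"
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size < 8:
            raise ValueError("matrix_size too small")
        if self.field_of_view <= 0 or self.slice_thickness <= 0:
            raise ValueError("field_of_view and slice_thickness must be > 0")
        if self.n_slices < 3:
            raise ValueError("need at least 3 slices (2 reference + 1 informative)")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.contrast_mode not in ("native", "agent"):
            raise ValueError("contrast_mode must be 'native' or 'agent'")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.bias_length_scale < 2.0:
            raise ValueError("bias_length_scale must be >= 2 mm")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        levels = self.levels
        if self.contrast_mode == "native" and not (
            levels["scaffold"] < levels["liquid"] < levels["tissue"]
        ):
            raise ValueError("native mode requires scaffold < liquid < tissue levels")

    @property
    def pixel_size(self) -> float:
        """In-plane voxel edge (mm): FOV / matrix."""
        return self.field_of_view / self.matrix_size

    @property
    def levels(self) -> Dict[str, float]:
        if self.intensity_levels is not None:
            return dict(self.intensity_levels)
        return dict(NATIVE_LEVELS if self.contrast_mode == "native" else AGENT_LEVELS)

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)


# ---------------------------------------------------------------------------
# geometry helpers


def _plane_coords(acq: AcquisitionModel) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel-center x/y coordinates (mm) with the FOV centered on 0."""
    n = acq.matrix_size
    c = (np.arange(n) + 0.5) * acq.pixel_size - acq.field_of_view / 2.0
    return c, c  # x (columns), y (rows)


def _slice_centers(acq: AcquisitionModel) -> np.ndarray:
    return (np.arange(acq.n_slices) + 0.5) * acq.slice_thickness


def _scaffold_z0(geometry: ScaffoldGeometry, acq: AcquisitionModel) -> float:
    """z (mm) of the scaffold top face; scaffold centered in the stack."""
    span = acq.n_slices * acq.slice_thickness
    margin = span - geometry.cylinder_height
    if margin < 2 * acq.slice_thickness:
        raise ValueError(
            "stack too short: the scaffold must leave at least one empty "
            "reference slice at the top and at the bottom "
            f"(stack span {span:.3f} mm, cylinder height {geometry.cylinder_height} mm)"
        )
    return margin / 2.0


def scaffold_roi(geometry: ScaffoldGeometry, acq: AcquisitionModel) -> CircularROI:
    """Counting ROI matching the scaffold's outer ring, in pixels."""
    n = acq.matrix_size
    center = (n - 1) / 2.0
    return CircularROI(center, center, geometry.cylinder_diameter / 2.0 / acq.pixel_size)


def tube_roi(acq: AcquisitionModel) -> CircularROI:
    """Circle of the liquid-filled glass tube, in pixels."""
    n = acq.matrix_size
    center = (n - 1) / 2.0
    return CircularROI(center, center, acq.tube_diameter / 2.0 / acq.pixel_size)


def generate_scaffold_mask(geometry: ScaffoldGeometry, acq: AcquisitionModel) -> np.ndarray:
    """Voxelize the woodpile scaffold on the acquisition grid.

    Fibers are cylinders of ``fiber_diameter`` whose axes lie in the
    mid-plane of each deposited layer, running alternately along x and y
    (0/90° lay-down) at ``fiber_spacing`` pitch.  Because the layer
    thickness (0.15 mm) is smaller than the fiber diameter (0.2 mm),
    consecutive layers interpenetrate, as in the fused fibers of the real
    scaffold.  Returns a boolean ``(n_slices, n, n)`` volume.
    """
    if geometry.cylinder_diameter > acq.field_of_view:
        raise ValueError(
            f"cylinder diameter {geometry.cylinder_diameter} mm exceeds the "
            f"field of view {acq.field_of_view} mm"
        )
    if acq.tube_diameter > acq.field_of_view:
        raise ValueError("tube diameter exceeds the field of view")

    n = acq.matrix_size
    mask = np.zeros((acq.n_slices, n, n), dtype=bool)
    if geometry.fiber_diameter == 0:
        return mask

    x, y = _plane_coords(acq)
    xx, yy = np.meshgrid(x, y)  # row-major: yy varies along rows
    in_cylinder = xx**2 + yy**2 <= (geometry.cylinder_diameter / 2.0) ** 2

    z0 = _scaffold_z0(geometry, acq)
    z_centers = _slice_centers(acq)
    radius = geometry.fiber_diameter / 2.0
    spacing = geometry.fiber_spacing
    n_layers = max(1, round(geometry.cylinder_height / geometry.layer_thickness))

    # signed distance to nearest fiber axis across the pitch, per column/row
    def stripe(coord: np.ndarray, halfwidth: float) -> np.ndarray:
        d = np.abs(((coord + spacing / 2.0) % spacing) - spacing / 2.0)
        return d <= halfwidth

    z_bottom = z0 + geometry.cylinder_height
    for k in range(n_layers):
        z_axis = z0 + (k + 0.5) * geometry.layer_thickness
        angle = geometry.lay_down_pattern[k % len(geometry.lay_down_pattern)] % 180.0
        for i, zc in enumerate(z_centers):
            if i == 0 or i == acq.n_slices - 1:
                continue  # reference slices stay empty
            if not (z0 <= zc <= z_bottom):
                continue
            dz = zc - z_axis
            if abs(dz) >= radius:
                continue
            halfwidth = math.sqrt(radius**2 - dz**2)
            if angle == 0.0:
                # fibers along x: stripes vary with y (rows)
                sl = stripe(y, halfwidth)[:, None] & in_cylinder
            else:
                sl = stripe(x, halfwidth)[None, :] & in_cylinder
            mask[i] |= sl
    return mask


def section_ranges(scaffold_mask: np.ndarray) -> Dict[str, Tuple[int, int]]:
    """Split the informative slice range (slices containing scaffold) into
    top/middle/bottom thirds.  Slice 0 is the scaffold top."""
    occupied = np.flatnonzero(scaffold_mask.reshape(scaffold_mask.shape[0], -1).any(axis=1))
    if occupied.size == 0:
        raise ValueError("scaffold mask is empty; cannot derive sections")
    return split_into_sections(int(occupied[0]), int(occupied[-1]))


def split_into_sections(first: int, last: int) -> Dict[str, Tuple[int, int]]:
    """Deterministic near-equal thirds of [first, last]; remainder slices go
    to the earlier sections."""
    n = last - first + 1
    if n < 3:
        raise ValueError("need at least 3 informative slices for three sections")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    out: Dict[str, Tuple[int, int]] = {}
    start = first
    for name, size in zip(SECTION_ORDER, sizes):
        out[name] = (start, start + size - 1)
        start += size
    return out


# ---------------------------------------------------------------------------
# tissue generation


def _ellipsoid_offsets(rx: float, rz: float) -> np.ndarray:
    """Offsets (dz, dy, dx) inside an axis-aligned ellipsoid, sorted by
    normalized radius (compact truncation order)."""
    nx = max(1, int(math.ceil(rx)))
    nz = max(1, int(math.ceil(rz)))
    dz, dy, dx = np.mgrid[-nz : nz + 1, -nx : nx + 1, -nx : nx + 1]
    r = (dx / max(rx, 0.5)) ** 2 + (dy / max(rx, 0.5)) ** 2 + (dz / max(rz, 0.5)) ** 2
    inside = r <= 1.0
    order = np.argsort(r[inside], kind="stable")
    pts = np.stack([dz[inside], dy[inside], dx[inside]], axis=1)
    return pts[order]


def _stamp(
    center: np.ndarray, offsets: np.ndarray, shape: Tuple[int, int, int]
) -> np.ndarray:
    pts = center[None, :] + offsets
    ok = np.all((pts >= 0) & (pts < np.array(shape)[None, :]), axis=1)
    return pts[ok]


def _structure_voxels(
    morphology: str,
    scale_vox: Tuple[float, float],
    pore: np.ndarray,
    pore_idx: np.ndarray,
    rng: np.random.Generator,
    zlo: int,
    zhi: int,
    face: str = "bottom",
) -> np.ndarray:
    """Ordered candidate voxels (N, 3) of one tissue structure; truncating
    the list keeps the structure compact.

    * ``blob``: spheroid cell aggregate (ellipsoid in voxel space).
    * ``string``: pore-channel ribbon — an in-plane persistent random walk
      stamped with a disk of the component radius, extruded over a flat
      slice band (tissue strings fill the channels between fiber layers,
      so their top and bottom are bounded by fiber planes).
    * ``sheet``: connected layer hugging the section's outward scaffold
      face, grown radially from a random in-plane center.
    """
    rx, rz = scale_vox
    shape = pore.shape
    start = pore_idx[rng.integers(pore_idx.shape[0])]
    if morphology == "blob":
        return _stamp(start, _ellipsoid_offsets(rx, rz), shape)
    if morphology == "string":
        height = max(1, int(round(2 * rz)))
        z0 = int(np.clip(start[0] - height // 2, zlo, zhi))
        z1 = int(min(z0 + height - 1, zhi))
        band = np.arange(z0, z1 + 1)
        nx = max(1, int(math.ceil(rx)))
        dy, dx = np.mgrid[-nx : nx + 1, -nx : nx + 1]
        in_disk = dy**2 + dx**2 <= max(rx, 0.5) ** 2
        disk = np.stack([dy[in_disk], dx[in_disk]], axis=1)
        offsets = np.concatenate(
            [np.column_stack([np.full(len(disk), z), disk]) for z in band - start[0]]
        )
        ang = rng.uniform(0.0, 2.0 * np.pi)
        pos = start[1:].astype(float)
        seen: list[np.ndarray] = []
        n_steps = int(rng.integers(25, 60))
        for _ in range(n_steps):
            center = np.array([start[0], round(pos[0]), round(pos[1])], dtype=int)
            seen.append(_stamp(center, offsets, shape))
            ang += rng.normal(scale=0.35)
            pos = pos + np.array([math.sin(ang), math.cos(ang)]) * max(rx, 1.0)
        if not seen:
            return np.empty((0, 3), dtype=int)
        return np.concatenate(seen, axis=0)
    # sheet
    thickness = max(1, int(round(2 * rz)))
    if face == "top":
        zs = np.arange(zlo, min(zhi, zlo + thickness - 1) + 1)
    else:
        zs = np.arange(max(zlo, zhi - thickness + 1), zhi + 1)[::-1]
    cy, cx = start[1], start[2]
    vox: list[np.ndarray] = []
    for z in zs:
        ys, xs = np.nonzero(pore[z])
        if ys.size == 0:
            continue
        d2 = (ys - cy) ** 2 + (xs - cx) ** 2
        order = np.argsort(d2, kind="stable")
        cols = np.stack([np.full(ys.size, z), ys[order], xs[order]], axis=1)
        vox.append(cols)
    if not vox:
        return np.empty((0, 3), dtype=int)
    # ordered by (z distance from the face, radial rank): fill the face first
    return np.concatenate(vox, axis=0)


def generate_tissue_mask(
    scaffold_mask: np.ndarray,
    tissue: TissueModel,
    acq: AcquisitionModel,
    geometry: ScaffoldGeometry,
    seed: int,
) -> np.ndarray:
    """Place tissue structures in the pore space to hit the per-section
    occupancy targets.

    Pore space is the counting ROI (scaffold outer ring) minus scaffold
    voxels; the achieved occupancy per section is exact to one voxel because
    the last structure is truncated in its compactness order.  Deterministic
    for a given seed; tissue never overlaps scaffold.
    """
    rng = np.random.default_rng([int(seed), _TISSUE_STREAM])
    roi2d = scaffold_roi(geometry, acq).mask(scaffold_mask.shape[1:])
    sections = section_ranges(scaffold_mask)
    pore_all = roi2d[None, :, :] & ~scaffold_mask
    tissue_mask = np.zeros_like(scaffold_mask)

    rx = tissue.component_scale / 2.0 / acq.pixel_size
    rz = tissue.component_scale / 2.0 / acq.slice_thickness

    for name in SECTION_ORDER:
        frac = float(tissue.target_occupancy_by_section.get(name, 0.0))
        if frac == 0.0:
            continue
        zlo, zhi = sections[name]
        pore = np.zeros_like(pore_all)
        pore[zlo : zhi + 1] = pore_all[zlo : zhi + 1]
        pore_count = int(pore.sum())
        target = int(round(frac * pore_count))
        if target == 0:
            continue
        pore_idx = np.argwhere(pore)
        placed = 0
        stalls = 0
        while placed < target:
            if stalls > 200:
                achieved = placed / pore_count
                raise RuntimeError(
                    f"cannot reach occupancy {frac:.4f} in section {name!r} with "
                    f"morphology {tissue.morphology!r} at scale "
                    f"{tissue.component_scale} mm; achievable maximum ~{achieved:.4f}"
                )
            vox = _structure_voxels(
                tissue.morphology,
                (rx, rz),
                pore,
                pore_idx,
                rng,
                zlo,
                zhi,
                face="top" if name == "top" else "bottom",
            )
            if vox.shape[0] == 0:
                stalls += 1
                continue
            # drop duplicate voxels (overlapping stamps), keeping first-seen order
            _, first = np.unique(vox, axis=0, return_index=True)
            vox = vox[np.sort(first)]
            z, y, x = vox[:, 0], vox[:, 1], vox[:, 2]
            keep = pore[z, y, x] & ~tissue_mask[z, y, x]
            vox = vox[keep]
            if vox.shape[0] == 0:
                stalls += 1
                continue
            need = target - placed
            vox = vox[:need]
            tissue_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            placed += vox.shape[0]
            stalls = 0
    return tissue_mask


# ---------------------------------------------------------------------------
# rendering


def bias_field(acq: AcquisitionModel) -> np.ndarray:
    """Multiplicative intensity field ``1 + a*b`` of shape (nz, n, n).

    ``b`` is a seeded low-order 2D polynomial (z-independent, matching a
    coil profile that varies little across the thin stack) plus an optional
    3D Gaussian random field of the configured length scale, normalized so
    its extremes over the tube region are exactly -1 and +1.
    """
    n, nz = acq.matrix_size, acq.n_slices
    if acq.bias_amplitude == 0.0:
        return np.ones((nz, n, n))
    rng = np.random.default_rng([int(acq.seed), _BIAS_STREAM])
    u = np.linspace(-1.0, 1.0, n)
    uu, vv = np.meshgrid(u, u)
    c = rng.uniform(-1.0, 1.0, size=5)
    poly = c[0] * uu + c[1] * vv + c[2] * uu * vv + c[3] * uu**2 + c[4] * vv**2
    raw = np.broadcast_to(poly, (nz, n, n)).astype(float).copy()
    if acq.bias_grf_weight > 0.0:
        sigma_xy = acq.bias_length_scale / acq.pixel_size
        sigma_z = acq.bias_length_scale / acq.slice_thickness
        white = rng.normal(size=(nz, n, n))
        grf = ndimage.gaussian_filter(white, sigma=(sigma_z, sigma_xy, sigma_xy))
        scale = np.max(np.abs(grf))
        if scale > 0:
            raw += acq.bias_grf_weight * grf / scale
    tube = tube_roi(acq).mask((n, n))
    vals = raw[:, tube]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        return np.ones((nz, n, n))
    b = 2.0 * (raw - lo) / (hi - lo) - 1.0
    return 1.0 + acq.bias_amplitude * b


def render_stack(
    scaffold_mask: np.ndarray,
    tissue_mask: np.ndarray,
    acq: AcquisitionModel,
) -> ImageStack:
    """Render class masks into an MRI-like intensity stack.

    Intensity = class level x bias field + noise, clipped to the bit-depth
    range.  Liquid fills the tube; air/glass outside the tube sits near zero
    signal.  The first and last slices contain no scaffold or tissue by
    construction of the masks.
    """
    if scaffold_mask.shape != tissue_mask.shape:
        raise ValueError("scaffold and tissue masks must share a shape")
    if (scaffold_mask & tissue_mask).any():
        raise ValueError("scaffold and tissue masks must be disjoint")
    nz, ny, nx = scaffold_mask.shape
    if (nz, ny, nx) != (acq.n_slices, acq.matrix_size, acq.matrix_size):
        raise ValueError("mask shape does not match the acquisition grid")

    levels = acq.levels
    tube = tube_roi(acq).mask((ny, nx))
    img = np.full((nz, ny, nx), acq.background_level, dtype=float)
    img[:, tube] = levels["liquid"]
    img[scaffold_mask] = levels["scaffold"]
    img[tissue_mask] = levels["tissue"]

    img = img * bias_field(acq)

    rng = np.random.default_rng([int(acq.seed), _NOISE_STREAM])
    if acq.noise_sigma > 0:
        if acq.noise_model == "gaussian":
            img = img + rng.normal(0.0, acq.noise_sigma, size=img.shape)
        else:  # rician: magnitude of complex signal + iid gaussian channels
            n1 = rng.normal(0.0, acq.noise_sigma, size=img.shape)
            n2 = rng.normal(0.0, acq.noise_sigma, size=img.shape)
            img = np.hypot(img + n1, n2)

    img = np.clip(img, 0.0, acq.max_value)
    dtype = np.uint8 if acq.bit_depth == 8 else np.uint16
    data = np.round(img).astype(dtype)
    return ImageStack(
        data=data,
        pixel_size=acq.pixel_size,
        slice_thickness=acq.slice_thickness,
        bit_depth=acq.bit_depth,
    )


# ---------------------------------------------------------------------------
# bundle


@dataclass
class PhantomResult:
    """A rendered phantom plus its complete ground truth."""

    stack: ImageStack
    scaffold_mask: np.ndarray
    tissue_mask: np.ndarray
    roi: CircularROI  # counting ROI (scaffold outer ring)
    tube: CircularROI  # liquid tube circle (what fit_roi recovers)
    sections: Dict[str, Tuple[int, int]]
    achieved_occupancy: Dict[str, float]
    geometry: ScaffoldGeometry
    tissue: TissueModel
    acquisition: AcquisitionModel

    def pore_mask(self) -> np.ndarray:
        roi2d = self.roi.mask(self.scaffold_mask.shape[1:])
        return roi2d[None, :, :] & ~self.scaffold_mask


def _achieved_occupancy(
    tissue_mask: np.ndarray,
    scaffold_mask: np.ndarray,
    roi2d: np.ndarray,
    sections: Mapping[str, Tuple[int, int]],
) -> Dict[str, float]:
    pore = roi2d[None, :, :] & ~scaffold_mask
    out = {}
    for name, (lo, hi) in sections.items():
        p = int(pore[lo : hi + 1].sum())
        t = int((tissue_mask[lo : hi + 1] & pore[lo : hi + 1]).sum())
        out[name] = t / p if p else 0.0
    return out


def generate_phantom(
    geometry: Optional[ScaffoldGeometry] = None,
    tissue: Optional[TissueModel] = None,
    acquisition: Optional[AcquisitionModel] = None,
) -> PhantomResult:
    """Generate a complete phantom (scaffold + tissue + rendered stack).

    All randomness (tissue placement, bias field, noise) derives from
    ``acquisition.seed`` through independent sub-streams, so a phantom is
    fully reproducible from its parameter record.
    """
    geometry = geometry or ScaffoldGeometry()
    tissue = tissue or TissueModel()
    acquisition = acquisition or AcquisitionModel()
    scaffold_mask = generate_scaffold_mask(geometry, acquisition)
    if scaffold_mask.any():
        sections = section_ranges(scaffold_mask)
        tissue_mask = generate_tissue_mask(
            scaffold_mask, tissue, acquisition, geometry, seed=acquisition.seed
        )
    else:
        sections = split_into_sections(1, acquisition.n_slices - 2)
        tissue_mask = np.zeros_like(scaffold_mask)
    stack = render_stack(scaffold_mask, tissue_mask, acquisition)
    roi = scaffold_roi(geometry, acquisition)
    roi2d = roi.mask(scaffold_mask.shape[1:])
    return PhantomResult(
        stack=stack,
        scaffold_mask=scaffold_mask,
        tissue_mask=tissue_mask,
        roi=roi,
        tube=tube_roi(acquisition),
        sections=sections,
        achieved_occupancy=_achieved_occupancy(tissue_mask, scaffold_mask, roi2d, sections),
        geometry=geometry,
        tissue=tissue,
        acquisition=acquisition,
    )


def generate_bare_phantom(
    geometry: Optional[ScaffoldGeometry] = None,
    acquisition: Optional[AcquisitionModel] = None,
) -> PhantomResult:
    """Phantom of a bare (cell-free) scaffold — the threshold-calibration
    control."""
    empty = TissueModel(target_occupancy_by_section={"top": 0.0, "middle": 0.0, "bottom": 0.0})
    return generate_phantom(geometry=geometry, tissue=empty, acquisition=acquisition)
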
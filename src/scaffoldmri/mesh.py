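"""Triangulated surface models of tissue and scaffold volumes.

Binary volumes are surfaced with marching cubes (optionally after integer
downsampling — "resampling factor" — to get a coarser mesh), expressed in
physical millimetres, and smoothed with the two-coefficient Taubin filter,
which alternates a positive (lambda) and a negative (mu) Laplacian step so
that, unlike plain Laplacian smoothing, the object does not shrink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import trimesh
from scipy import sparse
from skimage.measure import block_reduce, marching_cubes as _skimage_marching_cubes

__all__ = [
    "SurfaceMesh",
    "marching_cubes",
    "taubin_smooth",
    "laplacian_smooth",
    "assemble_model",
    "save_mesh",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface in physical coordinates (mm).

    ``vertices`` are (n, 3) points ordered (x, y, z); ``faces`` index into
    them.  ``spacing`` records the (dz, dy, dx) voxel spacing of the source
    volume so meshes from different frames are never silently combined.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = "tissue"
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def volume(self) -> float:
        """Enclosed volume (mm^3) by signed tetrahedron summation."""
        return 0.0 if self.is_empty else float(self.to_trimesh().volume)


def marching_cubes(
    volume: np.ndarray,
    resample_factor: int = 1,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    label: str = "tissue",
) -> SurfaceMesh:
    """Isosurface (level 0.5) of a binary volume in physical mm.

    ``resample_factor`` f > 1 downsamples the volume by f along every axis
    (block mean, re-binarized at 0.5) before surfacing, yielding a coarser
    mesh.  The volume is padded with one empty voxel shell so every
    component is closed.  An empty volume yields an empty mesh.
    """
    if resample_factor < 1:
        raise ValueError("resample_factor must be >= 1")
    vol = np.asarray(volume, dtype=bool)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    eff = tuple(s * resample_factor for s in spacing)
    if resample_factor > 1:
        vol = block_reduce(vol.astype(float), (resample_factor,) * 3, np.mean) >= 0.5
    if not vol.any():
        return SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64), label, spacing)
    padded = np.pad(vol, 1).astype(np.uint8)
    verts, faces, _normals, _ = _skimage_marching_cubes(padded, level=0.5, spacing=eff)
    verts = verts - np.asarray(eff)  # undo the one-voxel pad offset
    verts = verts[:, ::-1]  # (z, y, x) -> (x, y, z)
    mesh = SurfaceMesh(verts, faces, label, spacing)
    if mesh.volume < 0:  # enforce outward orientation
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def _vertex_adjacency(mesh: SurfaceMesh) -> sparse.csr_matrix:
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(rows.size)
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2).tocsr()
    adj.data[:] = 1.0  # collapse duplicate edges
    return adj


def _laplacian_steps(mesh: SurfaceMesh, factors, iterations: int) -> SurfaceMesh:
    adj = _vertex_adjacency(mesh)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1.0
    inv_deg = sparse.diags(1.0 / degree)
    verts = mesh.vertices.copy()
    for _ in range(iterations):
        for factor in factors:
            verts = verts + factor * (inv_deg @ (adj @ verts) - verts)
    return SurfaceMesh(verts, mesh.faces.copy(), mesh.label, mesh.spacing)


def taubin_smooth(
    mesh: SurfaceMesh,
    lam: float = 0.5,
    mu: float = -0.53,
    iterations: int = 10,
) -> SurfaceMesh:
    """Non-shrinking Taubin smoothing (uniform Laplacian weights).

    Each iteration applies a shrinking step of weight ``lam`` followed by an
    inflating step of weight ``mu``; the pass-band condition
    ``0 < lam < -mu < 1`` keeps low frequencies (hence the enclosed volume)
    nearly unchanged.  Connectivity and vertex/face counts are untouched.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not (0.0 < lam < -mu < 1.0):
        raise ValueError(
            f"invalid Taubin pair (lambda={lam}, mu={mu}): need 0 < lambda < -mu < 1"
        )
    if iterations == 0 or mesh.is_empty:
        return SurfaceMesh(
            mesh.vertices.copy(), mesh.faces.copy(), mesh.label, mesh.spacing
        )
    return _laplacian_steps(mesh, (lam, mu), iterations)


def laplacian_smooth(mesh: SurfaceMesh, lam: float = 0.5, iterations: int = 10) -> SurfaceMesh:
    """Plain (shrinking) Laplacian smoothing — the control Taubin improves on."""
    if iterations == 0 or mesh.is_empty:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy(), mesh.label, mesh.spacing)
    return _laplacian_steps(mesh, (lam,), iterations)


def assemble_model(
    tissue_mesh: Optional[SurfaceMesh], scaffold_mesh: Optional[SurfaceMesh]
) -> trimesh.Scene:
    """Combine tissue and scaffold meshes into one multi-object scene,
    keeping the labels as separate named objects."""
    meshes = [m for m in (tissue_mesh, scaffold_mesh) if m is not None and not m.is_empty]
    spacings = {m.spacing for m in meshes}
    if len(spacings) > 1:
        raise ValueError(f"meshes come from different voxel frames: {spacings}")
    scene = trimesh.Scene()
    for m in meshes:
        scene.add_geometry(m.to_trimesh(), node_name=m.label, geom_name=m.label)
    return scene


def save_mesh(mesh: SurfaceMesh, path) -> None:
    """Export a surface mesh as PLY or STL (by file extension)."""
    mesh.to_trimesh().export(str(path))
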
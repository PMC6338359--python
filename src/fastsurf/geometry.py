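"""Label-volume and triangle-mesh geometry substrate.

All geometry lives in world millimetres.  A :class:`LabelVolume` couples a
binary occupancy grid with its NIfTI voxel-index -> world-mm affine (0-based
voxel-centre convention); meshes are :class:`trimesh.Trimesh` objects whose
vertices are world-mm coordinates.  Surfaces are extracted from label volumes
with topology-correct (Lewiner) marching cubes at the 0.5 iso-level of the
binary field, so they are watertight by construction and enclose the
foreground.

Volumes are computed by the divergence theorem over faces; point containment
uses ray-crossing parity along +z with a half-open (top-left) rasterisation
rule on projected triangles so that a ray grazing a shared edge is counted
exactly once.  Points lying on the surface (within tolerance) count as
inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import (
    EmptySegmentation,
    InvalidTransform,
    MultiComponentError,
    OpenSurfaceError,
)

__all__ = [
    "LabelVolume",
    "AffineTransform",
    "mesh_from_labels",
    "mesh_volume",
    "contains_points",
    "apply_affine",
    "load_mesh",
    "save_mesh",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LabelVolume:
    """Binary occupancy grid with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data
        3D array; any values > 0 are coerced to foreground (1).
    affine
        4x4 homogeneous transform mapping 0-based voxel-centre indices to
        world mm (NIfTI convention).
    """

    data: np.ndarray
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {data.shape}")
        self.data = (data > 0).astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise InvalidTransform("label volume affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def validate(self) -> "LabelVolume":
        """Check the single-component invariant required by the
        reconstruction pipeline; returns self for chaining."""
        if self.n_foreground == 0:
            raise EmptySegmentation("label volume has no foreground voxels")
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        _, n_comp = ndimage.label(self.data, structure=structure)
        if n_comp != 1:
            raise MultiComponentError(
                f"foreground has {n_comp} 26-connected components; expected 1"
            )
        return self

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel-centre indices to (N,3) world-mm points."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))


@dataclass
class AffineTransform:
    """4x4 homogeneous world-mm -> world-mm transform (e.g. a FLIRT matrix
    exported after registration)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransform("transform must be a 4x4 matrix")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise InvalidTransform("last row of transform must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise InvalidTransform("transform linear part is singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_text(cls, path: str | Path) -> "AffineTransform":
        """Read a FLIRT-style whitespace-delimited 4x4 matrix."""
        return cls(np.loadtxt(str(path)))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        with open(path) as fh:
            return cls(np.asarray(json.load(fh)["matrix"], dtype=float))

    def to_text(self, path: str | Path) -> None:
        np.savetxt(str(path), self.matrix, fmt="%.12g")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def mesh_from_labels(vol: LabelVolume, iso: float = 0.5) -> trimesh.Trimesh:
    """Extract the closed iso-surface of a binary label volume.

    Marching cubes (Lewiner topology-correct variant) runs on the binary
    field padded by one zero voxel so surfaces touching the array border
    still close.  Vertices are mapped through the volume affine into world
    mm and faces are oriented outward (positive enclosed volume).
    """
    if not 0.0 < iso < 1.0:
        raise ValueError("iso level must lie in (0, 1)")
    vol.validate()
    padded = np.pad(vol.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso, method="lewiner")
    verts = verts - 1.0  # undo padding offset, back to voxel-index space
    world = vol.voxel_to_world(verts)
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=True, validate=True)
    if _signed_volume(mesh) < 0:
        mesh.invert()
    return mesh


def _signed_volume(mesh: trimesh.Trimesh) -> float:
    tri = mesh.triangles
    return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)


def _require_closed(mesh: trimesh.Trimesh) -> None:
    if not (mesh.is_watertight and mesh.is_winding_consistent):
        raise OpenSurfaceError("operation requires a watertight, consistently wound mesh")


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume in mm^3 via the divergence theorem over faces.

    Positive for outward-oriented closed meshes, translation invariant.
    """
    _require_closed(mesh)
    return _signed_volume(mesh)


def apply_affine(mesh: trimesh.Trimesh, t: AffineTransform) -> trimesh.Trimesh:
    """Map mesh vertices through a world->world affine.

    If the linear part is orientation-reversing (negative determinant) the
    face winding is flipped so normals stay outward.
    """
    m = t.matrix
    verts = mesh.vertices @ m[:3, :3].T + m[:3, 3]
    faces = mesh.faces.copy()
    if np.linalg.det(m[:3, :3]) < 0:
        faces = faces[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# -- point containment -------------------------------------------------------


def contains_points(
    mesh: trimesh.Trimesh, points: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Test which world-mm points lie inside a closed mesh.

    Ray-crossing parity along +z.  Projected triangles are tested with a
    half-open top-left rule so a ray through a shared edge or vertex crosses
    the surface exactly once; points within ``tol`` (scaled by mesh size) of
    the surface count as inside.
    """
    _require_closed(mesh)
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    scale = float(np.max(mesh.extents)) if len(mesh.vertices) else 1.0
    ztol = max(tol * max(scale, 1.0), 1e-12)

    inside = np.zeros(len(pts), dtype=bool)
    lo, hi = mesh.bounds
    in_box = np.all((pts >= lo - ztol) & (pts <= hi + ztol), axis=1)
    if not in_box.any():
        return inside

    tri = mesh.triangles  # (F, 3, 3)
    binner = _TriangleBins(tri)

    idx = np.flatnonzero(in_box)
    sub = pts[idx]
    # grid-sampled points share (x, y) columns; classify one column at a time
    cols, col_inv = np.unique(sub[:, :2], axis=0, return_inverse=True)
    order = np.argsort(col_inv, kind="stable")
    bounds = np.searchsorted(col_inv[order], np.arange(len(cols) + 1))
    for c in range(len(cols)):
        members = order[bounds[c] : bounds[c + 1]]
        if members.size == 0:
            continue
        x, y = cols[c]
        cand = binner.candidates(x, y)
        if cand.size == 0:
            continue
        z_par, z_closed = _column_crossings(tri[cand], x, y)
        zq = sub[members, 2]
        res = np.zeros(len(zq), dtype=bool)
        if z_par.size:
            res = (zq[:, None] < z_par[None, :] - ztol).sum(axis=1) % 2 == 1
        if z_closed.size:
            res |= np.any(np.abs(zq[:, None] - z_closed[None, :]) <= ztol, axis=1)
        inside[idx[members]] = res
    return inside


class _TriangleBins:
    """Uniform 2D binning of triangle xy-bounding boxes for ray broad-phase."""

    def __init__(self, tri: np.ndarray, target_cells: int = 64):
        xy = tri[:, :, :2]
        self.lo = xy.reshape(-1, 2).min(axis=0)
        self.hi = xy.reshape(-1, 2).max(axis=0)
        span = np.maximum(self.hi - self.lo, 1e-12)
        self.n = np.minimum(target_cells, np.maximum(1, np.ceil(span).astype(int) * 4))
        self.cell = span / self.n
        tlo = np.clip(((xy.min(axis=1) - self.lo) / self.cell).astype(int), 0, self.n - 1)
        thi = np.clip(((xy.max(axis=1) - self.lo) / self.cell).astype(int), 0, self.n - 1)
        buckets: dict[tuple[int, int], list[int]] = {}
        for f in range(len(tri)):
            for i in range(tlo[f, 0], thi[f, 0] + 1):
                for j in range(tlo[f, 1], thi[f, 1] + 1):
                    buckets.setdefault((i, j), []).append(f)
        self._buckets = {k: np.asarray(v, dtype=int) for k, v in buckets.items()}
        self._empty = np.empty(0, dtype=int)

    def candidates(self, x: float, y: float) -> np.ndarray:
        ij = ((np.array([x, y]) - self.lo) / self.cell).astype(int)
        if np.any(ij < 0) or np.any(ij >= self.n):
            return self._empty
        return self._buckets.get((int(ij[0]), int(ij[1])), self._empty)


def _column_crossings(tri: np.ndarray, x: float, y: float):
    """Surface crossing depths of the vertical line through (x, y).

    Returns ``(z_parity, z_closed)``: crossing z-values under the half-open
    top-left rule (each shared edge counted once, used for parity) and under
    the closed containment rule (used for on-surface detection).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    # signed area of projected triangle (z of cross product)
    d = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    nondeg = np.abs(d) > 1e-14
    if not nondeg.any():
        return np.empty(0), np.empty(0)
    a, b, c, d = a[nondeg], b[nondeg], c[nondeg], d[nondeg]
    # canonicalise projected winding to CCW
    flip = d < 0
    b_, c_ = b.copy(), c.copy()
    b_[flip], c_[flip] = c[flip], b[flip]
    b, c = b_, c_
    d = np.abs(d)

    def edge_fn(p0, p1):
        e = (p1[:, 0] - p0[:, 0]) * (y - p0[:, 1]) - (p1[:, 1] - p0[:, 1]) * (
            x - p0[:, 0]
        )
        # top-left fill rule for CCW triangles
        dx = p1[:, 0] - p0[:, 0]
        dy = p1[:, 1] - p0[:, 1]
        topleft = (dy < 0) | ((dy == 0) & (dx < 0))
        return e, (e > 0) | ((e == 0) & topleft), e >= 0

    e0, open0, closed0 = edge_fn(a, b)
    e1, open1, closed1 = edge_fn(b, c)
    e2, open2, closed2 = edge_fn(c, a)
    hit_open = open0 & open1 & open2
    hit_closed = closed0 & closed1 & closed2
    # barycentric z on the triangle plane: weights are opposite sub-areas
    z = (e1 * a[:, 2] + e2 * b[:, 2] + e0 * c[:, 2]) / d
    return z[hit_open], z[hit_closed]


# ---------------------------------------------------------------------------
# mesh file I/O
# ---------------------------------------------------------------------------


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a PLY/OBJ/STL triangle mesh (world-mm vertices)."""
    mesh = trimesh.load(str(path), force="mesh")
    return trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))
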
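"""Planar contour extraction, resampling and sparse selection.

A contour is a closed tracing of the structure's perimeter on a single
slice.  Contours are extracted at the 0.5 level of each binary slice
(sub-voxel, linearly interpolated — consistent with the 0.5 iso-level used
for marching cubes), canonicalised to counter-clockwise winding viewed down
the +slicing axis, and resampled to a fixed number of points at equal
arc-length spacing.  Sparse "delineated" subsets keep the two extreme
slices plus evenly spaced interior slices, emulating partial manual
outlining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import (
    DegenerateContourError,
    MultiContourSliceError,
    TooFewContours,
    TooManyContours,
)
from .geometry import LabelVolume

__all__ = [
    "PlanarContour",
    "ContourStack",
    "extract_contours",
    "resample_contour",
    "resample_stack",
    "select_sparse",
    "load_stack",
    "save_stack",
]

_AXIS_NAMES = {"sagittal": 0, "coronal": 1, "axial": 2}


def _resolve_axis(axis) -> int:
    if isinstance(axis, str):
        try:
            return _AXIS_NAMES[axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis name {axis!r}") from None
    axis = int(axis)
    if axis not in (0, 1, 2):
        raise ValueError("axis index must be 0, 1 or 2")
    return axis


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (u, v) for a unit normal.

    u is the first standard basis vector not parallel to the normal,
    Gram-Schmidt projected into the plane; v = normal x u.  For a +z normal
    this yields u = +x, v = +y.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    for e in np.eye(3):
        u = e - np.dot(e, n) * n
        if np.linalg.norm(u) > 1e-8:
            u = u / np.linalg.norm(u)
            break
    v = np.cross(n, u)
    return u, v


@dataclass
class PlanarContour:
    """Closed planar polyline on one slice, stored open (last != first).

    Points are (K, 3) world mm, all sharing the same coordinate along the
    stack's slicing axis.
    """

    slice_index: int
    plane_coord: float
    points: np.ndarray
    role: str = "known"  # known | intermediate

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("contour points must be (K>=3, 3)")
        if self.role not in ("known", "intermediate"):
            raise ValueError(f"invalid role {self.role!r}")
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def uv(self, normal: np.ndarray) -> np.ndarray:
        """In-plane (K, 2) coordinates in the canonical plane basis."""
        u, v = plane_basis(normal)
        return np.column_stack([self.points @ u, self.points @ v])

    def signed_area(self, normal: np.ndarray) -> float:
        """Shoelace area in the plane; positive for CCW viewed down +normal."""
        uv = self.uv(normal)
        x, y = uv[:, 0], uv[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def canonicalize(self, normal: np.ndarray) -> "PlanarContour":
        """CCW winding viewed down +normal; start at the point of maximal u
        (ties broken by maximal v)."""
        pts = self.points
        if self.signed_area(normal) < 0:
            pts = pts[::-1]
        c = replace(self, points=pts)
        uv = c.uv(normal)
        order = np.lexsort((uv[:, 1], uv[:, 0]))
        start = order[-1]
        return replace(c, points=np.roll(pts, -start, axis=0))


@dataclass
class ContourStack:
    """Ordered planar contours along a slicing axis.

    ``axis`` is the world-space unit normal of the slice planes;
    ``points_per_contour`` and ``n_intermediate`` carry the reconstruction
    defaults (100 points, 3 intermediate rings per gap).
    """

    axis: np.ndarray
    contours: list
    points_per_contour: int = 100
    n_intermediate: int = 3

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm < 1e-12:
            raise ValueError("slicing axis must be a nonzero vector")
        self.axis = self.axis / norm
        coords = [c.plane_coord for c in self.contours]
        if any(b <= a for a, b in zip(coords, coords[1:])):
            raise ValueError("contour plane coordinates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.contours)

    def validate(self) -> "ContourStack":
        if len(self.contours) < 2:
            raise TooFewContours("stack needs at least two contours")
        if self.contours[0].role != "known" or self.contours[-1].role != "known":
            raise ValueError("extreme-slice contours must be known")
        return self

    @property
    def known(self) -> list:
        return [c for c in self.contours if c.role == "known"]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_contours(vol: LabelVolume, axis="axial") -> ContourStack:
    """Trace one closed contour per occupied slice of a label volume.

    Each binary slice is traced at the 0.5 level with sub-voxel linear
    interpolation, mapped to world mm, and canonicalised.  A slice whose
    foreground has multiple components or internal holes raises
    :class:`MultiContourSliceError` (one contour per slice is a stated
    limitation of the method).
    """
    ax = _resolve_axis(axis)
    vol.validate()
    axis_world = vol.affine[:3, ax]
    axis_unit = axis_world / np.linalg.norm(axis_world)
    inplane = [a for a in range(3) if a != ax]

    occupied = np.flatnonzero(vol.data.sum(axis=tuple(inplane)) > 0)
    contours = []
    struct2d = np.ones((3, 3), dtype=bool)
    for k in occupied:
        sl = np.take(vol.data, k, axis=ax)
        _, n_comp = ndimage.label(sl, structure=struct2d)
        if n_comp != 1 or ndimage.binary_fill_holes(sl).sum() != sl.sum():
            raise MultiContourSliceError(
                f"slice {k} along axis {ax} has multiple contours or holes"
            )
        padded = np.pad(sl.astype(np.float32), 1)
        curves = measure.find_contours(padded, 0.5)
        if len(curves) != 1:
            raise MultiContourSliceError(
                f"slice {k} along axis {ax} traced {len(curves)} curves; expected 1"
            )
        rc = curves[0][:-1] - 1.0  # drop duplicated endpoint, undo padding
        ijk = np.zeros((len(rc), 3))
        ijk[:, ax] = k
        ijk[:, inplane[0]] = rc[:, 0]
        ijk[:, inplane[1]] = rc[:, 1]
        world = vol.voxel_to_world(ijk)
        c = PlanarContour(
            slice_index=int(k),
            plane_coord=float(world[0] @ axis_unit),
            points=world,
            role="known",
        ).canonicalize(axis_unit)
        contours.append(c)
    return ContourStack(axis=axis_unit, contours=contours)


def resample_contour(c: PlanarContour, n_points: int, normal=None) -> PlanarContour:
    """Resample a closed contour to ``n_points`` at equal arc-length spacing.

    The contour is first canonicalised (CCW, start at max-u point) so the
    first output point coincides with the canonical start; total perimeter
    is preserved to within one segment length.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if normal is None:
        normal = _infer_normal(c.points)
    c = c.canonicalize(normal)
    pts = np.vstack([c.points, c.points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 1e-12:
        raise DegenerateContourError("contour has zero perimeter")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * (total / n_points)
    new = np.column_stack([np.interp(targets, s, pts[:, d]) for d in range(3)])
    return replace(c, points=new)


def _infer_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of a planar point set via the constant coordinate axis,
    falling back to a cross-product estimate."""
    span = points.max(axis=0) - points.min(axis=0)
    flat = np.argmin(span)
    if span[flat] < 1e-9:
        n = np.zeros(3)
        n[flat] = 1.0
        return n
    centred = points - points.mean(axis=0)
    _, _, vh = np.linalg.svd(centred, full_matrices=False)
    return vh[-1]


def resample_stack(stack: ContourStack, n_points: int | None = None) -> ContourStack:
    """Resample every contour of a stack to the stack's point count."""
    n = n_points if n_points is not None else stack.points_per_contour
    contours = [resample_contour(c, n, normal=stack.axis) for c in stack.contours]
    return ContourStack(
        axis=stack.axis,
        contours=contours,
        points_per_contour=n,
        n_intermediate=stack.n_intermediate,
    )


def select_sparse(stack: ContourStack, n_known: int) -> ContourStack:
    """Keep ``n_known`` contours at evenly spaced slices.

    Always retains the first and last slices; interior kept indices are
    ``round(i * (S - 1) / (k - 1))``.  Dropped slices are discarded — the
    fairing stage regenerates intermediate rings itself.
    """
    S = len(stack.contours)
    if n_known < 4:
        raise TooFewContours("at least four contours are required")
    if n_known > S:
        raise TooManyContours(f"requested {n_known} contours from {S} slices")
    pos = np.arange(n_known) * (S - 1) / (n_known - 1)
    keep = np.unique(np.floor(pos + 0.5).astype(int))
    if len(keep) < 4:
        raise TooFewContours("even-interval selection collapsed below four contours")
    contours = [replace(stack.contours[j], role="known") for j in keep]
    return ContourStack(
        axis=stack.axis,
        contours=contours,
        points_per_contour=stack.points_per_contour,
        n_intermediate=stack.n_intermediate,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_stack(stack: ContourStack, path: str | Path) -> None:
    payload = {
        "axis": stack.axis.tolist(),
        "points_per_contour": stack.points_per_contour,
        "n_intermediate": stack.n_intermediate,
        "contours": [
            {
                "slice_index": c.slice_index,
                "plane_coord": c.plane_coord,
                "role": c.role,
                "points": c.points.tolist(),
            }
            for c in stack.contours
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_stack(path: str | Path) -> ContourStack:
    payload = json.loads(Path(path).read_text())
    contours = [
        PlanarContour(
            slice_index=int(c["slice_index"]),
            plane_coord=float(c["plane_coord"]),
            points=np.asarray(c["points"], dtype=float),
            role=c["role"],
        )
        for c in payload["contours"]
    ]
    stack = ContourStack(
        axis=np.asarray(payload["axis"], dtype=float),
        contours=contours,
        points_per_contour=int(payload["points_per_contour"]),
        n_intermediate=int(payload["n_intermediate"]),
    )
    return stack.validate()


def stack_summary(stack: ContourStack):
    """Per-contour perimeter and in-plane area as a pandas DataFrame."""
    import pandas as pd

    rows = [
        {
            "slice_index": c.slice_index,
            "plane_coord": c.plane_coord,
            "role": c.role,
            "n_points": c.n_points,
            "perimeter_mm": c.perimeter(),
            "area_mm2": abs(c.signed_area(stack.axis)),
        }
        for c in stack.contours
    ]
    return pd.DataFrame(rows)
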
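"""Mesh-based agreement and longitudinal change metrics.

Overlap is measured directly on surfaces: a fine regular grid encloses both
meshes and the Jaccard index is approximated as the ratio of grid points
inside both surfaces to grid points inside either,

    Jacc(A, B) ~= N_{A and B} / N_{A or B},

with Dice related by D = 2J / (1 + J).  Volume agreement uses the
cross-sectional percentage volume difference

    PVD(A, B) = 2 (V_A - V_B) / (V_A + V_B) * 100

and longitudinal change (atrophy when positive) the percentage volume
change from baseline to follow-up

    PVC(A, B) = (V_A - V_B) / V_A * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import DomainError, GridError
from .geometry import AffineTransform, apply_affine, contains_points, mesh_volume

__all__ = [
    "OverlapGrid",
    "MetricReport",
    "jaccard_grid",
    "dice_from_jaccard",
    "jaccard_from_dice",
    "pvd",
    "pvc",
    "compare",
]

DEFAULT_SPACING = 0.5  # mm; half the smallest default phantom voxel size


@dataclass
class OverlapGrid:
    """Grid-sampling counts over the padded joint bounding box."""

    spacing: float
    origin: np.ndarray
    shape: tuple
    n_a: int
    n_b: int
    n_intersection: int

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_intersection

    @property
    def jaccard(self) -> float:
        if self.n_union == 0:
            raise GridError("empty union: no grid point inside either mesh")
        return self.n_intersection / self.n_union


@dataclass
class MetricReport:
    jaccard: float
    dice: float
    pvd: float
    pvc: float
    volume_a: float
    volume_b: float
    spacing: float

    def to_dict(self) -> dict:
        return {
            "jaccard": self.jaccard,
            "dice": self.dice,
            "pvd_percent": self.pvd,
            "pvc_percent": self.pvc,
            "volume_a_mm3": self.volume_a,
            "volume_b_mm3": self.volume_b,
            "grid_spacing_mm": self.spacing,
        }


def jaccard_grid(
    A: trimesh.Trimesh, B: trimesh.Trimesh, spacing: float = DEFAULT_SPACING
) -> OverlapGrid:
    """Grid-approximated overlap counts of two closed meshes.

    The grid is anchored at the joint bounding box minimum padded by twice
    the spacing, so the counts are exactly symmetric in (A, B).
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    lo = np.minimum(A.bounds[0], B.bounds[0]) - 2 * spacing
    hi = np.maximum(A.bounds[1], B.bounds[1]) + 2 * spacing
    counts = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[d] + spacing * np.arange(counts[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    in_a = contains_points(A, pts)
    in_b = contains_points(B, pts)
    grid = OverlapGrid(
        spacing=spacing,
        origin=lo,
        shape=tuple(counts),
        n_a=int(in_a.sum()),
        n_b=int(in_b.sum()),
        n_intersection=int((in_a & in_b).sum()),
    )
    if grid.n_union == 0:
        raise GridError("no grid point inside either mesh; check inputs/spacing")
    return grid


def dice_from_jaccard(j: float) -> float:
    """Dice overlap from a Jaccard index: D = 2J / (1 + J)."""
    if not 0.0 <= j <= 1.0:
        raise DomainError(f"Jaccard index {j} outside [0, 1]")
    return 2.0 * j / (1.0 + j)


def jaccard_from_dice(d: float) -> float:
    """Inverse relation J = D / (2 - D)."""
    if not 0.0 <= d <= 1.0:
        raise DomainError(f"Dice index {d} outside [0, 1]")
    return d / (2.0 - d)


def pvd(v_a: float, v_b: float) -> float:
    """Cross-sectional percentage volume difference (antisymmetric)."""
    if v_a + v_b <= 0:
        raise DomainError("PVD undefined for non-positive total volume")
    return 2.0 * (v_a - v_b) / (v_a + v_b) * 100.0


def pvc(v_baseline: float, v_followup: float) -> float:
    """Longitudinal percentage volume change; positive = shrinkage."""
    if v_baseline <= 0:
        raise DomainError("PVC undefined for non-positive baseline volume")
    return (v_baseline - v_followup) / v_baseline * 100.0


def compare(
    A: trimesh.Trimesh,
    B: trimesh.Trimesh,
    spacing: float = DEFAULT_SPACING,
    transform: AffineTransform | None = None,
) -> MetricReport:
    """Full agreement report between two closed meshes.

    ``transform``, if given, is applied to mesh A first (e.g. a FLIRT
    registration matrix bringing A into B's space).
    """
    if transform is not None:
        A = apply_affine(A, transform)
    grid = jaccard_grid(A, B, spacing=spacing)
    v_a = mesh_volume(A)
    v_b = mesh_volume(B)
    j = grid.jaccard
    return MetricReport(
        jaccard=j,
        dice=dice_from_jaccard(j),
        pvd=pvd(v_a, v_b),
        pvc=pvc(v_a, v_b) if v_a > 0 else float("nan"),
        volume_a=v_a,
        volume_b=v_b,
        spacing=spacing,
    )
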
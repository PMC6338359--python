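"""Surface fairing core: scaffold, graph Laplacian, sparse solve.

The delineated contours are connected into a regular triangulated tube
("scaffold"): between each consecutive pair of known rings a fixed number of
intermediate rings is inserted by linear interpolation (the initial
"parallel" contours), bands between rings are triangulated as quads split
along a fixed diagonal, and the tube is closed with centroid-apex fans at
both ends.  Point correspondence across each gap is the cyclic offset of the
later ring minimising the total squared length of connecting edges, which
removes twist.

On the scaffold's connectivity graph the discrete (umbrella) Laplacian is

    L[n, m] = 1                      if n == m
            = -1 / deg(v_n)          if v_m adjacent to v_n
            = 0                      otherwise

Interpreting edges as equal-stiffness springs and demanding zero net force
at every vertex gives the membrane (minimal-surface) system L x = 0 per
coordinate; squaring the operator gives the thin-plate (curvature
minimising) system L^2 x = 0.  Known vertices are moved to the right-hand
side and the restricted sparse system is solved per coordinate with the
iterative bi-conjugate gradient method, falling back to a direct sparse
factorisation if it fails to converge.  The thin-plate solution is the
FASTSURF reconstruction.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh

from .contours import ContourStack, resample_stack
from .errors import GraphError, ScaffoldError, SolverError
from .geometry import _signed_volume

__all__ = [
    "ScaffoldMesh",
    "FairingSystem",
    "build_scaffold",
    "build_laplacian",
    "solve_fairing",
    "reconstruct",
]

log = logging.getLogger(__name__)

DIRECT_FALLBACK_MAX_UNKNOWNS = 20_000


@dataclass
class ScaffoldMesh:
    """Regular ring-stacked tube with end caps.

    Vertex layout: rings 0..n_rings-1, each with n_points_per_ring vertices,
    followed by the two cap apices (bottom, top).  ``ring_index`` is -1 for
    apices; ``known_mask`` is True for vertices of delineated rings and for
    both apices.
    """

    mesh: trimesh.Trimesh
    ring_index: np.ndarray
    known_mask: np.ndarray
    n_rings: int
    n_points_per_ring: int

    @property
    def n_vertices(self) -> int:
        return len(self.mesh.vertices)


@dataclass
class FairingSystem:
    """Sparse umbrella Laplacian with a known/unknown vertex partition.

    The graph covers the ring vertices of the tube only: cap apices are
    geometric closure, always held fixed, and kept out of the operator so
    the artificial flat cap discs contribute no curvature penalty.
    """

    L: sp.csr_matrix
    known_idx: np.ndarray
    unknown_idx: np.ndarray
    order: int  # 1 = membrane (Laplacian), 2 = thin plate (bi-Laplacian)

    @property
    def matrix(self) -> sp.csr_matrix:
        if self.order == 1:
            return self.L
        return (self.L @ self.L).tocsr()


def _best_cyclic_offset(prev_pts: np.ndarray, next_pts: np.ndarray) -> int:
    """Cyclic shift of ``next_pts`` minimising total squared connecting-edge
    length to ``prev_pts`` (exhaustive over all K offsets)."""
    K = len(prev_pts)
    costs = np.empty(K)
    for o in range(K):
        d = np.roll(next_pts, -o, axis=0) - prev_pts
        costs[o] = np.einsum("ij,ij->", d, d)
    return int(np.argmin(costs))


def build_scaffold(stack: ContourStack) -> ScaffoldMesh:
    """Assemble the closed triangulated scaffold from a contour stack.

    Rings of role ``known`` keep their positions and are flagged fixed;
    ``n_intermediate`` rings per gap are inserted by linear interpolation at
    equal fractions of the gap.  Cap apices sit at the extreme-ring
    centroids and are fixed.
    """
    stack.validate()
    known = stack.known
    if len(known) < 2:
        raise ScaffoldError("scaffold needs at least two known contours")
    counts = {c.n_points for c in stack.contours}
    if len(counts) != 1:
        raise ScaffoldError(f"contours have mismatched point counts: {sorted(counts)}")
    K = counts.pop()
    n_int = int(stack.n_intermediate)
    if n_int < 0:
        raise ScaffoldError("n_intermediate must be >= 0")

    # twist-minimising correspondence: roll each known ring against its
    # aligned predecessor
    aligned = [known[0].points.copy()]
    for c in known[1:]:
        o = _best_cyclic_offset(aligned[-1], c.points)
        aligned.append(np.roll(c.points, -o, axis=0))

    rings: list[np.ndarray] = []
    ring_known: list[bool] = []
    for g in range(len(aligned) - 1):
        a, b = aligned[g], aligned[g + 1]
        rings.append(a)
        ring_known.append(True)
        for j in range(1, n_int + 1):
            f = j / (n_int + 1)
            rings.append((1 - f) * a + f * b)
            ring_known.append(False)
    rings.append(aligned[-1])
    ring_known.append(True)

    R = len(rings)
    verts = np.vstack(rings + [rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    apex_bot, apex_top = R * K, R * K + 1

    i = np.arange(K)
    ip1 = (i + 1) % K
    faces = []
    for r in range(R - 1):
        lo, hi = r * K, (r + 1) * K
        # quad (r,i)-(r,i+1)-(r+1,i+1)-(r+1,i) split along (i,j)->(i+1,j+1)
        faces.append(np.column_stack([lo + i, lo + ip1, hi + ip1]))
        faces.append(np.column_stack([lo + i, hi + ip1, hi + i]))
    faces.append(np.column_stack([np.full(K, apex_bot), ip1, i]))
    top = (R - 1) * K
    faces.append(np.column_stack([np.full(K, apex_top), top + i, top + ip1]))
    faces = np.vstack(faces)

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if _signed_volume(mesh) < 0:
        mesh.invert()

    ring_index = np.repeat(np.arange(R), K)
    ring_index = np.concatenate([ring_index, [-1, -1]])
    known_mask = np.repeat(np.asarray(ring_known, dtype=bool), K)
    known_mask = np.concatenate([known_mask, [True, True]])
    return ScaffoldMesh(
        mesh=mesh,
        ring_index=ring_index,
        known_mask=known_mask,
        n_rings=R,
        n_points_per_ring=K,
    )


def build_laplacian(scaffold: ScaffoldMesh, order: int = 2) -> FairingSystem:
    """Assemble the umbrella Laplacian of the scaffold's ring graph.

    Edges incident to the cap apices are excluded: the caps only close the
    surface, and penalising curvature across a flat centroid fan would pull
    the rings near the ends outward.  Rows therefore satisfy the operator
    structure exactly (diagonal 1, off-diagonals -1/deg, zero row sum).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 (membrane) or 2 (thin plate)")
    mesh = scaffold.mesh
    n_ring = scaffold.n_rings * scaffold.n_points_per_ring
    edges = mesh.edges_unique
    edges = edges[np.all(edges < n_ring, axis=1)]
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_ring, n_ring)
    ).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise GraphError("scaffold graph has isolated vertices")
    inv_deg = sp.diags(1.0 / deg)
    L = (sp.eye(n_ring) - inv_deg @ adj).tocsr()
    known = scaffold.known_mask[:n_ring]
    known_idx = np.flatnonzero(known)
    unknown_idx = np.flatnonzero(~known)
    if known_idx.size == 0:
        raise GraphError("fairing system requires at least one known vertex")
    return FairingSystem(L=L, known_idx=known_idx, unknown_idx=unknown_idx, order=order)


def solve_fairing(system: FairingSystem, scaffold: ScaffoldMesh) -> trimesh.Trimesh:
    """Solve the restricted fairing system and return the faired mesh.

    Per coordinate, rows/columns of known vertices are moved to the
    right-hand side; unknowns are solved with BiCG (relative residual 1e-8,
    warm-started from the linear-interpolation scaffold positions) with a
    sparse-LU fallback.  Known vertex positions are returned untouched.
    """
    u, k = system.unknown_idx, system.known_idx
    verts = scaffold.mesh.vertices.copy()
    if u.size == 0:
        return trimesh.Trimesh(
            vertices=verts, faces=scaffold.mesh.faces.copy(), process=False
        )
    M = system.matrix
    A = M[np.ix_(u, u)].tocsr()
    B = M[np.ix_(u, k)].tocsr()
    t0 = time.perf_counter()
    for d in range(3):
        rhs = -B @ verts[k, d]
        x0 = verts[u, d]
        x, info = spla.bicg(A, rhs, x0=x0, rtol=1e-8, maxiter=10 * A.shape[0])
        resid = np.linalg.norm(A @ x - rhs)
        ok = info == 0 and resid <= 1e-6 * max(np.linalg.norm(rhs), 1.0)
        if not ok:
            if A.shape[0] > DIRECT_FALLBACK_MAX_UNKNOWNS:
                raise SolverError(
                    f"BiCG failed (info={info}, resid={resid:.3g}) and system "
                    f"too large for direct fallback"
                )
            x = spla.spsolve(A.tocsc(), rhs)
            resid = np.linalg.norm(A @ x - rhs)
            if not np.isfinite(resid) or resid > 1e-6 * max(np.linalg.norm(rhs), 1.0):
                raise SolverError(f"direct fallback residual {resid:.3g} too large")
        log.info("fairing solve coord %d: n=%d resid=%.3g", d, A.shape[0], resid)
        verts[u, d] = x
    log.info(
        "fairing solved %d unknowns (order %d) in %.3f s",
        u.size,
        system.order,
        time.perf_counter() - t0,
    )
    return trimesh.Trimesh(
        vertices=verts, faces=scaffold.mesh.faces.copy(), process=False
    )


def reconstruct(
    stack: ContourStack,
    order: int = 2,
    n_intermediate: int | None = None,
    points_per_contour: int | None = None,
) -> trimesh.Trimesh:
    """Complete a sparse contour stack into a closed surface.

    Composition of scaffold construction, Laplacian assembly and the fairing
    solve; ``order=2`` (thin plate / bi-Laplacian) is the FASTSURF
    reconstruction.  Optional overrides replace the stack's stored
    ``n_intermediate`` and ``points_per_contour``.
    """
    if n_intermediate is not None or points_per_contour is not None:
        stack = ContourStack(
            axis=stack.axis,
            contours=list(stack.contours),
            points_per_contour=(
                points_per_contour
                if points_per_contour is not None
                else stack.points_per_contour
            ),
            n_intermediate=(
                n_intermediate if n_intermediate is not None else stack.n_intermediate
            ),
        )
    if any(c.n_points != stack.points_per_contour for c in stack.contours):
        stack = resample_stack(stack)
    scaffold = build_scaffold(stack)
    system = build_laplacian(scaffold, order=order)
    return solve_fairing(system, scaffold)
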
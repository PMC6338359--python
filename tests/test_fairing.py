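"""Scaffold construction, Laplacian assembly, fairing solves."""

import time

import numpy as np
import pytest

from fastsurf import (
    ContourStack,
    PlanarContour,
    build_laplacian,
    build_scaffold,
    mesh_volume,
    reconstruct,
    select_sparse,
    solve_fairing,
)
from fastsurf.errors import ScaffoldError
from tests.conftest import circle_ring


def dense_umbrella(mesh, n_ring):
    """Independent dense Laplacian from brute-force adjacency sets."""
    adj = [set() for _ in range(n_ring)]
    for f in mesh.faces:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            u, v = f[a], f[b]
            if u < n_ring and v < n_ring:
                adj[u].add(v)
                adj[v].add(u)
    L = np.eye(n_ring)
    for n, nbrs in enumerate(adj):
        for m in nbrs:
            L[n, m] = -1.0 / len(nbrs)
    return L


def dense_fairing_solution(scaffold, order):
    """Dense direct-solve oracle for the restricted fairing system."""
    n_ring = scaffold.n_rings * scaffold.n_points_per_ring
    L = dense_umbrella(scaffold.mesh, n_ring)
    M = L @ L if order == 2 else L
    known = scaffold.known_mask[:n_ring]
    u = np.flatnonzero(~known)
    k = np.flatnonzero(known)
    verts = scaffold.mesh.vertices[:n_ring].copy()
    for d in range(3):
        verts[u, d] = np.linalg.solve(M[np.ix_(u, u)], -M[np.ix_(u, k)] @ verts[k, d])
    return verts


class TestBuildScaffold:
    def test_regular_scaffold_counts(self):
        c0 = PlanarContour(0, 0.0, circle_ring(0.0, 5.0, n=100))
        c1 = PlanarContour(4, 4.0, circle_ring(4.0, 5.0, n=100))
        stack = ContourStack([0, 0, 1], [c0, c1], points_per_contour=100, n_intermediate=3)
        s = build_scaffold(stack)
        assert s.n_rings == 5 and s.n_points_per_ring == 100
        assert len(s.mesh.vertices) == 502
        assert s.mesh.is_watertight
        assert s.mesh.euler_number == 2
        # interior-ring vertices have valence 6 in the band triangulation
        graph = [set() for _ in range(len(s.mesh.vertices))]
        for f in s.mesh.faces:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                graph[f[a]].add(f[b])
                graph[f[b]].add(f[a])
        for v in range(100, 400):  # rings 1..3
            assert len(graph[v]) == 6
        assert len(graph[500]) == 100 and len(graph[501]) == 100  # apices

    def test_identical_rings_interpolate_parallel(self, coaxial_stack):
        s = build_scaffold(coaxial_stack)
        K = s.n_points_per_ring
        for r, z in enumerate([0.0, 1.0, 2.0, 3.0, 4.0]):
            ring = s.mesh.vertices[r * K : (r + 1) * K]
            assert np.allclose(ring[:, 2], z, atol=1e-12)
            assert np.allclose(np.linalg.norm(ring[:, :2], axis=1), 5.0, atol=1e-9)

    def test_twist_offset_recovered(self):
        # second ring rotated by 90 deg in index space: the cyclic-offset
        # search must undo it, leaving connecting edges near-vertical
        K = 100
        c0 = PlanarContour(0, 0.0, circle_ring(0.0, 5.0, n=K))
        c1 = PlanarContour(4, 4.0, circle_ring(4.0, 5.0, n=K, phase=np.pi / 2))
        stack = ContourStack([0, 0, 1], [c0, c1], points_per_contour=K, n_intermediate=0)
        s = build_scaffold(stack)
        bottom = s.mesh.vertices[:K]
        top = s.mesh.vertices[K : 2 * K]
        lateral = np.linalg.norm((top - bottom)[:, :2], axis=1)
        assert np.all(lateral < 2 * np.pi * 5.0 / K + 1e-9)

    def test_mismatched_point_counts_raise(self):
        c0 = PlanarContour(0, 0.0, circle_ring(0.0, 5.0, n=40))
        c1 = PlanarContour(4, 4.0, circle_ring(4.0, 5.0, n=50))
        stack = ContourStack([0, 0, 1], [c0, c1], points_per_contour=40)
        with pytest.raises(ScaffoldError):
            build_scaffold(stack)


class TestBuildLaplacian:
    def test_row_structure(self, coaxial_stack):
        s = build_scaffold(coaxial_stack)
        sys1 = build_laplacian(s, order=1)
        L = sys1.L.toarray()
        assert np.allclose(L.sum(axis=1), 0.0, atol=1e-14)
        assert np.allclose(np.diag(L), 1.0)
        # interior vertex with 6 neighbours: six off-diagonals of -1/6
        K = s.n_points_per_ring
        row = L[2 * K]  # middle intermediate ring
        offdiag = row[np.arange(len(row)) != 2 * K]
        vals = offdiag[offdiag != 0]
        assert len(vals) == 6
        assert np.allclose(vals, -1.0 / 6.0)

    def test_bilaplacian_matches_dense_product(self):
        # 3 rings of 10 points: compare sparse L^2 against dense (L @ L)
        c0 = PlanarContour(0, 0.0, circle_ring(0.0, 5.0, n=10))
        c1 = PlanarContour(4, 4.0, circle_ring(4.0, 5.0, n=10))
        stack = ContourStack([0, 0, 1], [c0, c1], points_per_contour=10, n_intermediate=1)
        s = build_scaffold(stack)
        sys2 = build_laplacian(s, order=2)
        n_ring = s.n_rings * s.n_points_per_ring
        dense = dense_umbrella(s.mesh, n_ring)
        assert np.allclose(sys2.matrix.toarray(), dense @ dense, atol=1e-12)


class TestSolveFairing:
    def test_known_vertices_unchanged_exactly(self, coaxial_stack):
        s = build_scaffold(coaxial_stack)
        out = solve_fairing(build_laplacian(s, order=2), s)
        known = s.known_mask
        assert np.array_equal(out.vertices[known], s.mesh.vertices[known])

    def test_harmonic_maximum_principle(self, coaxial_stack):
        s = build_scaffold(coaxial_stack)
        out = solve_fairing(build_laplacian(s, order=1), s)
        n_ring = s.n_rings * s.n_points_per_ring
        known_z = s.mesh.vertices[s.known_mask[:n_ring].nonzero()[0], 2]
        unk = (~s.known_mask[:n_ring]).nonzero()[0]
        assert np.all(out.vertices[unk, 2] >= known_z.min() - 1e-8)
        assert np.all(out.vertices[unk, 2] <= known_z.max() + 1e-8)

    def test_order1_necks_order2_near_cylinder(self, coaxial_stack):
        # membrane fairing pulls intermediate rings inward (minimal surface
        # neck); thin-plate fairing stays much closer to the cylinder
        s = build_scaffold(coaxial_stack)
        K = s.n_points_per_ring
        radii = {}
        for order in (1, 2):
            out = solve_fairing(build_laplacian(s, order), s)
            mid = out.vertices[K : 4 * K]
            radii[order] = np.linalg.norm(mid[:, :2], axis=1).mean()
        assert radii[1] < 5.0 - 0.05
        assert radii[1] < radii[2] <= 5.0 + 0.01

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_dense_direct_oracle(self, coaxial_stack, order):
        s = build_scaffold(coaxial_stack)
        out = solve_fairing(build_laplacian(s, order), s)
        oracle = dense_fairing_solution(s, order)
        n_ring = s.n_rings * s.n_points_per_ring
        assert np.allclose(out.vertices[:n_ring], oracle, atol=1e-6)

    def test_rotational_symmetry_preserved(self, coaxial_stack):
        s = build_scaffold(coaxial_stack)
        out = solve_fairing(build_laplacian(s, order=2), s)
        K = s.n_points_per_ring
        for r in range(1, 4):
            ring = out.vertices[r * K : (r + 1) * K]
            radii = np.linalg.norm(ring[:, :2], axis=1)
            assert radii.std() < 1e-6
            assert ring[:, 2].std() < 1e-6


class TestReconstruct:
    def test_dense_input_self_consistency(self, ellipsoid_volume):
        from fastsurf import compare, extract_contours, mesh_from_labels, resample_stack

        full = mesh_from_labels(ellipsoid_volume)
        stack = resample_stack(extract_contours(ellipsoid_volume, 2), 100)
        rec = reconstruct(stack, order=2, n_intermediate=0)
        assert compare(full, rec, spacing=0.5).jaccard >= 0.95

    def test_seven_contour_ellipsoid_recovery(self, ellipsoid_volume):
        from fastsurf import compare, extract_contours, mesh_from_labels, resample_stack

        full = mesh_from_labels(ellipsoid_volume)
        stack = resample_stack(extract_contours(ellipsoid_volume, 2), 100)
        rec = reconstruct(select_sparse(stack, 7), order=2)
        assert compare(full, rec, spacing=0.5).jaccard >= 0.90

    def test_minimum_four_contours_valid(self, hippocampus_stack):
        rec = reconstruct(select_sparse(hippocampus_stack, 4), order=2)
        assert rec.is_watertight
        assert mesh_volume(rec) > 0

    def test_speed_under_one_second(self, hippocampus_stack):
        sub = select_sparse(hippocampus_stack, 7)
        t0 = time.perf_counter()
        reconstruct(sub, order=2)
        assert time.perf_counter() - t0 < 1.0
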
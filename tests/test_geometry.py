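"""Label-volume <-> mesh conversion, volumes, containment, affines."""

import numpy as np
import pytest
import trimesh

from fastsurf import (
    AffineTransform,
    LabelVolume,
    apply_affine,
    contains_points,
    load_mesh,
    mesh_from_labels,
    mesh_volume,
    save_mesh,
)
from fastsurf.errors import (
    EmptySegmentation,
    InvalidTransform,
    MultiComponentError,
    OpenSurfaceError,
)


class TestMeshFromLabels:
    def test_cube_volume_within_5pct(self):
        # 20 voxels of 0.5 mm = 10 mm cube, analytic volume 1000 mm^3
        data = np.zeros((30, 30, 30), np.uint8)
        data[5:25, 5:25, 5:25] = 1
        vol = LabelVolume(data, np.diag([0.5, 0.5, 0.5, 1.0]))
        v = mesh_volume(mesh_from_labels(vol))
        assert abs(v - 1000.0) / 1000.0 < 0.05

    def test_sphere_volume_within_2pct(self):
        # sphere centre offset half a voxel from the grid: generic alignment
        r, n = 8.0, 24
        g = np.indices((n, n, n)) - (n - 1) / 2
        data = ((g**2).sum(axis=0) <= r**2).astype(np.uint8)
        mesh = mesh_from_labels(LabelVolume(data, np.eye(4)))
        analytic = 4.0 / 3.0 * np.pi * r**3
        assert abs(mesh_volume(mesh) - analytic) / analytic < 0.02
        assert mesh.is_watertight

    def test_empty_volume_raises(self):
        vol = LabelVolume(np.zeros((5, 5, 5), np.uint8), np.eye(4))
        with pytest.raises(EmptySegmentation):
            mesh_from_labels(vol)

    def test_multi_component_raises(self, two_cube_volume):
        with pytest.raises(MultiComponentError):
            mesh_from_labels(two_cube_volume)

    def test_convergence_with_voxel_size(self):
        # error vs analytic sphere volume must not increase as voxels shrink
        spec_r = 8.0
        analytic = 4.0 / 3.0 * np.pi * spec_r**3
        errs = []
        for scale in (2.0, 1.0, 0.5):
            n = 2 * int(np.ceil((spec_r + 3) / scale))  # even: generic alignment
            g = (np.indices((n, n, n)) - (n - 1) / 2) * scale
            data = (g[0] ** 2 + g[1] ** 2 + g[2] ** 2 <= spec_r**2).astype(np.uint8)
            vol = LabelVolume(data, np.diag([scale, scale, scale, 1.0]))
            errs.append(abs(mesh_volume(mesh_from_labels(vol)) - analytic) / analytic)
        assert errs[2] <= errs[1] <= errs[0]


class TestMeshVolume:
    def test_unit_cube(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariance(self, unit_cube):
        shifted = unit_cube.copy()
        shifted.vertices = shifted.vertices + np.array([100.0, -50.0, 7.0])
        assert mesh_volume(shifted) == pytest.approx(1.0, abs=1e-9)

    def test_icosphere_within_half_pct(self, icosphere):
        analytic = 4.0 * np.pi / 3.0
        assert abs(mesh_volume(icosphere) - analytic) / analytic < 0.005

    def test_agrees_with_trimesh(self, icosphere):
        # independent route: trimesh's own mass-properties volume
        assert mesh_volume(icosphere) == pytest.approx(icosphere.volume, rel=1e-10)

    def test_open_mesh_raises(self, unit_cube):
        open_mesh = trimesh.Trimesh(
            vertices=unit_cube.vertices, faces=unit_cube.faces[:-2], process=False
        )
        with pytest.raises(OpenSurfaceError):
            mesh_volume(open_mesh)


class TestContainsPoints:
    def test_cube_inside_outside(self, unit_cube):
        res = contains_points(unit_cube, np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]]))
        assert res.tolist() == [True, False]

    def test_sphere_parity_with_analytic(self, icosphere):
        rng = np.random.default_rng(42)
        pts = rng.uniform(-1.3, 1.3, (1000, 3))
        inside = contains_points(icosphere, pts)
        truth = np.linalg.norm(pts, axis=1) < 1.0
        assert (inside == truth).mean() >= 0.995

    def test_voxel_oracle_agreement(self, sphere_volume):
        # grid containment must agree with the label volume it was meshed
        # from on >= 99.5% of voxel centres, discrepancies near the surface
        mesh = mesh_from_labels(sphere_volume)
        shape = sphere_volume.data.shape
        ijk = np.indices(shape).reshape(3, -1).T
        world = sphere_volume.voxel_to_world(ijk)
        inside = contains_points(mesh, world)
        truth = sphere_volume.data.ravel().astype(bool)
        agree = inside == truth
        assert agree.mean() >= 0.995
        # disagreements only within one voxel of the boundary
        r = np.linalg.norm(world, axis=1)
        assert np.all(np.abs(r[~agree] - 8.0) <= 1.0)

    def test_own_vertices_no_crash(self, icosphere):
        res = contains_points(icosphere, icosphere.vertices)
        res2 = contains_points(icosphere, icosphere.vertices)
        assert np.array_equal(res, res2)  # deterministic

    def test_open_mesh_raises(self, unit_cube):
        open_mesh = trimesh.Trimesh(
            vertices=unit_cube.vertices, faces=unit_cube.faces[:-1], process=False
        )
        with pytest.raises(OpenSurfaceError):
            contains_points(open_mesh, np.zeros((1, 3)))


class TestApplyAffine:
    def test_identity(self, unit_cube):
        out = apply_affine(unit_cube, AffineTransform.identity())
        assert np.allclose(out.vertices, unit_cube.vertices)

    def test_rigid_preserves_volume(self, icosphere):
        m = trimesh.transformations.rotation_matrix(0.7, [1.0, 2.0, 3.0])
        m[:3, 3] = [5.0, -2.0, 9.0]
        out = apply_affine(icosphere, AffineTransform(m))
        assert mesh_volume(out) == pytest.approx(mesh_volume(icosphere), rel=1e-9)

    def test_uniform_scale_cubes_volume(self, unit_cube):
        t = AffineTransform(np.diag([2.0, 2.0, 2.0, 1.0]))
        assert mesh_volume(apply_affine(unit_cube, t)) == pytest.approx(8.0, rel=1e-9)

    def test_reflection_keeps_positive_volume(self, unit_cube):
        t = AffineTransform(np.diag([-1.0, 1.0, 1.0, 1.0]))
        assert mesh_volume(apply_affine(unit_cube, t)) == pytest.approx(1.0, rel=1e-9)

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(InvalidTransform):
            AffineTransform(m)


class TestIO:
    def test_nifti_roundtrip(self, sphere_volume, tmp_path):
        p = tmp_path / "sphere.nii.gz"
        sphere_volume.to_nifti(p)
        back = LabelVolume.from_nifti(p)
        assert np.array_equal(back.data, sphere_volume.data)
        assert np.allclose(back.affine, sphere_volume.affine)

    @pytest.mark.parametrize("ext", ["ply", "obj", "stl"])
    def test_mesh_roundtrip(self, unit_cube, tmp_path, ext):
        p = tmp_path / f"cube.{ext}"
        save_mesh(unit_cube, p)
        back = load_mesh(p)
        assert mesh_volume(back) == pytest.approx(1.0, rel=1e-6)

    def test_affine_text_roundtrip(self, tmp_path):
        t = AffineTransform(np.diag([1.0, 2.0, 3.0, 1.0]))
        p = tmp_path / "xfm.mat"
        t.to_text(p)
        assert np.allclose(AffineTransform.from_text(p).matrix, t.matrix)
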
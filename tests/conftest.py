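import numpy as np
import pytest
import trimesh

from fastsurf import (
    ContourStack,
    LabelVolume,
    PhantomSpec,
    PlanarContour,
    extract_contours,
    make_phantom,
    resample_stack,
)


@pytest.fixture(scope="session")
def unit_cube():
    """Closed 12-triangle unit cube centred at the origin."""
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def sphere_volume():
    """Rasterised sphere r=8 mm at 1 mm voxels, centred on the grid."""
    spec = PhantomSpec(kind="sphere", size=(8.0,), spacing=(1.0, 1.0, 1.0))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def ellipsoid_volume():
    """21-slice ellipsoid phantom at MRI-like 1 x 1 x 1.2 mm voxels."""
    return make_phantom(PhantomSpec(kind="ellipsoid", size=(10.0, 8.0, 12.6)))


@pytest.fixture(scope="session")
def hippocampus_volume():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def hippocampus_stack(hippocampus_volume):
    return resample_stack(extract_contours(hippocampus_volume, 2), 100)


def circle_ring(z, r, n=40, phase=0.0):
    th = np.arange(n) * 2 * np.pi / n + phase
    return np.column_stack([r * np.cos(th), r * np.sin(th), np.full(n, z)])


@pytest.fixture
def coaxial_stack():
    """Two identical coaxial circular rings 4 mm apart, 3 intermediate rings."""
    c0 = PlanarContour(0, 0.0, circle_ring(0.0, 5.0))
    c1 = PlanarContour(4, 4.0, circle_ring(4.0, 5.0))
    return ContourStack([0, 0, 1], [c0, c1], points_per_contour=40, n_intermediate=3)


@pytest.fixture
def two_cube_volume():
    """Two disconnected cubes — violates the single-component invariant."""
    data = np.zeros((20, 10, 10), np.uint8)
    data[2:6, 3:7, 3:7] = 1
    data[12:16, 3:7, 3:7] = 1
    return LabelVolume(data, np.eye(4))
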
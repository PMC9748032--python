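import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lesionfit3d import Ellipsoid, VoxelGrid
from lesionfit3d.synthetic import PhantomSpec, voxelize_ellipsoid


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform directions on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def exact_ellipsoid_points(center, semi_axes, rotation, n=120) -> np.ndarray:
    """Points lying exactly on a given ellipsoid surface."""
    unit = fibonacci_sphere(n)
    return np.asarray(center) + (unit * np.asarray(semi_axes)) @ np.asarray(rotation).T


def random_rotation(rng) -> np.ndarray:
    R = Rotation.random(rng=rng).as_matrix()
    if np.linalg.det(R) < 0:  # pragma: no cover - Rotation always gives det +1
        R[:, 2] = -R[:, 2]
    return R


def random_ellipsoid(rng, axis_range=(5.0, 20.0), center_scale=30.0) -> Ellipsoid:
    axes = np.sort(rng.uniform(*axis_range, size=3))[::-1]
    center = rng.uniform(-center_scale, center_scale, size=3)
    return Ellipsoid(center=center, semi_axes=axes, rotation=random_rotation(rng))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def iso_grid():
    """1 mm isotropic, gap-free grid."""
    return VoxelGrid(nx=50, ny=50, nz=50, dx=1.0, dy=1.0,
                     slice_thickness=1.0, slice_gap=0.0)


@pytest.fixture
def t2_paper_grid():
    """T2-like acquisition geometry: 0.49 mm in-plane, 3 mm + 3 mm gap."""
    return VoxelGrid(nx=100, ny=100, nz=12, dx=0.49, dy=0.49,
                     slice_thickness=3.0, slice_gap=3.0)


@pytest.fixture
def dwi_paper_grid():
    """DWI-like acquisition geometry: 2.6 mm in-plane, 3 mm + 3 mm gap."""
    return VoxelGrid(nx=40, ny=40, nz=12, dx=2.6, dy=2.6,
                     slice_thickness=3.0, slice_gap=3.0)


def grid_center(grid: VoxelGrid, zoff: float = 0.0):
    return (
        grid.origin[0] + (grid.nx - 1) / 2.0 * grid.dx,
        grid.origin[1] + (grid.ny - 1) / 2.0 * grid.dy,
        grid.origin[2] + (grid.nz - 1) / 2.0 * grid.dz + zoff,
    )


def make_phantom(grid, semi_axes, euler=(0.0, 0.0, 0.0), zoff=0.0, **kwargs):
    spec = PhantomSpec(center=grid_center(grid, zoff), semi_axes=semi_axes,
                       grid=grid, euler_deg=euler, **kwargs)
    return voxelize_ellipsoid(spec)


@pytest.fixture
def sphere_phantom_iso(iso_grid):
    """Radius-10 mm sphere on the isotropic grid, off-lattice centre."""
    return make_phantom(iso_grid, (10.0, 10.0, 10.0), zoff=0.5)
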
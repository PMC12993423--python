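"""Shared fixtures: small grids, simple shapes and a tiny in-memory course."""

import numpy as np
import pytest

from doseaccum.core import DoseGrid, ImageGeometry, Roi
from doseaccum.geometry import BinaryMask


@pytest.fixture
def unit_grid():
    """41^3 grid, 1 mm isotropic, centred on the origin."""
    return ImageGeometry(origin=(-20.0, -20.0, -20.0), spacing=(1.0, 1.0, 1.0),
                         dims=(41, 41, 41))


@pytest.fixture
def big_grid():
    """81^3 grid, 1 mm isotropic, centred on the origin."""
    return ImageGeometry(origin=(-40.0, -40.0, -40.0), spacing=(1.0, 1.0, 1.0),
                         dims=(81, 81, 81))


def circle_roi(name, cx, cy, cz, r, z_spacing=1.0, n_vertices=96,
               sphere=True):
    """Sphere (or constant-radius cylinder) as an axial contour stack."""
    slices = []
    zs = np.arange(cz - r, cz + r + 1e-9, z_spacing)
    for z in zs:
        if sphere:
            t = (z - cz) / r
            if abs(t) >= 1:
                continue
            rad = r * np.sqrt(1 - t * t)
        else:
            rad = r
        th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        poly = np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)])
        slices.append((float(z), [poly]))
    return Roi(name=name, slices=slices)


@pytest.fixture
def sphere_roi():
    return circle_roi("sphere", 0.0, 0.0, 0.0, 15.0)


def sphere_mask(geometry, center, r) -> BinaryMask:
    """Direct voxel-centre sphere mask (no polygon rasterization)."""
    xs = [geometry.axis_coords(i) for i in range(3)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    vox = ((gx - center[0]) ** 2 + (gy - center[1]) ** 2
           + (gz - center[2]) ** 2) <= r * r
    return BinaryMask(geometry, vox, label="sphere")


@pytest.fixture
def uniform_dose():
    """Uniform 60 Gy on a coarse grid covering the unit grid."""
    geom = ImageGeometry(origin=(-24.0, -24.0, -24.0), spacing=(2.0, 2.0, 2.0),
                         dims=(25, 25, 25))
    return DoseGrid(geometry=geom, values=np.full((25, 25, 25), 60.0))


@pytest.fixture(scope="session")
def small_course(tmp_path_factory):
    """A 3-fraction phantom course on disk, shared across I/O tests."""
    from doseaccum.phantom import PhantomConfig, generate_course

    out = tmp_path_factory.mktemp("course")
    cfg = PhantomConfig(seed=11, n_fractions=3)
    manifest, truth = generate_course(cfg, out, write_ct=False)
    return manifest, truth, cfg
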
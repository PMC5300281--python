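"""Shared phantom fixtures; everything is generated programmatically."""

import numpy as np
import pytest

from hippomesh.phantom import ShapeSpec, rasterize
from hippomesh.surfaces import LabelVolume, extract_surface


@pytest.fixture(scope="session")
def sphere_surface():
    """Marching-cubes surface of a 10 mm sphere rasterized at 1 mm voxels."""
    vol = rasterize(ShapeSpec(kind="sphere", radii=(10, 10, 10)), (32, 32, 32), 1.0)
    return extract_surface(vol, 1)


@pytest.fixture(scope="session")
def small_sphere_surface():
    vol = rasterize(ShapeSpec(kind="sphere", radii=(4, 4, 4)), (16, 16, 16), 1.0)
    return extract_surface(vol, 1)


@pytest.fixture(scope="session")
def bent_tube_surface():
    """Asymmetric elongated phantom: 4 mm tube swept along a 15 mm, 60 deg arc."""
    vol = rasterize(ShapeSpec(kind="bent_tube", radii=(4, 15, 0), bend_angle=60), (48, 48, 24), 1.0)
    return extract_surface(vol, 1)


@pytest.fixture(scope="session")
def ellipsoid_surface():
    vol = rasterize(ShapeSpec(kind="ellipsoid", radii=(12, 6, 5)), (32, 20, 18), 1.0)
    return extract_surface(vol, 1)


@pytest.fixture(scope="session")
def two_blob_surface():
    vox = np.zeros((16, 8, 8), dtype=np.int16)
    vox[2:6, 2:6, 2:6] = 1
    vox[9:14, 2:7, 2:7] = 1
    return extract_surface(LabelVolume(vox, np.eye(4)), 1)


@pytest.fixture(scope="session")
def unit_cube_surface():
    """Closed 12-triangle unit cube [0,1]^3, outward-oriented."""
    from hippomesh.surfaces import TriSurface

    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0
        [4, 6, 7], [4, 7, 5],          # x = 1
        [0, 4, 5], [0, 5, 1],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return TriSurface(v, f)
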
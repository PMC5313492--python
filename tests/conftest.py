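import numpy as np
import pytest

from petburden import (
    BoneMask,
    Ellipsoid,
    PhantomSpec,
    SphereLesion,
    SUVMap,
)


@pytest.fixture
def simple_suv():
    """Uniform background SUV map, 20^3 voxels at 2 mm isotropic."""
    return SUVMap(np.ones((20, 20, 20)), (2.0, 2.0, 2.0))


@pytest.fixture
def two_lesion_phantom_spec():
    """One in-bone lesion and one out-of-bone lesion, noise-free, equal grids."""
    return PhantomSpec(
        shape=(40, 40, 40),
        pet_spacing_mm=(2.0, 2.0, 2.0),
        ct_spacing_mm=(2.0, 2.0, 2.0),
        bones=[Ellipsoid((40.0, 40.0, 40.0), (26.0, 22.0, 18.0))],
        lesions=[
            SphereLesion((40.0, 40.0, 40.0), 8.0, 20.0),   # inside bone
            SphereLesion((10.0, 10.0, 66.0), 7.0, 20.0),   # outside bone
        ],
    )


def sphere_suv(shape, spacing, center_mm, radius_mm, plateau, background=1.0):
    """Digitized plateau sphere in a uniform background (voxel-center rule)."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    vals = np.full(shape, float(background))
    vals[d2 <= radius_mm**2] = plateau
    return SUVMap(vals, spacing)


def full_mask(shape, spacing):
    return BoneMask(np.ones(shape, dtype=np.uint8), spacing)
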
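import numpy as np
import pytest

from geotract import GridFieldProvider, HalfPlaneProvider, precompute
from geotract.phantoms import make_halfplane, make_homogeneous


@pytest.fixture(scope="session")
def halfplane_fields():
    """Precomputed fields of the 64x64x8, y0=1 half-plane phantom."""
    return precompute(make_halfplane((64, 64, 8), y0=1.0))


@pytest.fixture(scope="session")
def halfplane_grid_provider(halfplane_fields):
    return GridFieldProvider(halfplane_fields)


@pytest.fixture(scope="session")
def halfplane_analytic():
    return HalfPlaneProvider(y0=1.0)


@pytest.fixture(scope="session")
def homogeneous_fields():
    """Long homogeneous x-aligned anisotropic phantom fields."""
    return precompute(make_homogeneous((64, 16, 16), (9.0, 1.0, 1.0), (1.0, 0.0, 0.0)))


def random_spd(rng, scale=1.0):
    """A well-conditioned random SPD tensor as a 6-vector."""
    a = rng.normal(size=(3, 3))
    m = a @ a.T + 0.5 * np.eye(3)
    iu, ju = np.triu_indices(3)
    return scale * m[iu, ju]


def random_sym(rng, scale=1.0):
    a = rng.normal(size=(3, 3))
    m = 0.5 * (a + a.T)
    iu, ju = np.triu_indices(3)
    return scale * m[iu, ju]
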
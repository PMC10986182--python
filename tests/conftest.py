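import numpy as np
import pytest

from scarwave.mesh import LGEMap
from scarwave.synth import SyntheticSpec, generate_lge, generate_mesh


@pytest.fixture(scope="session")
def sheet20():
    """Small healthy 20x20 sheet with a centered patch map."""
    spec = SyntheticSpec(grid_shape=(20, 20), patch_radii_mm=(4.0,),
                         noise_sd=0.0, seed=7)
    mesh = generate_mesh(spec)
    lge = generate_lge(spec, mesh)
    return mesh, lge


@pytest.fixture(scope="session")
def sheet30():
    spec = SyntheticSpec(grid_shape=(30, 30), patch_radii_mm=(6.0,),
                         noise_sd=0.0, seed=11)
    mesh = generate_mesh(spec)
    lge = generate_lge(spec, mesh)
    return mesh, lge


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_lge(mesh, value):
    return LGEMap(np.full(mesh.n_elements, float(value)))
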
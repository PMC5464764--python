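import warnings

import numpy as np
import pytest
import trimesh

from rootshape.geometry_io import TriangleMesh
from rootshape.synthetic import (
    APEX_DIRECTION,
    MESIAL_DIRECTION,
    ToothParams,
    generate_tooth,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def icosphere4():
    """Unit icosphere at subdivision 4 (2562 vertices)."""
    tm = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return TriangleMesh.from_trimesh(tm)


@pytest.fixture(scope="session")
def icosphere3_r2():
    tm = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
    return TriangleMesh.from_trimesh(tm)


@pytest.fixture(scope="session")
def template_tooth():
    """Noise-free neutral incisor surface."""
    return generate_tooth(ToothParams(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_tooth():
    return generate_tooth(ToothParams(noise_sigma=0.05, seed=11))


@pytest.fixture(scope="session")
def template_pdm(template_tooth):
    from rootshape.correspondence import correspond

    return correspond(template_tooth, APEX_DIRECTION, MESIAL_DIRECTION)


@pytest.fixture(scope="session")
def anatomy_axes():
    return APEX_DIRECTION, MESIAL_DIRECTION


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
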
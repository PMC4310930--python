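import numpy as np
import pytest

from lisweep import default_grid, make_paradigm
from lisweep.pipeline import make_fixtures


@pytest.fixture(scope="session")
def paradigm():
    """The study block design: 20 s rest / 20 s task, five cycles, TR 2 s."""
    return make_paradigm(20, 20, 5, 2)


@pytest.fixture(scope="session")
def small_grid():
    """16 x 16 x 10 lattice of 3 mm voxels, symmetric about x = 0."""
    return default_grid((16, 16, 10), 3.0)


@pytest.fixture(scope="session")
def glm_grid():
    """A reduced grid big enough to hold a few-cm cluster, for GLM tests."""
    return default_grid((24, 24, 16), 3.0)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(out)
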
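import pytest

from reefcarb.raster import GridSpec
from reefcarb.synthetic import generate_omega_trajectory, generate_scene


@pytest.fixture(scope="session")
def default_grid():
    return GridSpec(100, 100, 12.0)


@pytest.fixture(scope="session")
def default_scene(default_grid):
    """One default synthetic platform shared by read-only tests."""
    return generate_scene(default_grid, seed=0)


@pytest.fixture(scope="session")
def default_trajectory():
    return generate_omega_trajectory()
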
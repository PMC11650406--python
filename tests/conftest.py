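import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pfa_fieldsim.anatomy import (
    assign_conductivity,
    build_phantom,
    default_conductivity_table,
    define_target,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def antrum_grid():
    """Default antrum phantom at 1 mm voxels (shared, read-only)."""
    return build_phantom("antrum", spacing_mm=1.0)


@pytest.fixture(scope="session")
def antrum_target(antrum_grid):
    return define_target(antrum_grid)


@pytest.fixture(scope="session")
def antrum_cond(antrum_grid):
    return assign_conductivity(antrum_grid, default_conductivity_table())


@pytest.fixture(scope="session")
def slab_grid():
    """Small validation slab at 0.5 mm voxels."""
    return build_phantom("slab", {"extent_mm": (40.0, 24.0, 16.0)}, 0.5)


@pytest.fixture(scope="session")
def slab_cond(slab_grid):
    return assign_conductivity(slab_grid, default_conductivity_table())


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
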
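import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shrubvol import GeneratorConfig, generate_stands, generate_trees

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tree_table():
    """One medium-sized synthetic tree campaign (n = 300, fixed seed)."""
    return generate_trees(GeneratorConfig(seed=42, n_trees=300))


@pytest.fixture(scope="session")
def stand_data():
    """Default 11-plot synthetic stand campaign at a coarser raster (speed)."""
    cfg = GeneratorConfig(seed=7, grid_resolution_m=0.05)
    stands, grids = generate_stands(cfg)
    return cfg, stands, grids


@pytest.fixture()
def rng():
    return np.random.default_rng(20220)
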
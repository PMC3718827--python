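import numpy as np
import pytest

from habsuit.grid import GridLayer, LayerStack
from habsuit.synth import SyntheticConfig, TruthSpec, generate_environment, generate_occurrences


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        lon_min=-2.0,
        lon_max=2.0,
        lat_min=54.0,
        lat_max=58.0,
        cell_size=0.05,
        seed=42,
        n_populations=3,
        pts_per_pop=25,
        pop_spread_km=6.0,
        land_fraction=0.1,
    )


@pytest.fixture(scope="session")
def truth():
    return TruthSpec()


@pytest.fixture(scope="session")
def small_stack(small_config, truth):
    return generate_environment(small_config, truth)


@pytest.fixture(scope="session")
def small_occ(small_stack, truth, small_config):
    return generate_occurrences(small_stack, truth, small_config)


def make_layer(values, origin_lon=0.0, origin_lat=0.0, cell_size=0.005, mask=None, name="x"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return GridLayer(
        name=name,
        values=values,
        nodata_mask=mask,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size=cell_size,
    )


@pytest.fixture
def flat_sea_stack():
    """16x16 single-layer all-sea stack for plumbing tests."""
    layer = make_layer(np.full((16, 16), 1.5), origin_lat=56.0, origin_lon=-1.0, cell_size=0.05, name="temperature")
    return LayerStack({"temperature": layer})
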
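import numpy as np
import pytest

from parasdm.cascade import CascadeConfig
from parasdm.geodata import GridSpec, Layer, ScenarioKey, Stack
from parasdm.synthetic import WorldConfig, make_world


@pytest.fixture(scope="session")
def small_world():
    """Compact synthetic system: current + two futures, 2 GCM variants."""
    cfg = WorldConfig(
        seed=7,
        n_rows=60,
        n_cols=50,
        n_presence=150,
        scenarios=[
            ScenarioKey("current"),
            ScenarioKey("SSP126", "2020-2040"),
            ScenarioKey("SSP585", "2080-2100"),
        ],
    )
    return make_world(cfg)


@pytest.fixture(scope="session")
def fast_cascade_config():
    """Candidate grid small enough for test-scale fitting."""
    return CascadeConfig(classes=("L", "LQ"), rms=(1.0,), background_n=2000, k_h=4)


@pytest.fixture
def grid10():
    """10 x 10 one-degree grid with NW corner at (0 E, 10 N)."""
    return GridSpec(origin_lon=0.0, origin_lat=10.0, cell_size=1.0, n_rows=10, n_cols=10)


def layer_from(spec: GridSpec, values, mask=None) -> Layer:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(spec.shape, dtype=bool)
    return Layer(spec, np.where(mask, values, np.nan), np.asarray(mask, bool))


def stack_from(spec: GridSpec, named_values: dict) -> Stack:
    st = Stack(spec)
    for name, vals in named_values.items():
        st.add(name, layer_from(spec, vals))
    return st
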
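import numpy as np
import pytest

from cocoazone.geo_core import EnvStack, GridSpec, Layer
from cocoazone.synthetic_data import WorldConfig, make_world


@pytest.fixture
def grid5():
    return GridSpec(n_rows=5, n_cols=5, origin_y=5.0, cell_area_km2=1.0)


@pytest.fixture
def grid10():
    return GridSpec(n_rows=10, n_cols=10, origin_y=10.0, cell_area_km2=2.5)


def make_layer(grid, values, name="x", **kw):
    return Layer(grid=grid, name=name, values=np.asarray(values, dtype=float), **kw)


@pytest.fixture
def stack_factory():
    """Build an EnvStack from named flat vectors laid out on a 1×n grid."""

    def build(**vectors):
        n = len(next(iter(vectors.values())))
        grid = GridSpec(n_rows=1, n_cols=n, origin_y=1.0)
        layers = {
            name: Layer(grid=grid, name=name, values=np.asarray(v, float).reshape(1, n))
            for name, v in vectors.items()
        }
        return EnvStack(grid=grid, layers=layers)

    return build


@pytest.fixture(scope="session")
def small_world():
    """A compact world reused by tests that only need structure, not skill."""
    cfg = WorldConfig(n_rows=48, n_cols=48, occurrence_n=120, n_municipalities=12,
                      seed=11)
    return make_world(cfg)


@pytest.fixture(scope="session")
def default_world():
    """One default-condition world (120×120, 300 occurrences), seed 1."""
    return make_world(WorldConfig(seed=1))
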
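import numpy as np
import pytest

from pyrocell import GridGeometry, IgnitionSet, Landscape, ModelParams


@pytest.fixture
def geometry():
    return GridGeometry(n_rows=5, n_cols=5, cell_size=20.0)


@pytest.fixture
def flat_landscape(geometry):
    """Uniform, flat, calm 5x5 landscape, favourable to spread."""
    shape = geometry.shape
    return Landscape(
        geometry=geometry,
        fuel=np.full(shape, 1.0),
        moisture=np.full(shape, 0.2),
        burn_prob=np.full(shape, 1.0),
        elevation=np.zeros(shape),
        combustion_rate=np.full(shape, 0.9),
    )


@pytest.fixture
def params():
    return ModelParams(rng_seed=0)


@pytest.fixture
def center_ignition():
    return IgnitionSet.at_cells([(2, 2)])


def random_landscape(seed, n=5, wind=True):
    """Random-but-valid landscape used by the oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    geometry = GridGeometry(n_rows=n, n_cols=n, cell_size=20.0)
    return Landscape(
        geometry=geometry,
        fuel=rng.uniform(0.0, 1.0, (n, n)),
        moisture=rng.uniform(0.0, 1.0, (n, n)),
        burn_prob=rng.uniform(0.0, 1.0, (n, n)),
        elevation=rng.uniform(0.0, 60.0, (n, n)),
        combustion_rate=rng.uniform(0.1, 1.0, (n, n)),
        wind_speed=float(rng.uniform(0.0, 12.0)) if wind else 0.0,
        wind_direction=float(rng.uniform(0.0, 360.0)),
    )
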
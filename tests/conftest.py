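import datetime as dt

import numpy as np
import pytest

from granarywatch.grid_core import GranarySeries, StorageState, TemperatureGrid


def make_series(values, mask=None, moisture=None, variety="wheat", start=dt.date(2024, 1, 1)):
    """Build a GranarySeries from a (days, M, N, H) array."""
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    days = [start + dt.timedelta(days=i) for i in range(values.shape[0])]
    grids = [TemperatureGrid(values[i], mask[i], days[i]) for i in range(values.shape[0])]
    if moisture is None:
        moisture = np.full(values.shape[0], 12.5)
    return GranarySeries(
        granary_id="test", variety=variety, days=days, grids=grids,
        moisture=np.asarray(moisture, dtype=np.float64), region="testland",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_series(rng):
    """A small random series with a few missing voxels and realistic values."""
    values = rng.normal(10.0, 5.0, (6, 3, 2, 2))
    mask = rng.random(values.shape) < 0.1
    mask[0] = False  # guarantee at least one observed day per voxel
    moisture = np.full(6, np.nan)
    moisture[[1, 4]] = [12.0, 12.6]
    return make_series(values, mask, moisture=None)


@pytest.fixture
def all_states():
    return list(StorageState)
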
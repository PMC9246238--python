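from datetime import date

import numpy as np
import pytest

from dendroflux import synthetic
from dendroflux.timeseries_core import PeriodWindow


@pytest.fixture(scope="session")
def wet_window() -> PeriodWindow:
    return synthetic.WET_WINDOW


@pytest.fixture(scope="session")
def dry_window() -> PeriodWindow:
    return synthetic.DRY_WINDOW


@pytest.fixture(scope="session")
def default_config() -> synthetic.SimConfig:
    return synthetic.SimConfig(seed=42)


@pytest.fixture(scope="session")
def default_climate(default_config):
    return synthetic.simulate_climate(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def short_window() -> PeriodWindow:
    """A 60-day window for cheap half-hourly simulations."""
    return PeriodWindow(date(2007, 4, 1), date(2007, 5, 30), "short")
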
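"""Shared fixtures: small synthetic rivers and populations kept fast."""

import numpy as np
import pandas as pd
import pytest

from salmotherm.synthetic import RiverScenario, generate_true_field
from salmotherm.temperature import TemperatureGrid


@pytest.fixture
def cool_scenario():
    """A small cool river: every life stage is viable nearly everywhere."""
    return RiverScenario(
        river_length_km=10,
        start_date="2013-01-01",
        end_date="2013-12-31",
        mean_annual_temp=11.0,
        seasonal_amplitude=4.0,
        peak_day=200,
        downstream_warming=0.05,
        daily_noise_sd=0.2,
        seed=11,
    )


@pytest.fixture
def cool_grid(cool_scenario):
    return generate_true_field(cool_scenario)


def constant_grid(temp_c, n_km=3, n_days=365, start="2013-01-01"):
    """Uniform-temperature grid helper used across test modules."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    return TemperatureGrid(
        kms=np.arange(n_km),
        dates=dates,
        values=np.full((n_km, n_days), float(temp_c)),
    )


@pytest.fixture
def grid_16c():
    return constant_grid(16.0)
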
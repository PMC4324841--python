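import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import voltigen as vg

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_constant_series(tmax: float, tmin: float, year: int = 1975, n_days: int = 365) -> vg.WeatherSeries:
    """A flat replicate-year: every day has the same Tmax/Tmin."""
    index = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    df = pd.DataFrame({"tmax": np.full(n_days, float(tmax)), "tmin": np.full(n_days, float(tmin))}, index=index)
    return vg.WeatherSeries(data=df, station_id="const")


def make_random_series(rng: np.random.Generator, year: int = 1975) -> vg.WeatherSeries:
    """A random replicate-year spanning sub-threshold, normal and capped days."""
    tmin = rng.uniform(2.0, 32.0, 365)
    tmax = tmin + rng.uniform(0.0, 18.0, 365)
    index = pd.date_range(f"{year}-01-01", periods=365, freq="D")
    return vg.WeatherSeries(
        data=pd.DataFrame({"tmax": tmax, "tmin": tmin}, index=index), station_id="rand"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_study():
    """One full default study run (6 locations x 7 models x 3 scenarios x 4 periods)."""
    return vg.run_study(vg.default_config(seed=1))
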
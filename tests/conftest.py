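import numpy as np
import pandas as pd
import pytest

import tvmort as tm


def make_series(n=400, seed=0, tmin_sd=3.0, start="2000-01-03"):
    """Small random daily series (weather only) for unit tests."""
    rng = np.random.default_rng(seed)
    tmean = rng.normal(15.0, 5.0, n)
    half = np.abs(rng.normal(4.0, tmin_sd, n)) + 0.05
    return pd.DataFrame({
        "date": pd.date_range(start, periods=n),
        "tmin": tmean - half,
        "tmean": tmean,
        "tmax": tmean + half,
    })


@pytest.fixture
def random_series():
    return make_series()


@pytest.fixture
def sim_community():
    """One simulated community with the default (active) temperature surface."""
    wp = tm.WeatherParams()
    mp = tm.MortalityParams(temp_surface=tm.quadratic_lag_surface())
    return tm.simulate_community(wp, mp, 3 * 365 + 1, seed=42), mp
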
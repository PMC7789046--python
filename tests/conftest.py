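import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

from clisagri import ClimateSpec, WeatherSeries, generate_series
from clisagri.spei import ReferenceTooSmallError  # noqa: F401  (re-export convenience)

hypothesis_settings.register_profile("ci", derandomize=True)
hypothesis_settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_small_reference_warning():
    # 12-year fixtures inevitably sit below the recommended 30-year reference
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="reference sample has")
        yield


def make_constant_series(
    tavg: float = 20.0,
    n_days: int = 400,
    start: str = "2001-01-01",
    diurnal_range: float = 8.0,
    precip: float = 0.0,
    latitude: float = 44.4,
) -> WeatherSeries:
    dates = pd.date_range(start, periods=n_days)
    half = 0.5 * diurnal_range
    return WeatherSeries.from_arrays(
        dates,
        np.full(n_days, tavg - half),
        np.full(n_days, tavg + half),
        np.full(n_days, float(precip)),
        latitude=latitude,
    )


@pytest.fixture(scope="session")
def med_series() -> WeatherSeries:
    """12-year Mediterranean-style synthetic series (default climate, seed 3)."""
    return generate_series(ClimateSpec(seed=3))


@pytest.fixture(scope="session")
def med_spec() -> ClimateSpec:
    return ClimateSpec(seed=3)
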
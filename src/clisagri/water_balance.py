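"""Reference evapotranspiration and daily climatic water balance.

Atmospheric water demand is estimated with the temperature-and-rainfall
modified Hargreaves–Samani equation (Droogers & Allen 2002 form)::

    ET0 = 0.0013 * 0.408 * Ra * (Tavg + 17.0) * max(TD - 0.0123 * P, 0) ** 0.76

with ``Ra`` the extraterrestrial radiation (MJ m-2 day-1, FAO-56 solar
geometry), ``TD = Tmax - Tmin`` (°C) and ``P`` daily precipitation (mm).
The daily climatic water balance is ``D = P - ET0``; its aggregation over
phenological windows feeds the standardized drought index.

Edge cases are clamped to keep ET0 physically non-negative: a negative
radicand (rainy day with small diurnal range) and a temperature factor below
zero (Tavg < -17 °C) both give ET0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solar import (
    SOLAR_CONSTANT,
    inverse_earth_sun_distance,
    solar_declination,
    sunset_hour_angle,
)
from .weather import WeatherSeries

__all__ = [
    "WaterBalanceSeries",
    "extraterrestrial_radiation",
    "et0_hargreaves_modified",
    "climatic_water_balance",
]

#: temperature offset (°C) in the Hargreaves temperature factor.  17.0 as in
#: Droogers & Allen (2002); some variants in the literature use 17.8.
DEFAULT_T_OFFSET = 17.0


@dataclass
class WaterBalanceSeries:
    """Daily ET0 (mm/day) and climatic water balance D = precip - ET0 (mm/day)."""

    dates: pd.DatetimeIndex
    et0: pd.Series
    balance: pd.Series

    def __post_init__(self) -> None:
        if not (len(self.dates) == len(self.et0) == len(self.balance)):
            raise ValueError("dates/et0/balance length mismatch")
        if (self.et0.to_numpy() < 0).any():
            raise ValueError("ET0 must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"et0": self.et0, "balance": self.balance}, index=self.dates)


def extraterrestrial_radiation(latitude: float, day_of_year) -> np.ndarray | float:
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1), FAO-56 Eq. 21.

    Vectorized over ``day_of_year``.  During polar night the sunset hour
    angle is 0 and Ra = 0; tiny negative rounding is floored at zero.
    """
    doy = np.asarray(day_of_year)
    if ((doy < 1) | (doy > 366)).any():
        raise ValueError("day_of_year must be within 1..366")
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    phi = np.deg2rad(latitude)
    delta = solar_declination(doy)
    dr = inverse_earth_sun_distance(doy)
    ws = sunset_hour_angle(latitude, doy)
    ra = (
        (24.0 * 60.0 / np.pi)
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    ra = np.maximum(ra, 0.0)
    return float(ra) if np.isscalar(day_of_year) else ra


def et0_hargreaves_modified(
    series: WeatherSeries, t_offset: float = DEFAULT_T_OFFSET
) -> pd.Series:
    """Daily reference evapotranspiration (mm/day) for a weather series."""
    doy = series.dates.dayofyear.to_numpy()
    ra = extraterrestrial_radiation(series.latitude, doy)
    tavg = series.tavg.to_numpy()
    td = series.tmax.to_numpy() - series.tmin.to_numpy()
    p = series.precip.to_numpy()
    radicand = np.maximum(td - 0.0123 * p, 0.0)
    et0 = 0.0013 * 0.408 * ra * (tavg + t_offset) * radicand**0.76
    et0 = np.maximum(et0, 0.0)
    return pd.Series(et0, index=series.dates, name="et0")


def climatic_water_balance(
    series: WeatherSeries, t_offset: float = DEFAULT_T_OFFSET
) -> WaterBalanceSeries:
    """Daily climatic water balance D = precip - ET0 for a weather series."""
    et0 = et0_hargreaves_modified(series, t_offset=t_offset)
    balance = series.precip - et0
    balance.name = "balance"
    return WaterBalanceSeries(series.dates, et0, balance)
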
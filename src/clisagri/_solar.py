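"""Shared solar geometry: declination, sunset hour angle (FAO-56 forms)."""

from __future__ import annotations

import numpy as np

#: solar constant, MJ m-2 min-1
SOLAR_CONSTANT = 0.0820


def solar_declination(day_of_year):
    """Solar declination (radians) for a day of year (FAO-56 Eq. 24)."""
    j = np.asarray(day_of_year, dtype=float)
    return 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)


def inverse_earth_sun_distance(day_of_year):
    """Inverse relative Earth-Sun distance d_r (FAO-56 Eq. 23)."""
    j = np.asarray(day_of_year, dtype=float)
    return 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)


def sunset_hour_angle(latitude_deg, day_of_year):
    """Sunset hour angle ω_s (radians), FAO-56 Eq. 25.

    The argument of arccos is clamped to [-1, 1] so polar night gives 0 and
    polar day gives π rather than a domain error.
    """
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    delta = solar_declination(day_of_year)
    x = -np.tan(phi) * np.tan(delta)
    return np.arccos(np.clip(x, -1.0, 1.0))
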
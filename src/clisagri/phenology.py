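"""Dynamic winter-wheat phenology: thermal-time development-stage simulation.

Two models share a common engine based on daily effective temperature
``max(0, min(Tavg - Tb, Tmax_e))`` (growing degree days above a base
temperature, capped at a maximum effective temperature, 30 °C by default for
winter wheat):

* the **two-phase model** advances a development stage DVS from 0 at sowing
  through 1 (flowering) to 2 (maturity); the vegetative accumulation
  (DVS < 1, thermal requirement TSUM1) is multiplied by the vernalization
  factor Vf and photoperiod factor Pf, the reproductive accumulation
  (1 <= DVS < 2, requirement TSUM2) is uncorrected;
* the **multi-phase model** tracks six sub-phases (sowing-emergence,
  emergence-tillering, tillering-stem elongation, stem elongation-booting,
  booting-flowering, flowering-ripening), each with its own thermal
  requirement and base temperature, DVS running 0..6, with Vf and Pf applied
  only within sub-phases 2-5.

Vf and Pf are clamped-linear responses (the convention used by WOFOST-family
crop models): Vf rises from 0 to 1 as effective vernalization days accumulate
between ``v_base`` and ``v_sat``; each day contributes between 0 and 1
effective vernalization days through a piecewise-linear temperature response
peaking at cool (3-10 °C) temperatures.  Pf rises linearly with daylength
between a critical and an optimal photoperiod.  All response parameters are
package defaults, not measurements, and are exposed for recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._solar import sunset_hour_angle
from .weather import WeatherSeries

__all__ = [
    "VernalizationParams",
    "PhotoperiodParams",
    "VarietyParams2",
    "VarietyParamsMulti",
    "PhenologyTrack",
    "StageWindow",
    "IncompleteSeasonError",
    "daylength",
    "effective_temperature",
    "vernalization_factor",
    "photoperiod_factor",
    "simulate_2phase",
    "simulate_multiphase",
    "resolve_window",
    "DEFAULT_STAGE_DVS_2PHASE",
    "DEFAULT_STAGE_DVS_MULTI",
    "TABLE_TSUM_BOUNDS",
    "DEFAULT_TSUMS_MULTI",
    "DEFAULT_TBASE_MULTI",
]

# Stage -> DVS map for the two-phase model (WOFOST-convention ordering of
# intermediate stages; configurable because these anchors are a modelling
# convention, not observations).
DEFAULT_STAGE_DVS_2PHASE: dict[str, float] = {
    "sowing": 0.0,
    "emergence": 0.0,
    "tillering_start": 0.15,
    "stem_elongation": 0.35,
    "booting": 0.75,
    "heading": 0.90,
    "flowering": 1.0,
    "end_flowering": 1.15,
    "maturity": 2.0,
}

# Stage -> DVS map for the multi-phase model (integer sub-phase boundaries;
# heading and end-of-flowering are interpolated conventions).
DEFAULT_STAGE_DVS_MULTI: dict[str, float] = {
    "sowing": 0.0,
    "emergence": 1.0,
    "tillering_start": 2.0,
    "stem_elongation": 3.0,
    "booting": 4.0,
    "heading": 4.75,
    "flowering": 5.0,
    "end_flowering": 5.15,
    "maturity": 6.0,
}

#: per-sub-phase thermal requirement bounds (GDD) for typical Italian durum
#: wheat varieties: sowing-emergence, emergence-tillering, tillering-stem
#: elongation, stem elongation-booting, booting-flowering, flowering-ripening
TABLE_TSUM_BOUNDS: tuple[tuple[float, float], ...] = (
    (120.0, 200.0),
    (35.0, 140.0),
    (100.0, 220.0),
    (100.0, 200.0),
    (50.0, 150.0),
    (450.0, 550.0),
)

#: mid-range defaults of the bounds above
DEFAULT_TSUMS_MULTI: tuple[float, ...] = tuple(
    0.5 * (lo + hi) for lo, hi in TABLE_TSUM_BOUNDS
)

#: per-sub-phase base temperatures (°C) for the same varieties
DEFAULT_TBASE_MULTI: tuple[float, ...] = (2.0, -2.0, -2.0, 0.0, 0.0, 9.0)


#: tolerance for stage-threshold comparisons: a DVS that misses an integer
#: boundary by accumulated floating-point rounding still counts as attained
DVS_TOL = 1e-9


class IncompleteSeasonError(RuntimeError):
    """A dynamic window could not be resolved: the season never reached the
    requested development stage.  Carries the maximum DVS attained."""

    def __init__(self, message: str, max_dvs: float):
        super().__init__(message)
        self.max_dvs = max_dvs


# -- response functions -------------------------------------------------------


@dataclass
class VernalizationParams:
    """Clamped-linear vernalization response.

    ``v_base``/``v_sat`` are effective vernalization days at which the factor
    leaves 0 and reaches 1.  ``curve`` gives (temperature °C, effectiveness
    0..1) breakpoints of the daily effectiveness response; the default is
    fully effective between 3 and 10 °C and ineffective outside [-4, 17] °C.
    """

    v_base: float = 0.0
    v_sat: float = 40.0
    curve: tuple[tuple[float, float], ...] = (
        (-4.0, 0.0),
        (3.0, 1.0),
        (10.0, 1.0),
        (17.0, 0.0),
    )

    def __post_init__(self) -> None:
        if not 0 <= self.v_base < self.v_sat:
            raise ValueError("require 0 <= v_base < v_sat")

    def effectiveness(self, tavg: float) -> float:
        """Effective vernalization days contributed by one day at ``tavg``."""
        xs = [t for t, _ in self.curve]
        ys = [e for _, e in self.curve]
        return float(np.interp(tavg, xs, ys, left=0.0, right=0.0))


@dataclass
class PhotoperiodParams:
    """Clamped-linear long-day photoperiod response (wheat is a long-day crop)."""

    d_critical: float = 8.0
    d_optimal: float = 16.0

    def __post_init__(self) -> None:
        if not self.d_critical < self.d_optimal:
            raise ValueError("require d_critical < d_optimal")


def daylength(latitude: float, day_of_year) -> float | np.ndarray:
    """Astronomical daylength in hours, N = 24 ω_s / π (standard solar geometry)."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    ws = sunset_hour_angle(latitude, day_of_year)
    n = 24.0 / np.pi * ws
    return float(n) if np.isscalar(day_of_year) else n


def effective_temperature(tavg: float, t_base: float, t_max_eff: float) -> float:
    """Daily effective temperature: (tavg - t_base) clamped to [0, t_max_eff]."""
    if not t_base < t_max_eff:
        raise ValueError("require t_base < t_max_eff")
    return float(np.clip(tavg - t_base, 0.0, t_max_eff))


def vernalization_factor(state: float, params: VernalizationParams) -> float:
    """Vf in [0, 1] from accumulated effective vernalization days."""
    if state < 0:
        raise ValueError("vernalization state must be >= 0")
    return float(np.clip((state - params.v_base) / (params.v_sat - params.v_base), 0.0, 1.0))


def photoperiod_factor(daylength_h: float, params: PhotoperiodParams) -> float:
    """Pf in [0, 1] from daylength in hours."""
    if not 0.0 <= daylength_h <= 24.0:
        raise ValueError("daylength must be within [0, 24] hours")
    return float(
        np.clip(
            (daylength_h - params.d_critical) / (params.d_optimal - params.d_critical),
            0.0,
            1.0,
        )
    )


# -- variety parameter sets ---------------------------------------------------


@dataclass
class VarietyParams2:
    """Two-phase variety: vegetative (TSUM1) and reproductive (TSUM2) thermal
    requirements in GDD, with optional vernalization/photoperiod response.

    ``vern=None`` / ``photo=None`` force the corresponding factor to 1
    (insensitive variety), which is also how idealized test varieties are set
    up.
    """

    tsum1: float
    tsum2: float
    sowing_date: pd.Timestamp
    t_base: float = 0.0
    t_max_eff: float = 30.0
    vern: VernalizationParams | None = field(default_factory=VernalizationParams)
    photo: PhotoperiodParams | None = field(default_factory=PhotoperiodParams)

    def __post_init__(self) -> None:
        if self.tsum1 <= 0 or self.tsum2 <= 0:
            raise ValueError("TSUM values must be positive")
        if not self.t_base < self.t_max_eff:
            raise ValueError("require t_base < t_max_eff")
        self.sowing_date = pd.Timestamp(self.sowing_date)


@dataclass
class VarietyParamsMulti:
    """Six-sub-phase variety: per-phase thermal requirements and base
    temperatures (defaults mid-range of typical Italian durum values)."""

    tsums: Sequence[float] = DEFAULT_TSUMS_MULTI
    t_bases: Sequence[float] = DEFAULT_TBASE_MULTI
    sowing_date: pd.Timestamp = pd.Timestamp("2001-10-25")
    t_max_eff: float = 30.0
    vern: VernalizationParams | None = field(default_factory=VernalizationParams)
    photo: PhotoperiodParams | None = field(default_factory=PhotoperiodParams)

    def __post_init__(self) -> None:
        self.tsums = tuple(float(t) for t in self.tsums)
        self.t_bases = tuple(float(t) for t in self.t_bases)
        if len(self.tsums) != 6 or len(self.t_bases) != 6:
            raise ValueError("multi-phase model needs 6 tsums and 6 base temperatures")
        if any(t <= 0 for t in self.tsums):
            raise ValueError("TSUM values must be positive")
        if any(b >= self.t_max_eff for b in self.t_bases):
            raise ValueError("base temperatures must be below t_max_eff")
        self.sowing_date = pd.Timestamp(self.sowing_date)


@dataclass
class PhenologyTrack:
    """Daily DVS trajectory from sowing plus dated growth stages.

    ``dvs[0]`` is 0 on the sowing date; accumulation starts the day after
    sowing.  ``stage_dates`` maps stage name to the first date with
    DVS >= the stage's threshold.  ``complete`` is False when the series
    ended before maturity (the track is still usable; dynamic windows past
    the attained DVS raise :class:`IncompleteSeasonError`).
    """

    dates: pd.DatetimeIndex
    dvs: np.ndarray
    model_kind: str
    stage_dates: dict[str, pd.Timestamp | None]
    complete: bool
    max_stage_dvs: float

    @property
    def max_dvs(self) -> float:
        return float(self.dvs[-1])

    def first_date_at(self, threshold: float) -> pd.Timestamp | None:
        """First date with DVS >= threshold (within rounding tolerance),
        or None if never attained."""
        hit = np.nonzero(self.dvs >= threshold - DVS_TOL)[0]
        return self.dates[hit[0]] if hit.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dvs": self.dvs}, index=self.dates.rename("date"))


@dataclass
class StageWindow:
    """A static calendar window or a dynamic DVS-bounded window."""

    mode: str  # "static" | "dynamic"
    start: pd.Timestamp | None = None
    end: pd.Timestamp | None = None
    start_dvs: float | None = None
    end_dvs: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "static":
            if self.start is None or self.end is None:
                raise ValueError("static window needs calendar start and end")
            self.start, self.end = pd.Timestamp(self.start), pd.Timestamp(self.end)
            if self.start > self.end:
                raise ValueError("window start after end")
        elif self.mode == "dynamic":
            if self.start_dvs is None or self.end_dvs is None:
                raise ValueError("dynamic window needs start_dvs and end_dvs")
            if not self.start_dvs < self.end_dvs:
                raise ValueError("require start_dvs < end_dvs")
        else:
            raise ValueError("mode must be 'static' or 'dynamic'")


# -- simulation engine --------------------------------------------------------


def _daily_factors(
    tavg: np.ndarray,
    doys: np.ndarray,
    latitude: float,
    vern: VernalizationParams | None,
    photo: PhotoperiodParams | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day Vf and Pf arrays from sowing (index 0 = sowing day, unused).

    Both factors are independent of the development state: the vernalization
    state is the running sum of daily temperature effectiveness from the day
    after sowing, and the photoperiod factor depends only on the calendar.
    They can therefore be precomputed for the whole season.
    """
    n = len(tavg)
    if vern is not None:
        xs = [t for t, _ in vern.curve]
        ys = [e for _, e in vern.curve]
        effc = np.interp(tavg, xs, ys, left=0.0, right=0.0)
        effc[0] = 0.0  # accumulation starts the day after sowing
        state = np.cumsum(effc)
        vf = np.clip((state - vern.v_base) / (vern.v_sat - vern.v_base), 0.0, 1.0)
    else:
        vf = np.ones(n)
    if photo is not None:
        dl = daylength(latitude, doys)
        pf = np.clip(
            (dl - photo.d_critical) / (photo.d_optimal - photo.d_critical), 0.0, 1.0
        )
    else:
        pf = np.ones(n)
    return vf, pf


def _stage_dates(
    dates: pd.DatetimeIndex, dvs: np.ndarray, stage_map: Mapping[str, float]
) -> dict[str, pd.Timestamp | None]:
    out: dict[str, pd.Timestamp | None] = {}
    for stage, thr in stage_map.items():
        hit = np.nonzero(dvs >= thr - DVS_TOL)[0]
        out[stage] = dates[hit[0]] if hit.size else None
    return out


def simulate_2phase(
    series: WeatherSeries,
    params: VarietyParams2,
    stage_map: Mapping[str, float] | None = None,
) -> PhenologyTrack:
    """Run the two-phase thermal-time model from sowing to series end.

    Daily increment: effective temperature divided by TSUM1 and multiplied by
    Vf·Pf while DVS < 1; divided by TSUM2 (uncorrected) for 1 <= DVS < 2.
    A day whose increment crosses DVS = 1 is split: the fraction of its
    thermal time needed to complete the vegetative phase counts against
    TSUM1 (corrected), the remainder against TSUM2, so no thermal time is
    discarded at the boundary.  DVS is capped at 2.
    """
    stage_map = dict(stage_map or DEFAULT_STAGE_DVS_2PHASE)
    sow = params.sowing_date
    if sow < series.dates[0] or sow > series.dates[-1]:
        raise ValueError(
            f"sowing date {sow.date()} outside weather series "
            f"{series.dates[0].date()}..{series.dates[-1].date()}"
        )
    sub = series.data.loc[sow:]
    dates = sub.index
    tavg = (0.5 * (sub["tmin"] + sub["tmax"])).to_numpy()
    doys = dates.dayofyear.to_numpy()

    vf_arr, pf_arr = _daily_factors(
        tavg, doys, series.latitude, params.vern, params.photo
    )
    eff_arr = np.clip(tavg - params.t_base, 0.0, params.t_max_eff)

    dvs = np.zeros(len(dates))
    state = 0.0
    for i in range(1, len(dates)):
        if state >= 2.0:
            dvs[i] = 2.0
            continue
        eff = eff_arr[i]
        if state < 1.0:
            inc1 = eff * vf_arr[i] * pf_arr[i] / params.tsum1
            if state + inc1 <= 1.0:
                state += inc1
            else:
                # split the day at the flowering boundary; remaining thermal
                # time accrues under TSUM2, uncorrected
                used = (1.0 - state) / inc1 if inc1 > 0 else 1.0
                state = 1.0 + (1.0 - used) * eff / params.tsum2
        else:
            state += eff / params.tsum2
        state = min(state, 2.0)
        dvs[i] = state

    return PhenologyTrack(
        dates=dates,
        dvs=dvs,
        model_kind="2phase",
        stage_dates=_stage_dates(dates, dvs, stage_map),
        complete=bool(dvs[-1] >= 2.0 - DVS_TOL),
        max_stage_dvs=2.0,
    )


def simulate_multiphase(
    series: WeatherSeries,
    params: VarietyParamsMulti,
    stage_map: Mapping[str, float] | None = None,
) -> PhenologyTrack:
    """Run the six-sub-phase thermal-time model (DVS 0..6).

    Sub-phase ``p`` (DVS in (p-1, p]) uses its own base temperature and
    thermal requirement; Vf·Pf multiply the increment only within sub-phases
    2-5.  A day crossing an integer DVS boundary is split: the residual
    fraction of the day accrues under the next sub-phase's base temperature
    and requirement.  At most one boundary is crossed per day (with daily
    effective temperatures capped at 30 °C and requirements of tens of GDD
    this is never binding in practice).
    """
    stage_map = dict(stage_map or DEFAULT_STAGE_DVS_MULTI)
    sow = params.sowing_date
    if sow < series.dates[0] or sow > series.dates[-1]:
        raise ValueError(
            f"sowing date {sow.date()} outside weather series "
            f"{series.dates[0].date()}..{series.dates[-1].date()}"
        )
    sub = series.data.loc[sow:]
    dates = sub.index
    tavg = (0.5 * (sub["tmin"] + sub["tmax"])).to_numpy()
    doys = dates.dayofyear.to_numpy()

    vf_arr, pf_arr = _daily_factors(
        tavg, doys, series.latitude, params.vern, params.photo
    )
    tsums, tbases, tmax_eff = params.tsums, params.t_bases, params.t_max_eff

    dvs = np.zeros(len(dates))
    state = 0.0
    for i in range(1, len(dates)):
        if state >= 6.0:
            dvs[i] = 6.0
            continue
        phase = min(int(state) + 1, 6)  # DVS in [p-1, p) -> phase p
        corr = vf_arr[i] * pf_arr[i] if 2 <= phase <= 5 else 1.0
        eff = min(max(tavg[i] - tbases[phase - 1], 0.0), tmax_eff)
        inc = eff * corr / tsums[phase - 1]
        if state + inc <= phase:
            state += inc
        else:
            used = (phase - state) / inc if inc > 0 else 1.0
            state = float(phase)
            if phase < 6:
                nxt = phase + 1
                corr2 = vf_arr[i] * pf_arr[i] if 2 <= nxt <= 5 else 1.0
                eff2 = min(max(tavg[i] - tbases[nxt - 1], 0.0), tmax_eff)
                inc2 = (1.0 - used) * eff2 * corr2 / tsums[nxt - 1]
                state = min(state + inc2, float(nxt))
        state = min(state, 6.0)
        dvs[i] = state

    return PhenologyTrack(
        dates=dates,
        dvs=dvs,
        model_kind="multiphase",
        stage_dates=_stage_dates(dates, dvs, stage_map),
        complete=bool(dvs[-1] >= 6.0 - DVS_TOL),
        max_stage_dvs=6.0,
    )


def resolve_window(
    window: StageWindow, track: PhenologyTrack | None = None
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Resolve a window to calendar dates.

    Static windows pass through unchanged.  Dynamic windows resolve to the
    first date with DVS >= start_dvs through the first date with
    DVS >= end_dvs; an :class:`IncompleteSeasonError` (carrying the maximum
    DVS attained) is raised when the track never reaches a bound.
    """
    if window.mode == "static":
        return window.start, window.end
    if track is None:
        raise ValueError("dynamic window requires a phenology track")
    start = track.first_date_at(window.start_dvs)
    end = track.first_date_at(window.end_dvs)
    if start is None or end is None:
        bound = window.start_dvs if start is None else window.end_dvs
        raise IncompleteSeasonError(
            f"season incomplete: DVS reached {track.max_dvs:.3f}, window "
            f"bound {bound:g} never attained",
            max_dvs=track.max_dvs,
        )
    return start, end
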
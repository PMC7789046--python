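"""Phenology-linked agro-climate indicators for the winter-wheat season.

Sixteen built-in indicators cover four risk groups:

* **hydrological balance** (ids 1-6): standardized water-balance anomalies
  (SPEI) over pre-sowing, sowing-emergence, tillering, stem
  elongation-booting, heading-maturity and whole-season windows;
* **excessive wetness** (ids 7-13): pre-sowing rainfall cumulate, counts of
  days above 10/40/5/40 mm, and maximum consecutive runs of days above 5 mm
  around flowering;
* **cold stress** (id 14): days with tmin below 2 °C between booting and
  flowering;
* **heat stress** (ids 15-16): days with tmax above 28 °C between booting
  and end of flowering, and between end of flowering and maturity.

Windows are either static calendar periods or dynamic, resolved from a
simulated development-stage track so that the sensitive periods follow the
actual thermal conditions of each season.  Threshold comparisons are strict
("above 5 mm" means > 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import phenology as ph
from .spei import MIN_REFERENCE_N, spei_for_window
from .water_balance import WaterBalanceSeries, climatic_water_balance
from .weather import WeatherSeries

__all__ = [
    "IndicatorSpec",
    "IndicatorResult",
    "builtin_registry",
    "count_days",
    "cumulate",
    "max_consecutive",
    "compute_indicators",
    "clis_agri",
    "DEFAULT_STATIC_CALENDAR",
    "DEFAULT_PRE_SOWING_DAYS",
]

#: length of the pre-sowing window (days before the sowing date)
DEFAULT_PRE_SOWING_DAYS = 30

#: (month, day) anchors for static windows: the calendar periods in which the
#: growth stages of October-sown Mediterranean winter wheat typically occur
DEFAULT_STATIC_CALENDAR: dict[str, tuple[int, int]] = {
    "sowing": (10, 25),
    "emergence": (11, 10),
    "tillering_start": (12, 1),
    "stem_elongation": (3, 1),
    "booting": (4, 10),
    "heading": (4, 25),
    "flowering": (5, 5),
    "end_flowering": (5, 15),
    "maturity": (6, 30),
}


@dataclass(frozen=True)
class IndicatorSpec:
    """Definition of one indicator: statistic, variable, threshold, window."""

    id: int
    group: str  # hydrological | wetness | cold | heat
    name: str
    statistic: str  # spei | cumulate | count | max_consecutive
    variable: str | None  # precip | tmin | tmax (None for spei)
    threshold: float | None  # mm or °C
    direction: str | None  # above | below
    start_stage: str  # stage name, or "pre_sowing"
    end_stage: str


@dataclass
class IndicatorResult:
    id: int
    name: str
    window: tuple[pd.Timestamp, pd.Timestamp]
    value: float
    risk_class: str | None
    season_complete: bool


_REGISTRY: tuple[IndicatorSpec, ...] = (
    IndicatorSpec(1, "hydrological", "SPEI pre-sowing", "spei", None, None, None, "pre_sowing", "sowing"),
    IndicatorSpec(2, "hydrological", "SPEI sowing-emergence", "spei", None, None, None, "sowing", "emergence"),
    IndicatorSpec(3, "hydrological", "SPEI tillering", "spei", None, None, None, "tillering_start", "stem_elongation"),
    IndicatorSpec(4, "hydrological", "SPEI stem elongation-booting", "spei", None, None, None, "stem_elongation", "booting"),
    IndicatorSpec(5, "hydrological", "SPEI heading-maturity", "spei", None, None, None, "heading", "maturity"),
    IndicatorSpec(6, "hydrological", "SPEI sowing-maturity", "spei", None, None, None, "sowing", "maturity"),
    IndicatorSpec(7, "wetness", "rainfall cumulate pre-sowing", "cumulate", "precip", None, None, "pre_sowing", "sowing"),
    IndicatorSpec(8, "wetness", "days rainfall > 10 mm, tillering", "count", "precip", 10.0, "above", "tillering_start", "stem_elongation"),
    IndicatorSpec(9, "wetness", "days rainfall > 40 mm, tillering", "count", "precip", 40.0, "above", "tillering_start", "stem_elongation"),
    IndicatorSpec(10, "wetness", "days rainfall > 5 mm, heading-maturity", "count", "precip", 5.0, "above", "heading", "maturity"),
    IndicatorSpec(11, "wetness", "days rainfall > 40 mm, heading-maturity", "count", "precip", 40.0, "above", "heading", "maturity"),
    IndicatorSpec(12, "wetness", "max consecutive days rainfall > 5 mm, heading-flowering", "max_consecutive", "precip", 5.0, "above", "heading", "flowering"),
    IndicatorSpec(13, "wetness", "max consecutive days rainfall > 5 mm, flowering-maturity", "max_consecutive", "precip", 5.0, "above", "flowering", "maturity"),
    IndicatorSpec(14, "cold", "days tmin < 2 °C, booting-flowering", "count", "tmin", 2.0, "below", "booting", "flowering"),
    IndicatorSpec(15, "heat", "days tmax > 28 °C, booting-end of flowering", "count", "tmax", 28.0, "above", "booting", "end_flowering"),
    IndicatorSpec(16, "heat", "days tmax > 28 °C, end of flowering-maturity", "count", "tmax", 28.0, "above", "end_flowering", "maturity"),
)


def builtin_registry() -> list[IndicatorSpec]:
    """The sixteen built-in indicator definitions, in id order."""
    return list(_REGISTRY)


def _window_values(
    series: WeatherSeries,
    window: tuple[pd.Timestamp, pd.Timestamp],
    variable: str,
) -> np.ndarray:
    sub = series.slice(window[0], window[1])
    if len(sub) == 0:
        raise ValueError("empty indicator window")
    return sub[variable].to_numpy()


def count_days(
    series: WeatherSeries,
    window: tuple[pd.Timestamp, pd.Timestamp],
    variable: str,
    threshold: float,
    direction: str = "above",
) -> int:
    """Number of days in the window with the variable strictly above/below
    the threshold."""
    vals = _window_values(series, window, variable)
    if direction == "above":
        return int((vals > threshold).sum())
    if direction == "below":
        return int((vals < threshold).sum())
    raise ValueError("direction must be 'above' or 'below'")


def cumulate(
    series: WeatherSeries,
    window: tuple[pd.Timestamp, pd.Timestamp],
    variable: str = "precip",
) -> float:
    """Sum of the variable over the window (mm for precipitation)."""
    return float(_window_values(series, window, variable).sum())


def max_consecutive(
    series: WeatherSeries,
    window: tuple[pd.Timestamp, pd.Timestamp],
    variable: str,
    threshold: float,
    direction: str = "above",
) -> int:
    """Longest run of consecutive days qualifying against the threshold."""
    vals = _window_values(series, window, variable)
    qual = vals > threshold if direction == "above" else vals < threshold
    best = run = 0
    for q in qual:
        run = run + 1 if q else 0
        best = max(best, run)
    return best


# -- window resolution --------------------------------------------------------


def _static_anchor(
    stage: str,
    sowing_date: pd.Timestamp,
    calendar: Mapping[str, tuple[int, int]],
) -> pd.Timestamp:
    """Calendar date of a stage anchor for the season containing ``sowing_date``.

    Anchors with month >= August belong to the sowing calendar year; earlier
    months belong to the following (harvest) year.
    """
    month, day = calendar[stage]
    year = sowing_date.year if month >= 8 else sowing_date.year + 1
    return pd.Timestamp(year=year, month=month, day=day)


def _resolve_indicator_window(
    spec: IndicatorSpec,
    sowing_date: pd.Timestamp,
    mode: str,
    track: ph.PhenologyTrack | None,
    stage_map: Mapping[str, float],
    static_calendar: Mapping[str, tuple[int, int]],
    pre_sowing_days: int,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    def stage_date(stage: str) -> pd.Timestamp:
        if stage == "pre_sowing":
            return sowing_date - pd.Timedelta(days=pre_sowing_days)
        if mode == "static":
            if stage == "sowing":
                return sowing_date
            return _static_anchor(stage, sowing_date, static_calendar)
        assert track is not None
        date = track.first_date_at(stage_map[stage])
        if date is None:
            raise ph.IncompleteSeasonError(
                f"stage {stage!r} (DVS {stage_map[stage]:g}) not reached; "
                f"max DVS {track.max_dvs:.3f}",
                max_dvs=track.max_dvs,
            )
        return date

    start = stage_date(spec.start_stage)
    end = stage_date(spec.end_stage)
    if spec.start_stage == "pre_sowing":
        # pre-sowing window ends the day before sowing
        end = sowing_date - pd.Timedelta(days=1)
    return start, end


def compute_indicators(
    series: WeatherSeries,
    sowing_date: pd.Timestamp,
    track: ph.PhenologyTrack | None,
    stage_map: Mapping[str, float],
    selection: Sequence[int] | None = None,
    mode: str = "dynamic",
    wb: WaterBalanceSeries | None = None,
    static_calendar: Mapping[str, tuple[int, int]] | None = None,
    pre_sowing_days: int = DEFAULT_PRE_SOWING_DAYS,
    min_reference: int = MIN_REFERENCE_N,
    plotting_position: str = "weibull",
) -> list[IndicatorResult]:
    """Compute selected indicators for one season given a resolved track.

    This is the engine behind :func:`clis_agri`; it accepts any phenology
    track (two-phase or multi-phase) together with the matching
    stage->DVS map, which is what the variety optimizer uses.
    """
    registry = {s.id: s for s in _REGISTRY}
    ids = list(selection) if selection is not None else sorted(registry)
    unknown = [i for i in ids if i not in registry]
    if unknown:
        raise KeyError(f"unknown indicator id(s): {unknown}")
    static_calendar = dict(static_calendar or DEFAULT_STATIC_CALENDAR)
    sowing_date = pd.Timestamp(sowing_date)

    need_spei = any(registry[i].statistic == "spei" for i in ids)
    if need_spei and wb is None:
        wb = climatic_water_balance(series)

    results: list[IndicatorResult] = []
    for i in ids:
        spec = registry[i]
        try:
            window = _resolve_indicator_window(
                spec, sowing_date, mode, track, stage_map, static_calendar, pre_sowing_days
            )
        except ph.IncompleteSeasonError:
            results.append(
                IndicatorResult(i, spec.name, (pd.NaT, pd.NaT), float("nan"), None, False)
            )
            continue
        if spec.statistic == "spei":
            assert wb is not None
            res = spei_for_window(
                wb, window[0], window[1],
                plotting_position=plotting_position, min_n=min_reference,
            )
            value, risk = res.spei, res.risk_class
        elif spec.statistic == "cumulate":
            value, risk = cumulate(series, window, spec.variable), None
        elif spec.statistic == "count":
            value = float(
                count_days(series, window, spec.variable, spec.threshold, spec.direction)
            )
            risk = None
        elif spec.statistic == "max_consecutive":
            value = float(
                max_consecutive(series, window, spec.variable, spec.threshold, spec.direction)
            )
            risk = None
        else:  # pragma: no cover - registry is closed
            raise ValueError(f"unknown statistic {spec.statistic!r}")
        complete = track.complete if track is not None else True
        results.append(IndicatorResult(i, spec.name, window, value, risk, complete))
    return results


def clis_agri(
    series: WeatherSeries,
    params: ph.VarietyParams2,
    selection: Sequence[int] | None = None,
    mode: str = "dynamic",
    stage_map: Mapping[str, float] | None = None,
    static_calendar: Mapping[str, tuple[int, int]] | None = None,
    pre_sowing_days: int = DEFAULT_PRE_SOWING_DAYS,
    min_reference: int = MIN_REFERENCE_N,
    plotting_position: str = "weibull",
) -> list[IndicatorResult]:
    """Compute agro-climate indicators for the season sown at
    ``params.sowing_date``.

    In dynamic mode the two-phase phenology model is run internally and the
    indicator windows follow the simulated development stages; in static mode
    the default (configurable) calendar anchors are used.  Hydrological
    indicators additionally require the weather series to span enough years
    to build the same-window reference sample for standardization.
    """
    stage_map = dict(stage_map or ph.DEFAULT_STAGE_DVS_2PHASE)
    track = None
    if mode == "dynamic":
        track = ph.simulate_2phase(series, params, stage_map=stage_map)
    elif mode != "static":
        raise ValueError("mode must be 'static' or 'dynamic'")
    return compute_indicators(
        series,
        params.sowing_date,
        track,
        stage_map,
        selection=selection,
        mode=mode,
        static_calendar=static_calendar,
        pre_sowing_days=pre_sowing_days,
        min_reference=min_reference,
        plotting_position=plotting_position,
    )


def results_to_frame(results: Sequence[IndicatorResult]) -> pd.DataFrame:
    """Tabular export of indicator results."""
    return pd.DataFrame(
        {
            "id": [r.id for r in results],
            "name": [r.name for r in results],
            "window_start": [r.window[0] for r in results],
            "window_end": [r.window[1] for r in results],
            "value": [r.value for r in results],
            "risk_class": [r.risk_class for r in results],
            "season_complete": [r.season_complete for r in results],
        }
    )
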
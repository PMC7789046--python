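"""Non-parametric standardized precipitation–evapotranspiration index (SPEI).

The climatic water balance is aggregated over a (phenology-resolved) window;
the aggregate is standardized without fitting a parametric distribution:
its rank among same-window aggregates from other years is turned into an
empirical probability through a plotting position and mapped to standard
normal units with the inverse normal CDF.  Drought/wetness severity classes
follow the usual seven-band convention (moderate drought between -1.5 and
-1, severe between -2 and -1.5, extreme below -2, mirrored on the wet side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .water_balance import WaterBalanceSeries

__all__ = [
    "ReferenceSample",
    "SpeiResult",
    "aggregate_balance",
    "build_reference",
    "spei_nonparametric",
    "classify_spei",
    "spei_for_window",
    "RISK_CLASSES",
]

RISK_CLASSES = (
    "extreme_drought",
    "severe_drought",
    "moderate_drought",
    "normal",
    "moderately_wet",
    "very_wet",
    "extremely_wet",
)

#: fewer reference years than this raises; fewer than 30 warns
MIN_REFERENCE_N = 10
RECOMMENDED_REFERENCE_N = 30


class ReferenceTooSmallError(ValueError):
    """Raised when too few reference aggregates are available."""


@dataclass
class ReferenceSample:
    """Same-window water-balance aggregates (mm) across reference years."""

    values: np.ndarray
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class SpeiResult:
    window: tuple[pd.Timestamp, pd.Timestamp]
    aggregate_balance: float
    spei: float
    risk_class: str


def aggregate_balance(
    wb: WaterBalanceSeries, start: pd.Timestamp, end: pd.Timestamp
) -> float:
    """Sum of the daily balance over an inclusive date window (mm)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError("window start after end")
    if start < wb.dates[0] or end > wb.dates[-1]:
        raise ValueError(
            f"window {start.date()}..{end.date()} outside balance series"
        )
    return float(wb.balance.loc[start:end].sum())


def build_reference(
    wb: WaterBalanceSeries,
    start: pd.Timestamp,
    end: pd.Timestamp,
    min_n: int = MIN_REFERENCE_N,
    leave_current_out: bool = False,
) -> ReferenceSample:
    """Collect same-window aggregates across every year the series covers.

    The target window is shifted by whole calendar years in both directions
    while it remains inside the series (Feb 29 clamps to Feb 28 in non-leap
    years).  By default the target year itself is part of its own reference
    (leave-current-in); set ``leave_current_out`` to exclude it.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    values, years = [], []
    first, last = wb.dates[0], wb.dates[-1]
    # widest plausible span of shifts
    span = last.year - first.year + 1
    for k in range(-span, span + 1):
        if leave_current_out and k == 0:
            continue
        s = start + pd.DateOffset(years=k)
        e = end + pd.DateOffset(years=k)
        if s < first or e > last:
            continue
        values.append(aggregate_balance(wb, s, e))
        years.append(s.year)
    if len(values) < min_n:
        raise ReferenceTooSmallError(
            f"only {len(values)} reference aggregates available (minimum {min_n})"
        )
    if len(values) < RECOMMENDED_REFERENCE_N:
        warnings.warn(
            f"reference sample has {len(values)} years; standardized index "
            f"reliability degrades below {RECOMMENDED_REFERENCE_N}",
            stacklevel=2,
        )
    return ReferenceSample(np.asarray(values), years)


def _plotting_position(rank: float, n: int, kind: str) -> float:
    if kind == "weibull":
        return rank / (n + 1.0)
    if kind == "gringorten":
        return (rank - 0.44) / (n + 0.12)
    raise ValueError(f"unknown plotting position: {kind!r}")


def spei_nonparametric(
    value: float,
    reference: ReferenceSample,
    plotting_position: str = "weibull",
    min_n: int = MIN_REFERENCE_N,
) -> float:
    """Standardize an aggregate against its reference sample.

    The evaluated value is ranked within the union of the reference and
    itself, with ties sharing the mean rank and without double-counting: a
    value that coincides with a reference member (the leave-current-in case,
    where the current year's aggregate is part of its own reference) takes
    exactly that member's rank, while a new value takes the half-step rank
    between its neighbours::

        r = #(reference < value) + (#(reference == value) + 1) / 2

    The empirical probability is then the plotting position of ``r`` in the
    reference sample of size n (Weibull ``r/(n+1)`` by default, Gringorten
    available) and the index is its standard normal quantile.  Because the
    plotting position is bounded away from 0 and 1, the result is always
    finite.
    """
    if reference.n < min_n:
        raise ReferenceTooSmallError(
            f"reference sample of {reference.n} below minimum {min_n}"
        )
    ref = reference.values
    value = float(value)
    rank = float(np.count_nonzero(ref < value)) + 0.5 * (
        float(np.count_nonzero(ref == value)) + 1.0
    )
    p = _plotting_position(rank, reference.n, plotting_position)
    return float(stats.norm.ppf(p))


def classify_spei(spei: float) -> str:
    """Seven-band severity class of a standardized balance anomaly.

    Band edges are assigned to the more severe class: exactly -1.5 is
    severe_drought, exactly +2 is extremely_wet.
    """
    if not np.isfinite(spei):
        raise ValueError("SPEI must be finite")
    if spei <= -2.0:
        return "extreme_drought"
    if spei <= -1.5:
        return "severe_drought"
    if spei <= -1.0:
        return "moderate_drought"
    if spei < 1.0:
        return "normal"
    if spei < 1.5:
        return "moderately_wet"
    if spei < 2.0:
        return "very_wet"
    return "extremely_wet"


def spei_for_window(
    wb: WaterBalanceSeries,
    start: pd.Timestamp,
    end: pd.Timestamp,
    plotting_position: str = "weibull",
    min_n: int = MIN_REFERENCE_N,
    leave_current_out: bool = False,
) -> SpeiResult:
    """Aggregate, standardize and classify one window in one call."""
    agg = aggregate_balance(wb, start, end)
    ref = build_reference(
        wb, start, end, min_n=min_n, leave_current_out=leave_current_out
    )
    z = spei_nonparametric(agg, ref, plotting_position=plotting_position, min_n=min_n)
    return SpeiResult(
        window=(pd.Timestamp(start), pd.Timestamp(end)),
        aggregate_balance=agg,
        spei=z,
        risk_class=classify_spei(z),
    )
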
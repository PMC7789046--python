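"""Daily weather series: containers, validation, CSV I/O and ensemble handling.

A :class:`WeatherSeries` is the single input stream for the whole toolkit:
a gap-free daily sequence of minimum/maximum temperature (°C) and
precipitation (mm) together with the site latitude (needed for solar
geometry).  Ensembles of series (e.g. members of a seasonal climate
prediction) are held in a :class:`WeatherEnsemble` and processed member by
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeatherFormatError",
    "WeatherValidationError",
    "DailyRecord",
    "WeatherSeries",
    "WeatherEnsemble",
    "read_weather_csv",
    "write_weather_csv",
    "read_ensemble_csv",
    "write_ensemble_csv",
    "read_ensemble_dir",
    "map_over_ensemble",
    "summarize_ensemble",
]

REQUIRED_COLUMNS = ("date", "tmin", "tmax", "precip")


class WeatherFormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class WeatherValidationError(ValueError):
    """Raised when weather values violate physical/structural invariants."""


@dataclass(frozen=True)
class DailyRecord:
    """One day of weather: tmin/tmax in °C, precip in mm (non-negative)."""

    date: pd.Timestamp
    tmin: float
    tmax: float
    precip: float

    @property
    def tavg(self) -> float:
        return 0.5 * (self.tmin + self.tmax)


@dataclass
class WeatherSeries:
    """Contiguous daily weather at one site.

    Parameters
    ----------
    data
        DataFrame with a ``DatetimeIndex`` (daily, strictly consecutive, no
        gaps) and columns ``tmin``, ``tmax``, ``precip``.
    latitude
        Site latitude in decimal degrees, within [-90, 90].
    site_id
        Free-form site label.
    """

    data: pd.DataFrame
    latitude: float
    site_id: str = "site"

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise WeatherFormatError("weather data must be indexed by date")
        missing = [c for c in ("tmin", "tmax", "precip") if c not in self.data.columns]
        if missing:
            raise WeatherFormatError(f"missing column(s): {', '.join(missing)}")
        if len(self.data) < 1:
            raise WeatherValidationError("weather series must contain at least one day")
        if not -90.0 <= float(self.latitude) <= 90.0:
            raise WeatherValidationError(f"latitude {self.latitude} outside [-90, 90]")
        self.data = self.data[["tmin", "tmax", "precip"]].astype(float)
        self.data.index.name = "date"
        self._validate_values()

    def _validate_values(self) -> None:
        df = self.data
        if df[["tmin", "tmax", "precip"]].isna().any().any():
            bad = df.index[df.isna().any(axis=1)][0]
            raise WeatherValidationError(f"missing value on {bad.date()}")
        idx = df.index
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if (deltas <= 0).any():
                bad = idx[1:][deltas <= 0][0]
                raise WeatherValidationError(f"dates not strictly increasing at {bad.date()}")
            if (deltas > 1).any():
                prev = idx[:-1][deltas > 1][0]
                first_gap = (prev + pd.Timedelta(days=1)).date()
                raise WeatherValidationError(f"gap in daily dates: missing {first_gap}")
        bad_t = df["tmin"] > df["tmax"]
        if bad_t.any():
            d = df.index[bad_t][0]
            raise WeatherValidationError(
                f"tmin > tmax on {d.date()} "
                f"({df.loc[d, 'tmin']:g} > {df.loc[d, 'tmax']:g})"
            )
        if (df["precip"] < 0).any():
            d = df.index[df["precip"] < 0][0]
            raise WeatherValidationError(f"negative precipitation on {d.date()}")

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def tmin(self) -> pd.Series:
        return self.data["tmin"]

    @property
    def tmax(self) -> pd.Series:
        return self.data["tmax"]

    @property
    def precip(self) -> pd.Series:
        return self.data["precip"]

    @property
    def tavg(self) -> pd.Series:
        return 0.5 * (self.data["tmin"] + self.data["tmax"])

    def records(self) -> list[DailyRecord]:
        return [
            DailyRecord(d, r.tmin, r.tmax, r.precip)
            for d, r in zip(self.data.index, self.data.itertuples())
        ]

    @classmethod
    def from_records(
        cls, records: Sequence[DailyRecord], latitude: float, site_id: str = "site"
    ) -> "WeatherSeries":
        df = pd.DataFrame(
            {
                "tmin": [r.tmin for r in records],
                "tmax": [r.tmax for r in records],
                "precip": [r.precip for r in records],
            },
            index=pd.DatetimeIndex([r.date for r in records], name="date"),
        )
        return cls(df, latitude=latitude, site_id=site_id)

    @classmethod
    def from_arrays(
        cls,
        dates: pd.DatetimeIndex,
        tmin: np.ndarray,
        tmax: np.ndarray,
        precip: np.ndarray,
        latitude: float,
        site_id: str = "site",
    ) -> "WeatherSeries":
        df = pd.DataFrame(
            {"tmin": tmin, "tmax": tmax, "precip": precip},
            index=pd.DatetimeIndex(dates, name="date"),
        )
        return cls(df, latitude=latitude, site_id=site_id)

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
        """Inclusive date-window view of the underlying frame."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start < self.dates[0] or end > self.dates[-1]:
            raise WeatherValidationError(
                f"window {start.date()}..{end.date()} outside series "
                f"{self.dates[0].date()}..{self.dates[-1].date()}"
            )
        if start > end:
            raise WeatherValidationError("window start after window end")
        return self.data.loc[start:end]


@dataclass
class WeatherEnsemble:
    """A set of equally-likely weather realizations sharing dates and site."""

    members: list[WeatherSeries]
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise WeatherValidationError("ensemble must have at least one member")
        if not self.member_ids:
            self.member_ids = [f"m{i:02d}" for i in range(len(self.members))]
        if len(self.member_ids) != len(self.members):
            raise WeatherValidationError("member_ids length mismatch")
        ref = self.members[0]
        for m, mid in zip(self.members[1:], self.member_ids[1:]):
            if not m.dates.equals(ref.dates):
                raise WeatherValidationError(f"member {mid}: date range differs")
            if m.latitude != ref.latitude:
                raise WeatherValidationError(f"member {mid}: latitude differs")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def latitude(self) -> float:
        return self.members[0].latitude

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.members[0].dates


# -- I/O ----------------------------------------------------------------------


def _read_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherFormatError(f"{path}: unparsable date: {exc}") from exc
    return df


def read_weather_csv(
    path: str | Path, latitude: float, site_id: str | None = None
) -> WeatherSeries:
    """Read and validate a single-site daily weather CSV.

    Expected columns: ``date`` (ISO-8601), ``tmin``, ``tmax`` (°C),
    ``precip`` (mm).  Gaps in the daily sequence, tmin > tmax, negative
    precipitation and missing values are rejected with explicit errors.
    """
    df = _read_frame(path)
    df = df.set_index("date")
    return WeatherSeries(
        df, latitude=latitude, site_id=site_id or Path(path).stem
    )


def write_weather_csv(series: WeatherSeries, path: str | Path) -> None:
    """Write a series back to CSV (ISO dates, '.' decimal) — round-trip safe."""
    out = series.data.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)


def read_ensemble_csv(
    path: str | Path, latitude: float, site_id: str | None = None
) -> WeatherEnsemble:
    """Read a long-format ensemble CSV with a ``member_id`` column."""
    df = _read_frame(path)
    if "member_id" not in df.columns:
        raise WeatherFormatError(f"{path}: ensemble CSV requires a member_id column")
    members, ids = [], []
    for mid, grp in df.groupby("member_id", sort=True):
        sub = grp.set_index("date")[["tmin", "tmax", "precip"]]
        members.append(
            WeatherSeries(sub, latitude=latitude, site_id=site_id or Path(path).stem)
        )
        ids.append(str(mid))
    return WeatherEnsemble(members, ids)


def write_ensemble_csv(ensemble: WeatherEnsemble, path: str | Path) -> None:
    frames = []
    for mid, m in zip(ensemble.member_ids, ensemble.members):
        f = m.data.copy()
        f.insert(0, "date", f.index.strftime("%Y-%m-%d"))
        f.insert(0, "member_id", mid)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ensemble_dir(
    directory: str | Path, latitude: float, pattern: str = "*.csv"
) -> WeatherEnsemble:
    """Read one member per CSV file in a directory (sorted by filename)."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise WeatherFormatError(f"no files matching {pattern} in {directory}")
    members = [read_weather_csv(p, latitude=latitude) for p in paths]
    return WeatherEnsemble(members, [p.stem for p in paths])


# -- ensemble operations ------------------------------------------------------


def map_over_ensemble(ensemble: WeatherEnsemble, fn: Callable) -> list:
    """Apply ``fn`` independently to every member, preserving member order."""
    if len(ensemble) == 0:
        raise WeatherValidationError("empty ensemble")
    return [fn(m) for m in ensemble.members]


def summarize_ensemble(values: Sequence[float]) -> dict:
    """Summarize per-member numeric results (NaN members excluded, counted).

    Returns mean/median/q10/q90/min/max plus ``n`` (valid members) and
    ``n_missing``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise WeatherValidationError("no values to summarize")
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        raise WeatherValidationError("all ensemble values are NaN")
    return {
        "mean": float(np.mean(valid)),
        "median": float(np.median(valid)),
        "q10": float(np.quantile(valid, 0.10)),
        "q90": float(np.quantile(valid, 0.90)),
        "min": float(np.min(valid)),
        "max": float(np.max(valid)),
        "n": int(valid.size),
        "n_missing": int(arr.size - valid.size),
    }
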
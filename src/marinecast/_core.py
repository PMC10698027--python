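"""Shared plumbing: exceptions, month arithmetic, great-circle distance,
and the scalar monthly index container used by both management tools."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "ConfigurationError",
    "SchemaError",
    "CoverageError",
    "IndexSeries",
    "haversine_km",
    "month_range",
    "periods_from_ordinals",
    "to_period",
]


class ConfigurationError(ValueError):
    """Invalid domain/parameter configuration (empty masks, bad bounds...)."""


class SchemaError(ValueError):
    """A file does not follow the expected CF-style layout (dims, units)."""


class CoverageError(ValueError):
    """Required (year, month) / (init, lead) coverage is missing."""


def to_period(value) -> pd.Period:
    """Coerce a (year, month) pair, 'YYYY-MM' string, or Period to monthly Period."""
    if isinstance(value, pd.Period):
        if value.freqstr not in ("M", "ME"):
            raise ConfigurationError(f"expected a monthly period, got freq {value.freqstr!r}")
        return value
    if isinstance(value, (tuple, list)) and len(value) == 2:
        year, month = value
        return pd.Period(year=int(year), month=int(month), freq="M")
    return pd.Period(value, freq="M")


def periods_from_ordinals(ordinals) -> pd.PeriodIndex:
    """Monthly PeriodIndex from integer month ordinals (epoch Jan 1970)."""
    return pd.PeriodIndex.from_ordinals(np.asarray(ordinals, dtype=np.int64), freq="M")


def month_range(year_range: tuple[int, int]) -> pd.PeriodIndex:
    """All calendar months from Jan of the first year to Dec of the last, inclusive."""
    y0, y1 = int(year_range[0]), int(year_range[1])
    if y1 < y0:
        raise ConfigurationError(f"year range {year_range} is reversed")
    return pd.period_range(start=f"{y0}-01", end=f"{y1}-12", freq="M")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371 km).

    Inputs are degrees and broadcast against each other.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class IndexSeries:
    """Monthly scalar index values with optional event classification.

    ``values`` is unitless in [0, 1] for the habitat compression index or °C
    for 6-month-mean SST anomalies.  ``event_flags`` marks classified events
    (high compression / recommended closure); NaN values carry NaN flags —
    an undefined month is never silently treated as "no event".
    """

    times: pd.PeriodIndex
    values: np.ndarray
    kind: str = "index"
    units: str = ""
    event_flags: np.ndarray | None = None
    event_rule: str = ""

    def __post_init__(self):
        times = pd.PeriodIndex(self.times, freq="M")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(times),):
            raise ConfigurationError(
                f"values shape {values.shape} does not match {len(times)} times"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.event_flags is not None:
            flags = np.asarray(self.event_flags, dtype=float)
            if flags.shape != values.shape:
                raise ConfigurationError("event_flags shape mismatch")
            object.__setattr__(self, "event_flags", flags)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def years(self) -> np.ndarray:
        return self.times.year.to_numpy()

    @property
    def months(self) -> np.ndarray:
        return self.times.month.to_numpy()

    def value_at(self, period) -> float:
        period = to_period(period)
        loc = self.times.get_indexer([period])
        if loc[0] < 0:
            raise KeyError(f"{period} not in series")
        return float(self.values[loc[0]])

    def select_years(self, year_range: tuple[int, int]) -> "IndexSeries":
        keep = (self.years >= year_range[0]) & (self.years <= year_range[1])
        return replace(
            self,
            times=self.times[keep],
            values=self.values[keep],
            event_flags=None if self.event_flags is None else self.event_flags[keep],
        )

    def select_month(self, month: int) -> "IndexSeries":
        keep = self.months == month
        return replace(
            self,
            times=self.times[keep],
            values=self.values[keep],
            event_flags=None if self.event_flags is None else self.event_flags[keep],
        )

    def with_events(self, flags: np.ndarray, rule: str) -> "IndexSeries":
        return replace(self, event_flags=np.asarray(flags, dtype=float), event_rule=rule)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.times.astype(str), "value": self.values})
        if self.event_flags is not None:
            out["event"] = self.event_flags
        return out


def align_series(a: IndexSeries, b: IndexSeries) -> tuple[np.ndarray, np.ndarray, pd.PeriodIndex]:
    """Values of two series on their common months (order of ``a``)."""
    common = a.times.intersection(b.times)
    ia = a.times.get_indexer(common)
    ib = b.times.get_indexer(common)
    return a.values[ia], b.values[ib], common
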
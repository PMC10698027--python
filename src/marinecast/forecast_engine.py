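"""Lead/initialization bookkeeping, drift correction, and ensemble assembly.

Forecast systems drift: their mean state at long leads departs from the
observed climatology.  Following standard practice, anomalies are computed
against climatologies specific to each ensemble member and each lead time,
which removes the drift by construction.  This module also defines the four
retrospective configurations compared downstream (a full 73-member global
ensemble over 1981-2020, plus three 1981-2010 configurations: the full global
ensemble, a 3-member reduced global ensemble, and a 3-member "downscaled"
ensemble with January/July-only initializations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._core import ConfigurationError, CoverageError, IndexSeries
from .synthetic_ocean import ForecastSet, GridSpec

__all__ = [
    "LeadClimatology",
    "LeadForecast",
    "EnsembleConfig",
    "lead_climatology",
    "anomalize",
    "ensemble_mean",
    "build_configurations",
]


@dataclass(frozen=True)
class LeadClimatology:
    """Mean SST per (member, lead, calendar month) over the climatology years.

    NaN entries mark (lead, month) pairs never targeted by the forecast
    set's initialization schedule (e.g. only two months per lead exist for a
    Jan/Jul schedule); downstream use only touches months that occur.
    """

    grid: GridSpec
    members: tuple[str, ...]
    leads: np.ndarray
    clim_years: tuple[int, int]
    values: np.ndarray  # (member, lead, 12, lat, lon)
    covered: np.ndarray  # (lead, 12) bool

    def field(self, member_idx: int, lead_idx: int, month: int) -> np.ndarray:
        return self.values[member_idx, lead_idx, month - 1]


@dataclass(frozen=True)
class LeadForecast:
    """Ensemble index forecasts for one lead (one target month per init).

    ``member_values`` is (member, time); ``ensemble`` the member-averaged
    IndexSeries, carrying event flags once classified.  ``closure_month``
    distinguishes the closure-indicator groupings (one series per closure
    month) from the compression-index groupings (all target months).
    """

    lead: float
    times: pd.PeriodIndex
    member_values: np.ndarray
    ensemble: IndexSeries
    closure_month: int | None = None
    threshold: float | None = None


def lead_climatology(forecasts: ForecastSet, clim_years: tuple[int, int]) -> LeadClimatology:
    """Mean forecast SST separately per member, lead, and calendar month.

    Averages over initializations whose *target* falls in ``clim_years``.
    Raises listing the missing (lead, month) pairs if the schedule targets a
    (lead, month) pair with no climatology-year coverage at all.
    """
    t_month = forecasts.target_months  # (init, lead)
    t_year = forecasts.target_years
    n_i, n_l = t_month.shape
    n_m = len(forecasts.members)
    out = np.full((n_m, n_l, 12) + forecasts.grid.shape, np.nan, dtype=np.float32)
    covered = np.zeros((n_l, 12), dtype=bool)
    missing = []
    in_years = (t_year >= clim_years[0]) & (t_year <= clim_years[1])
    for l in range(n_l):
        months_here = np.unique(t_month[:, l])
        for m in months_here:
            sel = (t_month[:, l] == m) & in_years[:, l]
            if not sel.any():
                missing.append((float(forecasts.leads[l]), int(m)))
                continue
            # mean over qualifying inits -> (member, lat, lon)
            out[:, l, m - 1] = np.nanmean(forecasts.values[sel, l], axis=0)
            covered[l, m - 1] = True
    if missing:
        raise CoverageError(
            f"no climatology-year coverage for (lead, month) pairs: {missing[:12]}"
            + ("..." if len(missing) > 12 else "")
        )
    return LeadClimatology(
        grid=forecasts.grid,
        members=forecasts.members,
        leads=forecasts.leads,
        clim_years=tuple(clim_years),
        values=out,
        covered=covered,
    )


def anomalize(forecasts: ForecastSet, lead_clim: LeadClimatology) -> ForecastSet:
    """Subtract each member's own (member, lead, month) climatology.

    Removes lead-dependent drift and constant member biases by construction;
    anomalizing an already-anomalized set against its own lead climatology is
    the identity (idempotence), since the residual climatology is zero.
    """
    if tuple(lead_clim.members) != tuple(forecasts.members) or not np.array_equal(
        lead_clim.leads, forecasts.leads
    ):
        raise ConfigurationError("lead climatology does not match the forecast set")
    t_month = forecasts.target_months  # (init, lead)
    anoms = np.empty_like(forecasts.values)
    for l in range(forecasts.leads.size):
        clim_l = lead_clim.values[:, l, t_month[:, l] - 1]  # (member, init, lat, lon)
        anoms[:, l] = forecasts.values[:, l] - np.swapaxes(clim_l, 0, 1)
    return replace(forecasts, values=anoms)


def ensemble_mean(per_member_series: Sequence[IndexSeries]) -> IndexSeries:
    """Unweighted mean of member index series, per time.

    Members missing a value at a time are dropped from that time's mean
    (NaN-aware); a time with no valid member stays NaN.
    """
    if len(per_member_series) == 0:
        raise ConfigurationError("ensemble mean of zero members")
    first = per_member_series[0]
    for s in per_member_series[1:]:
        if not first.times.equals(s.times):
            raise ConfigurationError("member series are not aligned in time")
    stacked = np.vstack([s.values for s in per_member_series])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return IndexSeries(times=first.times, values=mean, kind=first.kind, units=first.units)


@dataclass(frozen=True)
class EnsembleConfig:
    """One of the four retrospective forecast configurations.

    ``eval_years`` is the evaluation/climatology span; compression-index
    thresholds always use ``hci_threshold_years`` (1981-2010) while anomaly
    climatologies for the closure indicator use ``total_clim_years``
    (1981-2020 only for the full-period Global run).
    """

    name: str
    members: tuple[str, ...]
    eval_years: tuple[int, int]
    init_schedule: str  # "monthly" | "jan-jul"
    hci_threshold_years: tuple[int, int] = (1981, 2010)
    total_clim_years: tuple[int, int] | None = None

    def __post_init__(self):
        if self.init_schedule not in ("monthly", "jan-jul"):
            raise ConfigurationError("init_schedule must be 'monthly' or 'jan-jul'")
        if self.total_clim_years is None:
            object.__setattr__(self, "total_clim_years", self.eval_years)

    @property
    def init_months(self) -> tuple[int, ...]:
        return tuple(range(1, 13)) if self.init_schedule == "monthly" else (1, 7)

    @property
    def n_members(self) -> int:
        return len(self.members)


def build_configurations(
    global_set: ForecastSet,
    downscaled_set: ForecastSet,
    reduced_member_ids: Sequence[str] | None = None,
    full_years: tuple[int, int] = (1981, 2020),
    reduced_years: tuple[int, int] = (1981, 2010),
) -> dict[str, tuple[EnsembleConfig, ForecastSet]]:
    """Assemble the four labelled configurations from two forecast sets.

    * Global           — all global members, full period, monthly inits.
    * GlobalFull       — all global members, reduced period, Jan/Jul inits
                         (restricted so the downscaled comparison is fair).
    * GlobalReduced    — a stated 3-member subset of the global members
                         (emulating the three downscaled source members),
                         reduced period, Jan/Jul inits.
    * Downscaled       — the downscaled set (higher per-member skill,
                         Jan/Jul-only initializations), reduced period.

    ``reduced_member_ids`` must be a subset of the global member ids; the
    default takes as many leading global members as the downscaled set has.
    """
    if reduced_member_ids is None:
        reduced_member_ids = global_set.members[: len(downscaled_set.members)]
    if not set(reduced_member_ids) <= set(global_set.members):
        raise ConfigurationError(
            "reduced-ensemble members must be a subset of the global members"
        )
    if len(reduced_member_ids) != len(downscaled_set.members):
        raise ConfigurationError(
            "reduced ensemble must match the downscaled member count"
        )

    def _cfg(name, members, years, schedule, total_clim):
        return EnsembleConfig(
            name=name,
            members=tuple(members),
            eval_years=years,
            init_schedule=schedule,
            hci_threshold_years=reduced_years,  # thresholds use the reduced period everywhere
            total_clim_years=total_clim,
        )

    jan_jul = (1, 7)
    configs = {
        "Global": (
            _cfg("Global", global_set.members, full_years, "monthly", full_years),
            global_set.subset(init_years=full_years),
        ),
        "GlobalFull": (
            _cfg("GlobalFull", global_set.members, reduced_years, "jan-jul", reduced_years),
            global_set.subset(init_months=jan_jul, init_years=reduced_years),
        ),
        "GlobalReduced": (
            _cfg("GlobalReduced", reduced_member_ids, reduced_years, "jan-jul", reduced_years),
            global_set.subset(
                members=reduced_member_ids, init_months=jan_jul, init_years=reduced_years
            ),
        ),
        "Downscaled": (
            _cfg("Downscaled", downscaled_set.members, reduced_years, "jan-jul", reduced_years),
            downscaled_set.subset(init_months=jan_jul, init_years=reduced_years),
        ),
    }
    return configs
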
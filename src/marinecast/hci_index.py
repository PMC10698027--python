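"""Habitat Compression Index (HCI).

The HCI measures how much cool upwelling habitat remains off California
(35-40°N): the fraction of grid cells within 150 km of the coast whose SST is
*lower than* a monthly threshold, where the threshold for each calendar month
is the 1981-2010 mean SST of the nearshore band (coast to 75 km).  Values lie
in [0, 1]; low values mean cool habitat is compressed against the shore,
which concentrates whales nearshore and raises entanglement risk in fixed
gear.  A month is classified as a *high-compression event* when the HCI is
below or equal to the long-term mean (lead-specific for forecasts).

Two comparators appear deliberately: strictly-below for cell counting,
below-or-equal for event classification; the event comparator is exposed for
sensitivity analysis.

For forecast ensembles, thresholds and long-term means are specific to each
member and lead time (drift correction); the index is computed per member and
then members are averaged into the ensemble-mean forecast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._core import ConfigurationError, CoverageError, IndexSeries, periods_from_ordinals
from .domain_masks import RegionMask
from .forecast_engine import LeadForecast, lead_climatology
from .synthetic_ocean import ForecastSet, SstSeries

__all__ = [
    "MonthlyThresholds",
    "IndexSeries",
    "monthly_thresholds",
    "compute_hci",
    "hci_series",
    "classify_high_compression",
    "long_term_mean",
    "forecast_hci",
]

_COMPARATORS = {"le": np.less_equal, "lt": np.less}


@dataclass(frozen=True)
class MonthlyThresholds:
    """One SST threshold (°C) per calendar month, with its provenance."""

    values: np.ndarray  # shape (12,), index = month - 1
    provenance: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (12,) or not np.all(np.isfinite(values)):
            raise ConfigurationError("thresholds must be 12 finite values")
        object.__setattr__(self, "values", values)

    def for_month(self, month: int) -> float:
        return float(self.values[month - 1])


def monthly_thresholds(
    sst: SstSeries, band75: RegionMask, clim_years: tuple[int, int]
) -> MonthlyThresholds:
    """Monthly mean SST of the nearshore (<=75 km) band over the climatology years."""
    if band75.n_cells == 0:
        raise ConfigurationError("empty nearshore band")
    in_years = (sst.years >= clim_years[0]) & (sst.years <= clim_years[1])
    cells = sst.values[:, band75.included]  # (time, cell)
    out = np.full(12, np.nan)
    missing = []
    for m in range(1, 13):
        sel = in_years & (sst.months == m)
        if not sel.any():
            missing.append(m)
            continue
        out[m - 1] = np.nanmean(cells[sel])
    if missing:
        raise CoverageError(f"climatology years {clim_years} missing months {missing}")
    return MonthlyThresholds(
        values=out, provenance=f"observed {clim_years[0]}-{clim_years[1]}, {band75.descriptor}"
    )


def compute_hci(sst_field: np.ndarray, threshold: float, band150: RegionMask) -> float:
    """Fraction of 150 km-band cells colder than the month's threshold.

    NaN cells are excluded from both numerator and denominator; a band with
    no valid cells yields NaN (undefined, never silently zero).
    """
    cells = np.asarray(sst_field, dtype=float)[band150.included]
    valid = np.isfinite(cells)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return float("nan")
    return float(np.count_nonzero(cells[valid] < threshold) / n_valid)


def hci_series(
    sst: SstSeries, thresholds: MonthlyThresholds, band150: RegionMask
) -> IndexSeries:
    """The HCI for every month of an SST series."""
    cells = sst.values[:, band150.included]  # (time, cell)
    valid = np.isfinite(cells)
    thr = thresholds.values[sst.months - 1][:, None]
    below = valid & (cells < thr)
    n_valid = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_valid > 0, below.sum(axis=1) / n_valid, np.nan)
    return IndexSeries(times=sst.times, values=values, kind="hci", units="")


def long_term_mean(series: IndexSeries, years: tuple[int, int]) -> float:
    """Reference mean of the index over the stated years."""
    sub = series.select_years(years)
    if len(sub) == 0 or not np.isfinite(sub.values).any():
        raise ConfigurationError(f"no index values in reference years {years}")
    return float(np.nanmean(sub.values))


def classify_high_compression(
    hci: IndexSeries, reference_mean: float, comparator: str = "le"
) -> IndexSeries:
    """Flag high-compression events: HCI below (or equal to) the reference mean."""
    if not np.isfinite(reference_mean):
        raise ConfigurationError("reference mean is undefined")
    cmp = _COMPARATORS.get(comparator)
    if cmp is None:
        raise ConfigurationError(f"comparator must be one of {sorted(_COMPARATORS)}")
    flags = np.where(
        np.isfinite(hci.values), cmp(hci.values, reference_mean).astype(float), np.nan
    )
    rule = f"high compression: HCI {'<=' if comparator == 'le' else '<'} {reference_mean:.4f}"
    return hci.with_events(flags, rule)


def forecast_hci(
    forecasts: ForecastSet,
    band75: RegionMask,
    band150: RegionMask,
    threshold_years: tuple[int, int],
    reference_years: tuple[int, int] | None = None,
    comparator: str = "le",
) -> dict[float, LeadForecast]:
    """Ensemble HCI forecasts per lead, with high-compression classification.

    Thresholds are member- and lead-specific monthly means of the nearshore
    band over ``threshold_years`` (computed from the forecasts themselves, so
    model drift cancels); the HCI is computed per member over the 150 km band
    and members are averaged into the ensemble mean.  Events are classified
    against the lead-specific long-term mean of the ensemble-mean HCI over
    ``reference_years`` (default: the threshold years).
    """
    reference_years = reference_years or threshold_years
    lc = lead_climatology(forecasts, threshold_years)
    # member/lead/month thresholds: nearshore-band mean of the lead climatology
    # ((lead, month) pairs never targeted by the schedule stay NaN)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        thr = np.nanmean(lc.values[:, :, :, band75.included], axis=3)  # (member, lead, 12)

    t_month = forecasts.target_months  # (init, lead)
    t_index = forecasts.target_index()
    cells = forecasts.values[:, :, :, band150.included]  # (init, lead, member, cell)
    valid = np.isfinite(cells)
    # threshold per (init, lead, member)
    thr_il = np.transpose(thr, (1, 2, 0))[  # (lead, month, member)
        np.arange(forecasts.leads.size)[None, :], t_month - 1
    ]  # (init, lead, member)
    below = valid & (cells < thr_il[..., None])
    n_valid = valid.sum(axis=3).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        hci = np.where(n_valid > 0, below.sum(axis=3) / n_valid, np.nan)  # (init, lead, member)

    out: dict[float, LeadForecast] = {}
    for l, lead in enumerate(forecasts.leads):
        times = periods_from_ordinals(t_index[:, l])
        member_values = hci[:, l, :].T  # (member, time)
        with np.errstate(invalid="ignore"):
            ens_values = np.nanmean(member_values, axis=0)
        ens = IndexSeries(times=times, values=ens_values, kind="hci", units="")
        ref = long_term_mean(ens, reference_years)
        ens = classify_high_compression(ens, ref, comparator=comparator)
        out[float(lead)] = LeadForecast(
            lead=float(lead), times=times, member_values=member_values, ensemble=ens
        )
    return out
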
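"""TOTAL: the loggerhead-bycatch closure indicator.

The indicator monitors anomalously warm water in the Southern California
Bight (31-34°N, 120-116°W), where warm years bring loggerhead turtles into
the range of the drift gillnet fishery.  For each potential closure month
(June, July, August) the TOTAL value is the mean SST anomaly of the six
months strictly preceding it (June <- Dec-May, July <- Jan-Jun,
August <- Feb-Jul).  A closure is recommended when TOTAL meets or exceeds a
threshold defined as the minimum TOTAL value across seven historical closure
months (Aug 2014; Jun-Aug 2015; Jun-Aug 2016) — the ">=" comparator makes
the defining closures themselves trigger.  The absolute threshold is also
expressed as a percentile of the closure-eligible TOTAL distribution so it
can be transferred to forecasts: each forecast lead uses the lead-specific
quantile of its own ensemble-mean TOTAL distribution at that percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._core import ConfigurationError, IndexSeries, periods_from_ordinals, to_period
from .domain_masks import RegionMask
from .forecast_engine import LeadForecast, anomalize, lead_climatology
from .synthetic_ocean import ForecastSet, SstSeries

__all__ = [
    "ClosureThreshold",
    "DEFAULT_HISTORICAL_CLOSURES",
    "box_mean_ssta",
    "total_value",
    "total_series",
    "closure_threshold",
    "recommend_closure",
    "forecast_total",
    "apply_closure_percentile",
]

#: the seven historical closure months defining the observed threshold
DEFAULT_HISTORICAL_CLOSURES = (
    (2014, 8),
    (2015, 6),
    (2015, 7),
    (2015, 8),
    (2016, 6),
    (2016, 7),
    (2016, 8),
)

CLOSURE_MONTHS = (6, 7, 8)

_COMPARATORS = {"ge": np.greater_equal, "gt": np.greater}


def box_mean_ssta(
    sst: SstSeries, box_mask: RegionMask, clim_years: tuple[int, int]
) -> IndexSeries:
    """Monthly spatial-mean SST anomaly over the box (°C).

    Anomalies are taken against the box's monthly climatology over
    ``clim_years`` (1981-2020 for the full-period configuration, 1981-2010
    for the comparison configurations).
    """
    if box_mask.n_cells == 0:
        raise ConfigurationError("empty box")
    cells = sst.values[:, box_mask.included]  # (time, cell)
    series = np.nanmean(cells, axis=1)
    in_years = (sst.years >= clim_years[0]) & (sst.years <= clim_years[1])
    clim = np.full(12, np.nan)
    for m in range(1, 13):
        sel = in_years & (sst.months == m)
        if not sel.any():
            raise ConfigurationError(f"climatology years {clim_years} missing month {m}")
        clim[m - 1] = series[sel].mean()
    return IndexSeries(
        times=sst.times, values=series - clim[sst.months - 1], kind="ssta", units="degC"
    )


def total_value(ssta: IndexSeries, closure_month) -> float:
    """Mean anomaly of the six months strictly preceding the closure month.

    NaN (undefined) when the window is incomplete, never a partial mean.
    """
    closure = to_period(closure_month)
    if closure.month not in CLOSURE_MONTHS:
        raise ConfigurationError(f"closure month must be Jun/Jul/Aug, got {closure}")
    window = pd.period_range(end=closure - 1, periods=6, freq="M")
    loc = ssta.times.get_indexer(window)
    if np.any(loc < 0):
        return float("nan")
    vals = ssta.values[loc]
    if not np.all(np.isfinite(vals)):
        return float("nan")
    return float(vals.mean())


def total_series(
    ssta: IndexSeries, closure_months: Sequence[int] = CLOSURE_MONTHS
) -> IndexSeries:
    """TOTAL at every closure month of every year in the anomaly series."""
    years = np.unique(ssta.years)
    periods, values = [], []
    for y in years:
        for m in closure_months:
            p = pd.Period(year=int(y), month=int(m), freq="M")
            if p in ssta.times:
                periods.append(p)
                values.append(total_value(ssta, p))
    return IndexSeries(
        times=pd.PeriodIndex(periods, freq="M"),
        values=np.asarray(values, dtype=float),
        kind="total",
        units="degC",
    )


@dataclass(frozen=True)
class ClosureThreshold:
    """The closure threshold (°C anomaly) and its percentile equivalent."""

    value: float
    percentile: float
    historical_closures: tuple
    period: tuple[int, int]

    def __post_init__(self):
        if not (0.0 <= self.percentile <= 100.0):
            raise ConfigurationError("percentile must be in [0, 100]")


def closure_threshold(
    observed_total: IndexSeries,
    historical_closures: Sequence = DEFAULT_HISTORICAL_CLOSURES,
    period: tuple[int, int] | None = None,
) -> ClosureThreshold:
    """Threshold = minimum TOTAL value at the historical closure months.

    The percentile is the empirical-CDF proportion (values <= threshold, on
    0-100) within the closure-eligible TOTAL distribution over ``period``
    (default: the whole series).
    """
    closures = tuple(to_period(c) for c in historical_closures)
    vals = []
    for c in closures:
        try:
            v = observed_total.value_at(c)
        except KeyError:
            raise ConfigurationError(f"TOTAL undefined at historical closure {c}") from None
        if not np.isfinite(v):
            raise ConfigurationError(f"TOTAL undefined at historical closure {c}")
        vals.append(v)
    threshold = float(min(vals))
    period = period or (int(observed_total.years.min()), int(observed_total.years.max()))
    eligible = observed_total.select_years(period).values
    eligible = eligible[np.isfinite(eligible)]
    if eligible.size == 0:
        raise ConfigurationError(f"no TOTAL values in period {period}")
    pct = float(np.clip(stats.percentileofscore(eligible, threshold, kind="weak"), 0.0, 100.0))
    return ClosureThreshold(
        value=threshold, percentile=pct, historical_closures=closures, period=tuple(period)
    )


def recommend_closure(total, threshold: float, comparator: str = "ge"):
    """Closure recommended when TOTAL meets/exceeds the threshold (NaN-safe)."""
    cmp = _COMPARATORS.get(comparator)
    if cmp is None:
        raise ConfigurationError(f"comparator must be one of {sorted(_COMPARATORS)}")
    total = np.asarray(total, dtype=float)
    out = np.where(np.isfinite(total), cmp(total, threshold).astype(float), np.nan)
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# forecast TOTAL
# ---------------------------------------------------------------------------

def _member_box_ssta(
    forecasts: ForecastSet, box_mask: RegionMask, clim_years: tuple[int, int]
) -> np.ndarray:
    """(init, lead, member) box-mean SST anomalies after drift correction."""
    lc = lead_climatology(forecasts, clim_years)
    anoms = anomalize(forecasts, lc)
    return np.nanmean(anoms.values[:, :, :, box_mask.included], axis=3)


def forecast_total(
    forecasts: ForecastSet,
    box_mask: RegionMask,
    clim_years: tuple[int, int],
    closure_months: Sequence[int] = CLOSURE_MONTHS,
    combine_inits: bool = False,
) -> list[LeadForecast]:
    """Ensemble TOTAL forecasts per (closure month, lead).

    With a monthly initialization schedule (``combine_inits=False``) each
    closure month is forecast from single initializations at closure leads
    6.5-11.5 months, the TOTAL window being the six consecutive leads that
    precede the closure month within the same initialization.

    With ``combine_inits=True`` (the Jan/Jul downscaled schedule) each of the
    six window months is taken from the most recent initialization that
    covers it, and the monthly anomalies from the contributing
    initializations are averaged into a single forecast per closure month
    (June: Dec from the previous July run, Jan-May from the January run).
    The reported lead is measured from the most recent contributing
    initialization to the closure month.
    """
    ssta = _member_box_ssta(forecasts, box_mask, clim_years)  # (init, lead, member)
    n_m = len(forecasts.members)
    init_i8 = forecasts.inits.asi8
    lead_k = np.floor(forecasts.leads).astype(int)
    out: list[LeadForecast] = []

    if not combine_inits:
        for c in closure_months:
            for l_idx, lead in enumerate(forecasts.leads):
                if l_idx < 6:
                    continue  # window needs the six preceding leads
                closure_ord = init_i8 + lead_k[l_idx]
                months = periods_from_ordinals(closure_ord).month
                sel = np.nonzero(months == c)[0]
                if sel.size == 0:
                    continue
                window = ssta[sel][:, l_idx - 6 : l_idx]  # (sel, 6, member)
                totals = window.mean(axis=1)  # (sel, member)
                times = periods_from_ordinals(closure_ord[sel])
                member_values = totals.T
                with np.errstate(invalid="ignore"):
                    ens = np.nanmean(member_values, axis=0)
                out.append(
                    LeadForecast(
                        lead=float(lead),
                        times=times,
                        member_values=member_values,
                        ensemble=IndexSeries(times=times, values=ens, kind="total", units="degC"),
                        closure_month=int(c),
                    )
                )
        return out

    # combined Jan/Jul-style schedule: stitch window months across inits
    inits = forecasts.inits
    years = np.unique(inits.year)
    lead_by_k = {k: i for i, k in enumerate(lead_k)}
    for c in closure_months:
        times, member_rows, labels = [], [], []
        for y in years:
            closure = pd.Period(year=int(y), month=int(c), freq="M")
            window = pd.period_range(end=closure - 1, periods=6, freq="M")
            contrib = []
            ok = True
            for w in window:
                # most recent init at or before w whose lead range reaches w
                k_arr = w.ordinal - init_i8
                cand = np.nonzero((k_arr >= 0) & (k_arr <= lead_k[-1]))[0]
                got = False
                for i_idx in cand[np.argsort(k_arr[cand])]:  # nearest init first
                    k = int(k_arr[i_idx])
                    if k in lead_by_k:
                        contrib.append((int(i_idx), lead_by_k[k], inits[i_idx]))
                        got = True
                        break
                if not got:
                    ok = False
                    break
            if not ok:
                continue
            vals = np.mean([ssta[i, l] for i, l, _ in contrib], axis=0)  # (member,)
            latest_init = max(init for _, _, init in contrib)
            labels.append((closure - latest_init).n + 0.5)
            times.append(closure)
            member_rows.append(vals)
        if not times:
            continue
        lead_label = float(max(labels))
        times = pd.PeriodIndex(times, freq="M")
        member_values = np.asarray(member_rows).T  # (member, time)
        with np.errstate(invalid="ignore"):
            ens = np.nanmean(member_values, axis=0)
        out.append(
            LeadForecast(
                lead=lead_label,
                times=times,
                member_values=member_values,
                ensemble=IndexSeries(times=times, values=ens, kind="total", units="degC"),
                closure_month=int(c),
            )
        )
    return out


def apply_closure_percentile(
    lead_forecasts: Sequence[LeadForecast],
    percentile: float,
    comparator: str = "ge",
) -> list[LeadForecast]:
    """Classify closures against lead-specific quantile thresholds.

    For each (closure month, lead) series, the threshold is the
    ``percentile`` quantile (linear interpolation) of the ensemble-mean
    TOTAL values for that series, transferring the observed threshold's
    percentile to each forecast's own distribution.
    """
    if not (0.0 <= percentile <= 100.0):
        raise ConfigurationError("percentile must be in [0, 100]")
    out = []
    for lf in lead_forecasts:
        vals = lf.ensemble.values
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ConfigurationError(
                f"no finite ensemble TOTAL values for closure month {lf.closure_month}"
            )
        thr = float(np.quantile(finite, percentile / 100.0, method="linear"))
        flags = recommend_closure(vals, thr, comparator=comparator)
        ens = lf.ensemble.with_events(
            np.asarray(flags, dtype=float),
            rule=f"closure: TOTAL {'>=' if comparator == 'ge' else '>'} {thr:.4f} "
            f"({percentile:g}th pct, lead {lf.lead})",
        )
        out.append(replace(lf, ensemble=ens, threshold=thr))
    return out
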
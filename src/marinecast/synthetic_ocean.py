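"""Synthetic gridded SST worlds for testing seasonal-forecast index pipelines.

This module generates an "observed" reanalysis-analog SST series and
multi-member retrospective forecast ensembles with controllable skill, so the
habitat-compression and closure-indicator pipelines downstream can be
exercised end to end without downloading real forecast archives.

The observed field is a latitude-dependent mean plus a sinusoidal seasonal
cycle plus a domain-coherent AR(1) monthly anomaly (optionally with per-cell
white noise), with additive warm extremes injected over stated windows to
emulate multi-year marine heatwaves.  Forecast members mix the observed
anomaly with independent noise at a lead-dependent correlation rho(L), add a
linear-in-lead drift bias and a constant per-member bias, so the generating
skill profile is a recoverable parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._core import (
    ConfigurationError,
    CoverageError,
    haversine_km,
    month_range,
    periods_from_ordinals,
    to_period,
)

__all__ = [
    "GridSpec",
    "SstSeries",
    "HeatwaveSpec",
    "SeasonalClimate",
    "ForecastSkillProfile",
    "ForecastSet",
    "make_grid",
    "simulate_observed_sst",
    "simulate_forecasts",
]

#: degrees of latitude sampled per coastline segment when discretizing
_COAST_SAMPLING_DEG = 0.05


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon mesh with a land mask and per-cell distance to coast.

    ``lats``/``lons`` are ascending cell-centre coordinates (°N / °E in the
    -180..180 convention).  ``coast_distance`` is km from the cell centre to
    the nearest coastline point; NaN on land cells.
    """

    lats: np.ndarray
    lons: np.ndarray
    land_mask: np.ndarray
    coast_distance: np.ndarray

    def __post_init__(self):
        lats = np.asarray(self.lats, dtype=float)
        lons = np.asarray(self.lons, dtype=float)
        land = np.asarray(self.land_mask, dtype=bool)
        dist = np.asarray(self.coast_distance, dtype=float)
        if lats.ndim != 1 or lons.ndim != 1:
            raise ConfigurationError("lats/lons must be 1-D")
        if np.any(np.diff(lats) <= 0) or np.any(np.diff(lons) <= 0):
            raise ConfigurationError("lats and lons must be strictly ascending")
        shape = (lats.size, lons.size)
        if land.shape != shape or dist.shape != shape:
            raise ConfigurationError("land_mask/coast_distance shape mismatch")
        ocean = ~land
        if not ocean.any():
            raise ConfigurationError("grid has no ocean cells")
        if not np.all(np.isfinite(dist[ocean])) or np.any(dist[ocean] < 0):
            raise ConfigurationError("ocean cells need finite nonnegative coast_distance")
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "land_mask", land)
        object.__setattr__(self, "coast_distance", dist)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lats.size, self.lons.size)

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    @property
    def n_ocean(self) -> int:
        return int(self.ocean_mask.sum())

    @property
    def lat_mesh(self) -> np.ndarray:
        return np.broadcast_to(self.lats[:, None], self.shape)

    @property
    def lon_mesh(self) -> np.ndarray:
        return np.broadcast_to(self.lons[None, :], self.shape)


def _coastline_points_from_meridian(
    coast_lon: Callable[[np.ndarray], np.ndarray],
    lat_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    lat_s = np.arange(lat_range[0], lat_range[1] + _COAST_SAMPLING_DEG / 2, _COAST_SAMPLING_DEG)
    return lat_s, np.asarray(coast_lon(lat_s), dtype=float)


def _coastline_points_from_mask(
    lats: np.ndarray, lons: np.ndarray, land: np.ndarray, res: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points along every ocean/land shared cell edge."""
    pts_lat, pts_lon = [], []
    half = res / 2.0
    n_sub = max(2, int(math.ceil(res / _COAST_SAMPLING_DEG)) + 1)
    frac = np.linspace(-half, half, n_sub)
    ni, nj = land.shape
    for i in range(ni):
        for j in range(nj):
            if not land[i, j]:
                continue
            # west/east edges (vertical, span latitude)
            for dj, edge_lon in ((-1, lons[j] - half), (1, lons[j] + half)):
                jj = j + dj
                if 0 <= jj < nj and not land[i, jj]:
                    pts_lat.append(lats[i] + frac)
                    pts_lon.append(np.full(n_sub, edge_lon))
            # south/north edges (horizontal, span longitude)
            for di, edge_lat in ((-1, lats[i] - half), (1, lats[i] + half)):
                ii = i + di
                if 0 <= ii < ni and not land[ii, j]:
                    pts_lat.append(np.full(n_sub, edge_lat))
                    pts_lon.append(lons[j] + frac)
    if not pts_lat:
        raise ConfigurationError("land mask has no ocean/land boundary to define a coastline")
    return np.concatenate(pts_lat), np.concatenate(pts_lon)


def _min_distance_to_points(
    grid_lats: np.ndarray, grid_lons: np.ndarray, pts_lat: np.ndarray, pts_lon: np.ndarray
) -> np.ndarray:
    """Minimum haversine distance from each (lat, lon) pair to the point set."""
    out = np.empty(grid_lats.size, dtype=float)
    # chunk to bound the (cells x points) broadcast
    chunk = max(1, int(2e6 / max(1, pts_lat.size)))
    for start in range(0, grid_lats.size, chunk):
        sl = slice(start, start + chunk)
        d = haversine_km(
            grid_lats[sl][:, None], grid_lons[sl][:, None], pts_lat[None, :], pts_lon[None, :]
        )
        out[sl] = d.min(axis=1)
    return out


def make_grid(
    lat_range: tuple[float, float] = (30.0, 48.0),
    lon_range: tuple[float, float] = (-134.0, -115.5),
    resolution_deg: float = 0.5,
    coastline_rule=None,
) -> GridSpec:
    """Build a rectangular grid with a synthetic coastline.

    The default domain is the U.S. West Coast study box (30–48°N,
    134–115.5°W).  ``coastline_rule`` controls the coastline:

    * ``None`` (default) — the coastline is the meridian at the eastern edge
      of the domain; every cell is ocean.
    * a float or callable ``lat -> lon`` — a meridian-following coastline;
      cells whose centre lies east of it are land.
    * a boolean array of shape (nlat, nlon) — an explicit land mask (e.g.
      read from a real land-mask netCDF); the coastline is the set of
      ocean/land cell edges.

    Distances are haversine on a spherical Earth (R = 6371 km), computed as
    the minimum over densely sampled coastline points.
    """
    res = float(resolution_deg)
    if res <= 0:
        raise ConfigurationError("resolution must be positive")
    span_lat = lat_range[1] - lat_range[0]
    span_lon = lon_range[1] - lon_range[0]
    n_lat = int(math.floor(span_lat / res + 1e-9))
    n_lon = int(math.floor(span_lon / res + 1e-9))
    if n_lat < 2 or n_lon < 2:
        raise ConfigurationError("resolution must divide the domain into >= 2 cells per axis")
    lats = lat_range[0] + res * (np.arange(n_lat) + 0.5)
    lons = lon_range[0] + res * (np.arange(n_lon) + 0.5)
    east_edge = lon_range[0] + res * n_lon

    if coastline_rule is None:
        land = np.zeros((n_lat, n_lon), dtype=bool)
        pts_lat, pts_lon = _coastline_points_from_meridian(
            lambda la: np.full_like(la, east_edge), lat_range
        )
    elif isinstance(coastline_rule, np.ndarray):
        land = np.asarray(coastline_rule, dtype=bool)
        if land.shape != (n_lat, n_lon):
            raise ConfigurationError("land mask shape does not match grid")
        pts_lat, pts_lon = _coastline_points_from_mask(lats, lons, land, res)
    else:
        if callable(coastline_rule):
            coast_fn = coastline_rule
        else:
            coast_lon = float(coastline_rule)
            coast_fn = lambda la: np.full_like(np.asarray(la, dtype=float), coast_lon)
        coast_at = np.asarray(coast_fn(lats), dtype=float)
        land = lons[None, :] > coast_at[:, None]
        pts_lat, pts_lon = _coastline_points_from_meridian(coast_fn, lat_range)

    ocean = ~land
    if not ocean.any():
        raise ConfigurationError("coastline rule leaves no ocean cells")

    dist = np.full((n_lat, n_lon), np.nan)
    lat_mesh = np.broadcast_to(lats[:, None], (n_lat, n_lon))
    lon_mesh = np.broadcast_to(lons[None, :], (n_lat, n_lon))
    dist[ocean] = _min_distance_to_points(
        lat_mesh[ocean], lon_mesh[ocean], pts_lat, pts_lon
    )
    return GridSpec(lats=lats, lons=lons, land_mask=land, coast_distance=dist)


# ---------------------------------------------------------------------------
# observed SST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonalClimate:
    """Deterministic part of the synthetic climate.

    Mean SST decreases poleward at ``lat_gradient`` °C per degree from
    ``mean_at_ref`` °C at ``ref_lat``; the seasonal cycle is a cosine of
    amplitude ``amplitude`` °C peaking in ``peak_month``.  Defaults are
    ballpark California Current values (coastal means in the low teens,
    ~3 °C seasonal range, warmest in August).
    """

    mean_at_ref: float = 14.0
    ref_lat: float = 40.0
    lat_gradient: float = -0.35
    amplitude: float = 3.0
    peak_month: int = 8

    def mean_field(self, lats: np.ndarray) -> np.ndarray:
        return self.mean_at_ref + self.lat_gradient * (np.asarray(lats) - self.ref_lat)

    def seasonal_term(self, months: np.ndarray) -> np.ndarray:
        return self.amplitude * np.cos(
            2.0 * np.pi * (np.asarray(months) - self.peak_month) / 12.0
        )


@dataclass(frozen=True)
class HeatwaveSpec:
    """A multi-year warm extreme: +amplitude °C over [start, end] months.

    ``mask`` restricts the extreme spatially (boolean per cell); ``None``
    applies it domain-wide, the analog of the 2014–2016 Northeast Pacific
    marine heatwave used throughout.
    """

    start: object
    end: object
    amplitude: float
    mask: np.ndarray | None = None

    def __post_init__(self):
        start = to_period(self.start)
        end = to_period(self.end)
        if end < start:
            raise ConfigurationError(f"heatwave end {end} precedes start {start}")
        if not (float(self.amplitude) > 0):
            raise ConfigurationError("heatwave amplitude must be positive")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "amplitude", float(self.amplitude))

    def in_window(self, times: pd.PeriodIndex) -> np.ndarray:
        return (times >= self.start) & (times <= self.end)


@dataclass(frozen=True)
class SstSeries:
    """Monthly gridded SST (°C): the observed truth or one member trajectory."""

    grid: GridSpec
    times: pd.PeriodIndex
    values: np.ndarray  # (time, lat, lon), NaN on land

    def __post_init__(self):
        times = pd.PeriodIndex(self.times, freq="M")
        if len(times) and not (np.diff(times.asi8) == 1).all():
            raise ConfigurationError("times must be consecutive calendar months")
        values = np.asarray(self.values)
        if values.shape != (len(times),) + self.grid.shape:
            raise ConfigurationError(
                f"values shape {values.shape} != (time, lat, lon) "
                f"{(len(times),) + self.grid.shape}"
            )
        ocean = self.grid.ocean_mask
        if not np.all(np.isfinite(values[:, ocean])):
            raise ConfigurationError("SST must be finite on ocean cells")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def years(self) -> np.ndarray:
        return self.times.year.to_numpy()

    @property
    def months(self) -> np.ndarray:
        return self.times.month.to_numpy()

    def monthly_climatology(self, clim_years: tuple[int, int]) -> np.ndarray:
        """Mean field per calendar month over ``clim_years`` -> (12, lat, lon)."""
        y0, y1 = clim_years
        in_years = (self.years >= y0) & (self.years <= y1)
        out = np.full((12,) + self.grid.shape, np.nan)
        missing = []
        for m in range(1, 13):
            sel = in_years & (self.months == m)
            if not sel.any():
                missing.append(m)
                continue
            out[m - 1] = self.values[sel].mean(axis=0)
        if missing:
            raise CoverageError(
                f"climatology years {clim_years} missing calendar months {missing}"
            )
        return out

    def anomalies(self, clim_years: tuple[int, int]) -> np.ndarray:
        """values minus the monthly climatology -> (time, lat, lon)."""
        clim = self.monthly_climatology(clim_years)
        return self.values - clim[self.months - 1]

    def select_years(self, year_range: tuple[int, int]) -> "SstSeries":
        keep = (self.years >= year_range[0]) & (self.years <= year_range[1])
        return SstSeries(grid=self.grid, times=self.times[keep], values=self.values[keep])


def simulate_observed_sst(
    grid: GridSpec,
    year_range: tuple[int, int] = (1981, 2020),
    seasonal: SeasonalClimate | None = None,
    ar1_coeff: float = 0.6,
    noise_sd: float = 0.6,
    cell_noise_sd: float = 0.1,
    heatwaves: Sequence[HeatwaveSpec] = (),
    seed: int | None = None,
) -> SstSeries:
    """Simulate the observed (reanalysis-analog) monthly SST series.

    The anomaly is a single domain-scale AR(1) process with lag-1
    autocorrelation ``ar1_coeff`` and stationary standard deviation
    ``noise_sd`` (°C), shared by every ocean cell so anomalies are spatially
    coherent, plus independent per-cell white noise of sd ``cell_noise_sd``.
    Heatwaves add their amplitude inside their window (and mask).
    Bit-reproducible under a fixed seed.
    """
    if not (0.0 <= ar1_coeff < 1.0):
        raise ConfigurationError("ar1_coeff must be in [0, 1)")
    if noise_sd < 0 or cell_noise_sd < 0:
        raise ConfigurationError("noise standard deviations must be nonnegative")
    seasonal = seasonal or SeasonalClimate()
    times = month_range(year_range)
    for hw in heatwaves:
        if hw.start < times[0] or hw.end > times[-1]:
            raise ConfigurationError(
                f"heatwave window {hw.start}..{hw.end} outside simulated years {year_range}"
            )
    rng = np.random.default_rng(seed)
    n_t = len(times)
    shape = grid.shape

    base = seasonal.mean_field(grid.lats)[:, None] + np.zeros(shape)  # (lat, lon)
    seas = seasonal.seasonal_term(times.month.to_numpy())  # (time,)

    # domain-scale AR(1) anomaly, stationary sd = noise_sd
    a = np.zeros(n_t)
    if noise_sd > 0:
        eps = rng.standard_normal(n_t)
        a[0] = noise_sd * eps[0]
        innov_sd = noise_sd * math.sqrt(1.0 - ar1_coeff**2)
        for t in range(1, n_t):
            a[t] = ar1_coeff * a[t - 1] + innov_sd * eps[t]

    values = base[None, :, :] + seas[:, None, None] + a[:, None, None]
    if cell_noise_sd > 0:
        values = values + cell_noise_sd * rng.standard_normal((n_t,) + shape)
    for hw in heatwaves:
        window = hw.in_window(times)
        bump = hw.amplitude if hw.mask is None else hw.amplitude * hw.mask
        values[window] = values[window] + bump
    values = np.where(grid.ocean_mask[None, :, :], values, np.nan)
    return SstSeries(grid=grid, times=times, values=values)


# ---------------------------------------------------------------------------
# forecasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecastSkillProfile:
    """Controls of synthetic forecast quality.

    ``rho0`` is the target anomaly correlation at lead 0.5 months; the
    correlation at lead L is ``rho0 * decay**L`` (multiplicative, default) or
    ``max(rho0 - decay * L, 0)`` (linear).  ``drift_bias`` is a systematic
    warm bias in °C per lead month (removed downstream by lead-specific
    climatologies); ``member_bias_sd`` is the sd of a constant per-member
    offset emulating inter-member climatology differences.
    ``member_noise_sd`` is the sd of the member-specific domain-coherent
    noise; ``None`` matches it to the observed domain-mean anomaly sd so the
    realized anomaly correlation equals rho(L).
    """

    rho0: float = 0.9
    decay: float = 0.95
    decay_kind: str = "multiplicative"
    drift_bias: float = 0.1
    member_noise_sd: float | None = None
    member_bias_sd: float = 0.2

    def __post_init__(self):
        if not (0.0 < self.rho0 <= 1.0):
            raise ConfigurationError("rho0 must be in (0, 1]")
        if self.decay_kind not in ("multiplicative", "linear"):
            raise ConfigurationError("decay_kind must be 'multiplicative' or 'linear'")
        if self.decay_kind == "multiplicative" and not (0.0 < self.decay <= 1.0):
            raise ConfigurationError("multiplicative decay must be in (0, 1]")
        if self.decay_kind == "linear" and self.decay < 0:
            raise ConfigurationError("linear decay must be nonnegative")

    def rho(self, leads) -> np.ndarray:
        leads = np.asarray(leads, dtype=float)
        if self.decay_kind == "multiplicative":
            r = self.rho0 * self.decay**leads
        else:
            r = np.maximum(self.rho0 - self.decay * leads, 0.0)
        return np.clip(r, 0.0, 1.0)


@dataclass(frozen=True)
class ForecastSet:
    """SST forecasts indexed by (initialization, lead, member).

    Leads are mid-month: lead k + 0.5 targets the k-th calendar month after
    the initialization month (lead 0.5 = the initialization month itself).
    ``values`` has shape (init, lead, member, lat, lon), NaN on land or where
    a member/model does not reach that lead.
    """

    grid: GridSpec
    inits: pd.PeriodIndex
    leads: np.ndarray
    members: tuple[str, ...]
    models: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        inits = pd.PeriodIndex(self.inits, freq="M")
        leads = np.asarray(self.leads, dtype=float)
        if leads.ndim != 1 or np.any(np.diff(leads) <= 0):
            raise ConfigurationError("leads must be 1-D ascending")
        if not np.allclose(leads % 1.0, 0.5):
            raise ConfigurationError("leads must be half-months (0.5, 1.5, ...)")
        members = tuple(self.members)
        models = tuple(self.models)
        if len(models) != len(members):
            raise ConfigurationError("models must label every member")
        expected = (len(inits), leads.size, len(members)) + self.grid.shape
        values = np.asarray(self.values)
        if values.shape != expected:
            raise ConfigurationError(f"values shape {values.shape} != {expected}")
        object.__setattr__(self, "inits", inits)
        object.__setattr__(self, "leads", leads)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "models", models)
        object.__setattr__(self, "values", values)

    @staticmethod
    def target_of(init: pd.Period, lead: float) -> pd.Period:
        return init + int(math.floor(lead))

    @property
    def target_months(self) -> np.ndarray:
        """(init, lead) -> calendar month of the target."""
        k = np.floor(self.leads).astype(int)
        return ((self.inits.month.to_numpy()[:, None] - 1 + k[None, :]) % 12) + 1

    @property
    def target_years(self) -> np.ndarray:
        k = np.floor(self.leads).astype(int)
        tot = self.inits.year.to_numpy()[:, None] * 12 + (self.inits.month.to_numpy()[:, None] - 1) + k[None, :]
        return tot // 12

    def target_index(self) -> np.ndarray:
        """(init, lead) -> months-since-epoch ordinal of the target month."""
        k = np.floor(self.leads).astype(int)
        return self.inits.asi8[:, None] + k[None, :]

    def lead_loc(self, lead: float) -> int:
        loc = np.nonzero(np.isclose(self.leads, lead))[0]
        if loc.size == 0:
            raise KeyError(f"lead {lead} not in forecast set")
        return int(loc[0])

    def subset(
        self,
        members: Sequence[str] | None = None,
        init_months: Sequence[int] | None = None,
        init_years: tuple[int, int] | None = None,
        max_lead: float | None = None,
    ) -> "ForecastSet":
        keep_i = np.ones(len(self.inits), dtype=bool)
        if init_months is not None:
            keep_i &= np.isin(self.inits.month.to_numpy(), list(init_months))
        if init_years is not None:
            yrs = self.inits.year.to_numpy()
            keep_i &= (yrs >= init_years[0]) & (yrs <= init_years[1])
        keep_l = np.ones(self.leads.size, dtype=bool)
        if max_lead is not None:
            keep_l = self.leads <= max_lead + 1e-9
        if members is None:
            keep_m = np.ones(len(self.members), dtype=bool)
        else:
            missing = set(members) - set(self.members)
            if missing:
                raise ConfigurationError(f"unknown members requested: {sorted(missing)}")
            keep_m = np.isin(np.array(self.members), list(members))
        return ForecastSet(
            grid=self.grid,
            inits=self.inits[keep_i],
            leads=self.leads[keep_l],
            members=tuple(np.array(self.members)[keep_m]),
            models=tuple(np.array(self.models)[keep_m]),
            values=self.values[np.ix_(np.nonzero(keep_i)[0], np.nonzero(keep_l)[0], np.nonzero(keep_m)[0])],
        )

    def mask_model_horizon(self, horizons: dict[str, float]) -> "ForecastSet":
        """NaN-out leads beyond a model's forecast horizon (months)."""
        values = self.values.copy()
        models = np.array(self.models)
        for model, horizon in horizons.items():
            m_idx = np.nonzero(models == model)[0]
            for li in np.nonzero(self.leads > horizon + 1e-9)[0]:
                values[:, li, m_idx] = np.nan
        return replace(self, values=values)


def simulate_forecasts(
    observed: SstSeries,
    skill_profile: ForecastSkillProfile,
    n_members: int,
    init_months: Sequence[int] = tuple(range(1, 13)),
    max_lead: float = 11.5,
    seed: int | None = None,
    clim_years: tuple[int, int] | None = None,
    init_years: tuple[int, int] | None = None,
    member_prefix: str = "m",
    model: str = "synthetic",
) -> ForecastSet:
    """Simulate a retrospective forecast ensemble against ``observed``.

    Each member's anomaly at lead L is
    ``rho(L) * observed_anomaly + sqrt(1 - rho(L)^2) * noise`` with noise
    shared across the domain but independent across (init, lead, member),
    plus ``drift_bias * L`` and a constant per-member offset, re-centred on
    the observed monthly climatology.  Members are exchangeable.

    Initializations are the first of every ``init_months`` month within
    ``init_years`` (default: the observed span); initializations whose
    longest-lead target falls outside the observed record are dropped, and if
    none survive the requested ``max_lead`` exceeds observed coverage.
    """
    if n_members < 1:
        raise ConfigurationError("need at least one ensemble member")
    leads = np.arange(0.5, max_lead + 0.5, 1.0)
    if leads.size == 0:
        raise ConfigurationError("max_lead must be >= 0.5")
    clim_years = clim_years or (int(observed.years.min()), int(observed.years.max()))
    clim = observed.monthly_climatology(clim_years)  # (12, lat, lon)
    anom = observed.values - clim[observed.months - 1]  # (time, lat, lon)

    yr0, yr1 = init_years or (int(observed.years.min()), int(observed.years.max()))
    candidates = [
        pd.Period(year=y, month=m, freq="M")
        for y in range(yr0, yr1 + 1)
        for m in sorted(set(init_months))
    ]
    max_k = int(math.floor(leads[-1]))
    first, last = observed.times[0], observed.times[-1]
    inits = pd.PeriodIndex(
        [p for p in candidates if p >= first and (p + max_k) <= last], freq="M"
    )
    if len(inits) == 0:
        raise ConfigurationError(
            f"max_lead {max_lead} exceeds observed coverage for the requested initializations"
        )

    rng = np.random.default_rng(seed)
    rho = skill_profile.rho(leads)
    ocean = observed.grid.ocean_mask
    # domain-mean observed anomaly sd sets the member-noise scale by default
    domain_anom = np.nanmean(anom[:, ocean], axis=1)
    noise_sd = (
        skill_profile.member_noise_sd
        if skill_profile.member_noise_sd is not None
        else float(np.std(domain_anom))
    )
    member_bias = (
        skill_profile.member_bias_sd * rng.standard_normal(n_members)
        if skill_profile.member_bias_sd > 0
        else np.zeros(n_members)
    )
    eps = rng.standard_normal((len(inits), leads.size, n_members))

    time_loc = observed.times.get_indexer(
        periods_from_ordinals(
            np.repeat(inits.asi8, leads.size)
            + np.tile(np.floor(leads).astype(int), len(inits))
        )
    ).reshape(len(inits), leads.size)
    target_month = ((inits.month.to_numpy()[:, None] - 1 + np.floor(leads).astype(int)[None, :]) % 12) + 1

    values = np.empty((len(inits), leads.size, n_members) + observed.grid.shape, dtype=np.float32)
    for l in range(leads.size):
        obs_a = anom[time_loc[:, l]]  # (init, lat, lon)
        clim_l = clim[target_month[:, l] - 1]  # (init, lat, lon)
        noise = math.sqrt(max(0.0, 1.0 - rho[l] ** 2)) * noise_sd * eps[:, l, :]  # (init, member)
        member_anom = (
            rho[l] * obs_a[:, None, :, :]
            + noise[:, :, None, None]
            + skill_profile.drift_bias * leads[l]
            + member_bias[None, :, None, None]
        )
        values[:, l] = (clim_l[:, None, :, :] + member_anom).astype(np.float32)
    values[:, :, :, observed.grid.land_mask] = np.nan

    members = tuple(f"{member_prefix}{i + 1:02d}" for i in range(n_members))
    models = tuple(model for _ in members)
    return ForecastSet(
        grid=observed.grid, inits=inits, leads=leads, members=members, models=models, values=values
    )
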
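"""Synthetic-ocean generator: grid geometry, observed SST statistics, and
recoverability of the forecast skill profile."""

import math

import numpy as np
import pandas as pd
import pytest

from marinecast import (
    ConfigurationError,
    ForecastSkillProfile,
    HeatwaveSpec,
    SeasonalClimate,
    make_grid,
    simulate_forecasts,
    simulate_observed_sst,
)
from marinecast._core import EARTH_RADIUS_KM


def _haversine(lat1, lon1, lat2, lon2):
    """Reference great-circle distance, written independently for oracle use."""
    p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
    a = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


class TestMakeGrid:
    def test_default_domain_bounding_box(self):
        grid = make_grid(resolution_deg=0.5)
        assert grid.lats[0] == pytest.approx(30.25)
        assert grid.lats[-1] == pytest.approx(47.75)
        assert grid.lons[0] == pytest.approx(-133.75)
        assert grid.lons[-1] == pytest.approx(-115.75)
        # all-ocean default; distances increase westward at fixed latitude
        assert grid.n_ocean == grid.land_mask.size
        row = grid.coast_distance[10]
        assert np.all(np.diff(row) < 0)

    def test_hci_band_feasible_on_default_grid(self):
        grid = make_grid(resolution_deg=0.5)
        in_band = (
            (grid.lats[:, None] >= 35)
            & (grid.lats[:, None] <= 40)
            & (grid.coast_distance <= 75)
        )
        assert in_band.any()

    def test_one_cell_strip_distance_is_half_cell_width(self):
        # one ocean column adjacent to a meridian coastline at -129°E
        grid = make_grid((35.0, 40.0), (-130.0, -125.0), 1.0, coastline_rule=-129.0)
        strip = grid.ocean_mask[:, 0]
        assert strip.all() and grid.land_mask[:, 1:].all()
        for i, lat in enumerate(grid.lats):
            expected = _haversine(lat, -129.5, lat, -129.0)
            assert grid.coast_distance[i, 0] == pytest.approx(expected, rel=0.01)

    def test_coast_distance_matches_brute_force_on_random_mask(self):
        rng = np.random.default_rng(7)
        res = 0.5
        land = rng.random((10, 10)) < 0.35
        land[0, 0] = False  # keep at least one ocean cell
        land[5, 5] = True  # and at least one land cell
        grid = make_grid((35.0, 40.0), (-130.0, -125.0), res, coastline_rule=land)
        # oracle: exhaustive minimum over densely sampled ocean/land edge points
        pts = []
        half = res / 2
        sub = np.linspace(-half, half, 11)
        for i in range(10):
            for j in range(10):
                if not land[i, j]:
                    continue
                for dj in (-1, 1):
                    if 0 <= j + dj < 10 and not land[i, j + dj]:
                        pts += [(grid.lats[i] + s, grid.lons[j] + dj * half) for s in sub]
                for di in (-1, 1):
                    if 0 <= i + di < 10 and not land[i + di, j]:
                        pts += [(grid.lats[i] + di * half, grid.lons[j] + s) for s in sub]
        for i in range(10):
            for j in range(10):
                if land[i, j]:
                    assert np.isnan(grid.coast_distance[i, j])
                    continue
                want = min(_haversine(grid.lats[i], grid.lons[j], pl, pn) for pl, pn in pts)
                assert grid.coast_distance[i, j] == pytest.approx(want, rel=0.02, abs=0.5)

    def test_empty_ocean_is_configuration_error(self):
        land = np.ones((4, 4), dtype=bool)
        with pytest.raises(ConfigurationError):
            make_grid((35.0, 37.0), (-130.0, -128.0), 0.5, coastline_rule=land)

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ConfigurationError):
            make_grid((35.0, 36.0), (-130.0, -128.0), 2.0)


class TestObservedSst:
    def test_zero_noise_is_pure_climatology(self, small_grid):
        obs = simulate_observed_sst(
            small_grid, (1990, 1995), noise_sd=0.0, cell_noise_sd=0.0, seed=0
        )
        first_year = obs.values[:12]
        for y in range(1, 6):
            np.testing.assert_allclose(obs.values[12 * y : 12 * (y + 1)], first_year)
        # seasonal cycle reproduces the configured monthly means exactly
        seasonal = SeasonalClimate()
        ocean = small_grid.ocean_mask
        for m in range(12):
            expected = (
                seasonal.mean_field(small_grid.lats)[:, None]
                + seasonal.seasonal_term(m + 1)
            )
            np.testing.assert_allclose(obs.values[m][ocean], np.broadcast_to(expected, small_grid.shape)[ocean])

    def test_heatwave_adds_its_amplitude(self, small_grid):
        hw = HeatwaveSpec("1993-01", "1994-12", 2.0)
        obs = simulate_observed_sst(
            small_grid, (1990, 1996), noise_sd=0.0, cell_noise_sd=0.0, heatwaves=[hw], seed=0
        )
        anoms = obs.anomalies((1990, 1996))
        inside = hw.in_window(obs.times)
        ocean = small_grid.ocean_mask
        diff = np.nanmean(anoms[inside][:, ocean]) - np.nanmean(anoms[~inside][:, ocean])
        assert diff == pytest.approx(2.0, abs=0.05)

    def test_ar1_coefficient_recovered(self, small_grid):
        obs = simulate_observed_sst(
            small_grid, (1981, 2020), ar1_coeff=0.6, noise_sd=0.6, cell_noise_sd=0.0, seed=5
        )
        a = np.nanmean(obs.anomalies((1981, 2020))[:, small_grid.ocean_mask], axis=1)
        r1 = np.corrcoef(a[:-1], a[1:])[0, 1]
        assert r1 == pytest.approx(0.6, abs=0.08)

    def test_fixed_seed_is_bit_identical(self, small_grid):
        kw = dict(year_range=(1990, 1999), seed=42, heatwaves=[HeatwaveSpec("1995-01", "1995-12", 1.0)])
        a = simulate_observed_sst(small_grid, **kw)
        b = simulate_observed_sst(small_grid, **kw)
        np.testing.assert_array_equal(a.values, b.values)

    def test_heatwave_outside_years_rejected(self, small_grid):
        with pytest.raises(ConfigurationError):
            simulate_observed_sst(
                small_grid, (1990, 1995), heatwaves=[HeatwaveSpec("1999-01", "1999-12", 1.0)], seed=0
            )


class TestForecasts:
    def test_perfect_forecast_limit_equals_observed(self, small_grid):
        obs = simulate_observed_sst(small_grid, (1990, 1999), seed=3)
        profile = ForecastSkillProfile(rho0=1.0, decay=1.0, drift_bias=0.0, member_bias_sd=0.0)
        fc = simulate_forecasts(obs, profile, n_members=2, seed=4, max_lead=5.5)
        t_loc = obs.times.get_indexer(
            pd.PeriodIndex([fc.inits[i] + int(l) for i in range(len(fc.inits)) for l in fc.leads - 0.5], freq="M")
        ).reshape(len(fc.inits), fc.leads.size)
        truth = obs.values[t_loc]  # (init, lead, lat, lon)
        for m in range(2):
            np.testing.assert_allclose(
                fc.values[:, :, m][:, :, small_grid.ocean_mask],
                truth[:, :, small_grid.ocean_mask],
                rtol=1e-5,
            )

    def test_drift_bias_accumulates_with_lead(self, small_grid):
        obs = simulate_observed_sst(small_grid, (1990, 2005), seed=6)
        profile = ForecastSkillProfile(rho0=1.0, decay=1.0, drift_bias=0.1, member_bias_sd=0.0)
        fc = simulate_forecasts(obs, profile, n_members=1, seed=7)
        t_loc = obs.times.get_indexer(
            pd.PeriodIndex([fc.inits[i] + 11 for i in range(len(fc.inits))], freq="M")
        )
        err = fc.values[:, -1, 0][:, small_grid.ocean_mask] - obs.values[t_loc][:, small_grid.ocean_mask]
        assert np.nanmean(err) == pytest.approx(1.15, abs=0.02)

    def test_skill_profile_correlation_recovered_per_lead(self, small_grid):
        obs = simulate_observed_sst(small_grid, (1981, 2015), seed=8, cell_noise_sd=0.0)
        profile = ForecastSkillProfile(rho0=0.9, decay=0.95, drift_bias=0.0, member_bias_sd=0.0)
        fc = simulate_forecasts(obs, profile, n_members=1, seed=9, clim_years=(1981, 2015))
        ocean = small_grid.ocean_mask
        obs_anom = np.nanmean(obs.anomalies((1981, 2015))[:, ocean], axis=1)
        t_loc = obs.times.get_indexer(
            pd.PeriodIndex(
                [fc.inits[i] + int(l) for i in range(len(fc.inits)) for l in fc.leads - 0.5],
                freq="M",
            )
        ).reshape(len(fc.inits), fc.leads.size)
        clim = obs.monthly_climatology((1981, 2015))
        rho = profile.rho(fc.leads)
        from marinecast import effective_n

        for l in range(fc.leads.size):
            fc_anom = np.nanmean(
                (fc.values[:, l, 0] - clim[fc.target_months[:, l] - 1])[:, ocean], axis=1
            )
            truth = obs_anom[t_loc[:, l]]
            r = np.corrcoef(fc_anom, truth)[0, 1]
            # sampling band: 3 SE of a correlation at the effective sample size
            se = (1.0 - r**2) / np.sqrt(effective_n(fc_anom, truth))
            assert abs(r - rho[l]) < max(3 * se, 0.03), f"lead {fc.leads[l]}"

    def test_ensemble_mean_beats_single_member_error(self, small_forecasts, observed_world):
        ocean = observed_world.grid.ocean_mask
        t_loc = observed_world.times.get_indexer(
            pd.PeriodIndex([i + 3 for i in small_forecasts.inits], freq="M")
        )
        l = small_forecasts.lead_loc(3.5)
        truth = np.nanmean(observed_world.values[t_loc][:, ocean], axis=1)
        members = np.nanmean(small_forecasts.values[:, l][:, :, ocean], axis=2)  # (init, member)
        # drift/bias removed for a fair error comparison
        members = members - members.mean(axis=0, keepdims=True) + truth.mean()
        single_var = np.mean([(members[:, m] - truth).var() for m in range(members.shape[1])])
        ens_var = (members.mean(axis=1) - truth).var()
        assert ens_var < single_var

    def test_members_are_exchangeable_in_distribution(self, small_forecasts):
        ocean = small_forecasts.grid.ocean_mask
        per_member_sd = np.nanstd(
            small_forecasts.values[:, :, :, ocean], axis=(0, 1, 3)
        )
        assert np.ptp(per_member_sd) < 0.25 * per_member_sd.mean()

    def test_jan_jul_schedule(self, observed_world):
        fc = simulate_forecasts(
            observed_world, ForecastSkillProfile(), n_members=2, init_months=(1, 7), seed=11
        )
        assert set(fc.inits.month) == {1, 7}

    def test_lead_exceeding_coverage_rejected(self, small_grid):
        # July starts with an 11.5-month horizon overrun a single observed year
        obs = simulate_observed_sst(small_grid, (1990, 1990), seed=0)
        with pytest.raises(ConfigurationError):
            simulate_forecasts(
                obs, ForecastSkillProfile(), n_members=1, init_months=(7,), max_lead=11.5, seed=0
            )

    def test_fixed_seed_forecasts_bit_identical(self, observed_world):
        kw = dict(n_members=2, seed=77, max_lead=3.5)
        a = simulate_forecasts(observed_world, ForecastSkillProfile(), **kw)
        b = simulate_forecasts(observed_world, ForecastSkillProfile(), **kw)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ConfigurationError):
            ForecastSkillProfile(rho0=1.4)
        with pytest.raises(ConfigurationError):
            ForecastSkillProfile(decay=1.2)
        # linear decay clips to zero, keeping the implied correlation in [0, 1]
        p = ForecastSkillProfile(rho0=0.5, decay=0.1, decay_kind="linear")
        assert np.all(p.rho([0.5, 5.5, 11.5]) >= 0)
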
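# marinecast

Retrospective seasonal forecasting of two SST-based marine-management
indices for the California Current, with a complete forecast-verification
suite and a synthetic-ocean generator so the entire analysis runs without
downloading forecast archives.

Dynamic ocean management tools that today run on *observed* temperatures can
be re-configured to run on *forecast* temperatures, turning reactive
management into proactive management. `marinecast` implements that
transition for two operational tools:

* **HCI — Habitat Compression Index.** The fraction of grid cells within
  150 km of the coast (35–40°N) whose SST is below a monthly climatological
  threshold (the 1981–2010 monthly mean of the nearshore coast-to-75 km
  band). Low HCI means cool upwelling habitat is squeezed against the shore,
  concentrating foraging whales where fixed-gear fisheries operate and
  raising entanglement risk. A month is a *high-compression event* when
  HCI ≤ its long-term mean.
* **TOTAL — loggerhead closure indicator.** The mean SST anomaly over the
  six months preceding a potential closure month (June, July, August) in the
  Southern California Bight (31–34°N, 120–116°W). When TOTAL meets a
  threshold — the minimum TOTAL across seven historical closure months —
  a drift-gillnet fishery closure is recommended to avoid sea-turtle
  bycatch. For forecasts the threshold transfers as a lead-specific
  quantile at the observed threshold's percentile.

Both indices are driven by multi-member forecast ensembles with leads of
0.5–11.5 months. Forecast drift is removed with climatologies specific to
each ensemble member and lead; the index is computed per member and members
are averaged. Four configurations are compared: a 73-member global ensemble
over the full period, and three reduced-period configurations (73-member
global, 3-member global subset, 3-member higher-skill "downscaled" ensemble
initialized only in January and July).

Verification follows standard forecast practice:

* **Correlation** r between yearly observed and forecast index values per
  target month and lead, with significance from a Fisher-Z 95% CI using the
  effective sample size
  `N_eff = N / [1 + 2·Σ_{t≥1} (1 − t/N)·rF_t·rO_t]`
  (sample autocorrelations of both series; skill is significant when the
  lower CI bound exceeds 0).
* **Accuracy** (TP+TN)/total against the random baseline
  `FA_rand = f² + (1−f)²` for event frequency *f* (0.5 at f=0.5; bound 0.62
  at f=0.26; 0.71 at f=0.18).
* **SEDI**, the Symmetric Extremal Dependence Index, base-rate robust for
  rare events (0 = random, 1 = perfect; undefined when there are no false
  positives).
* **Bootstrap significance**: 1000 random forecasts resampled from the
  observed event labels; skill must exceed the 97.5th percentile of that
  null.

The synthetic generator produces observed SST (latitude gradient + seasonal
cycle + domain-coherent AR(1) anomalies + injected multi-year marine
heatwaves) and forecast members whose anomaly correlation with truth decays
with lead by a configurable profile — so forecast skill, drift, and ensemble
size are recoverable, controllable experimental variables.

## Worked example

```python
import numpy as np
from marinecast import (
    HeatwaveSpec, ForecastSkillProfile, make_grid, simulate_observed_sst,
    simulate_forecasts, coastal_band, box, monthly_thresholds, hci_series,
    classify_high_compression, long_term_mean, forecast_hci, box_mean_ssta,
    total_series, closure_threshold, skill_report,
)

grid = make_grid(lat_range=(30, 42), lon_range=(-126, -115.5), resolution_deg=1.0)
heatwave = HeatwaveSpec("2011-03", "2013-02", amplitude=2.0)
obs = simulate_observed_sst(grid, year_range=(1981, 2013), seed=7, heatwaves=[heatwave])

band75 = coastal_band(grid, 75, 35, 40)
band150 = coastal_band(grid, 150, 35, 40)
thresholds = monthly_thresholds(obs, band75, clim_years=(1981, 2010))
hci = hci_series(obs, thresholds, band150)
hci = classify_high_compression(hci, long_term_mean(hci, (1981, 2010)))
print(f"June SST threshold:          {thresholds.for_month(6):.2f} degC")
print(f"mean HCI 1981-2010:          {np.nanmean(hci.select_years((1981, 2010)).values):.3f}")
print(f"high-compression frequency:  {np.nanmean(hci.select_years((1981, 2010)).event_flags):.2f}")

fc = simulate_forecasts(obs, ForecastSkillProfile(rho0=0.9, decay=0.95, drift_bias=0.1),
                        n_members=10, seed=8, clim_years=(1981, 2010), init_years=(1981, 2012))
lead_fcs = forecast_hci(fc, band75, band150, threshold_years=(1981, 2010))
report = skill_report(hci, lead_fcs, config="Global", n_boot=1000, seed=7)
corr = report[(report.metric == "correlation") & (report.target_month == 3)]
for _, row in corr[corr.lead.isin([0.5, 6.5, 11.5])].iterrows():
    print(f"March HCI skill, lead {row.lead:>4}: r = {row.value:.2f} "
          f"(N_eff = {row.n_eff:.1f}, significant: {row.significant})")

bight = box(grid, 31, 34, -120, -116)
total = total_series(box_mean_ssta(obs, bight, clim_years=(1981, 2010)))
thr = closure_threshold(total, historical_closures=[(2011, 8), (2012, 6), (2012, 7), (2012, 8)])
print(f"closure threshold:           {thr.value:.2f} degC = {thr.percentile:.0f}th percentile")
```

Output:

```
June SST threshold:          16.31 degC
mean HCI 1981-2010:          0.492
high-compression frequency:  0.48
March HCI skill, lead  0.5: r = 0.97 (N_eff = 22.1, significant: True)
March HCI skill, lead  6.5: r = 0.87 (N_eff = 23.1, significant: True)
March HCI skill, lead 11.5: r = 0.82 (N_eff = 24.8, significant: True)
closure threshold:           1.96 degC = 97th percentile
```

Reading this: thresholds and the index behave climatologically (events
roughly half the time over the reference period, as the ≤-mean rule
implies); forecast skill for March compression decays from r = 0.97 at
half a month ahead to r = 0.82 a year ahead but stays significant after the
autocorrelation correction; and the synthetic 2011–2013 heatwave defines a
closure threshold of ~2 °C anomaly, the 97th percentile of closure-eligible
TOTAL values.

There is also a CLI for file-based runs — `marinecast simulate | hci |
total | skill | compare | run`, each taking `--config config.yml --seed N
--outdir DIR` — which writes CF-style netCDF fields, tidy CSV skill tables,
and heat-map/boxplot figures, plus a `manifest.json` with the config hash,
stage timings and record counts.

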
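# Methods

## The retrospective-forecast procedure

The package re-runs two operational SST-based management indices on
retrospective forecast ensembles and verifies them against observations.
The flow is: build a grid and coastal geometry → obtain (here: simulate)
observed monthly SST and a forecast set indexed by (initialization, lead,
member) → correct forecast drift with member- and lead-specific
climatologies → compute each index per member, average members into the
ensemble mean, classify events → verify per target month and lead.

### Lead and target conventions

Leads are mid-month values 0.5, 1.5, …, 11.5: lead k + 0.5 targets the k-th
calendar month after the initialization month, so a 1 January start covers
January (0.5) through December (11.5). The closure indicator's reported
lead is the number of months from the initialization to the closure month
plus 0.5; its 6-month window therefore occupies the six leads immediately
below it, giving closure leads 6.5–11.5 for a monthly schedule with an
11.5-month horizon. For the January/July-only ("downscaled") schedule each
of the six window months is taken from the most recent initialization that
covers it and the monthly anomalies are averaged into a single forecast per
closure month: June stitches December from the previous July run (lead 5.5)
with January–May from the January run (leads 0.5–4.5) and is labelled lead
5.5; July (6.5) and August (7.5) come entirely from the January run. When
the six window months come from different initializations there is no
uniquely correct lead label; we label with the distance from the most
recent contributing initialization, which is the label that limits data
availability.

### Drift correction

Forecast systems drift with lead, and different members can carry constant
biases. All forecast climatologies (the compression index's monthly SST
thresholds, its long-term event reference, and the anomaly baselines of the
closure indicator) are computed separately per member, per lead, and per
calendar month over the stated climatology years, from the forecasts
themselves. Subtracting a member's own lead climatology removes linear (or
any deterministic) drift and member offsets exactly; the operation is
idempotent. Indices are computed per member and averaged afterwards
(unweighted — no member or model weighting), because both indices are
nonlinear in SST (a cell count and a thresholded decision), so the index of
the mean field is not the mean of the member indices.

### Index definitions and comparators

* Compression index: fraction of 150 km-band cells (cell-centre membership,
  35–40°N) with SST *strictly below* the month's threshold; thresholds are
  the monthly means of the coast-to-75 km band over 1981–2010. Events use
  *below-or-equal* against the (lead-specific) long-term mean. The two
  comparators differ deliberately: counting uses "lower than", event
  classification uses "below or equal"; the event comparator is a config
  switch (`le`/`lt`) because narrative conventions vary.
* Closure indicator: box-mean SST anomaly (31–34°N, 120–116°W) averaged
  over the six months strictly preceding June/July/August. The observed
  threshold is the minimum TOTAL across the stated historical closure
  months and is applied with ≥ so the defining closures themselves trigger.
  The threshold's percentile within the closure-eligible TOTAL distribution
  (empirical proportion ≤ threshold, on 0–100) transfers it to forecasts:
  each (closure month, lead) series uses its own quantile (linear
  interpolation) at that percentile, which compensates residual
  lead-dependent variance damping in the ensemble mean.

Undefined values (incomplete windows, all-missing bands) propagate as NaN
and are reported as "NA" in CSV; they are never coerced to zero or to
"no event".

## Verification

Skill is assessed per (target calendar month × lead × configuration) on the
across-year series of observed vs ensemble-mean forecast index values.

* **Correlation.** Pearson r, with significance via a Fisher-Z 95% CI whose
  standard error is 1/√(N_eff − 3). The effective sample size uses the
  two-sided triangular-weighted autocorrelation sum
  N_eff = N / [1 + 2·Σ_{t=1}^{N−1} (1 − t/N)·rF_t·rO_t], with biased (1/N)
  sample autocorrelations. A one-sided variant of this sum (lags 0…N−1
  without doubling) sometimes appears in print but converges to
  N·(1 − ρ²) for paired AR(1)(ρ) series instead of the classic
  N·(1 − ρ²)/(1 + ρ²); the two-sided form is the one with the correct
  closed-form limit and is what we implement. Sampling noise can push the
  sum below 1 or below 0; N_eff is clamped to at most N, a non-positive sum
  is flagged degenerate, and N_eff ≤ 3 leaves the CI undefined (not
  significant).
* **Accuracy and its baseline.** (TP+TN)/total vs FA_rand = f² + (1−f)².
  Printed baselines are reported conservatively as the smallest 0.01-grid
  value strictly above the raw number (0.6152 → 0.62, 0.7048 → 0.71), so a
  quoted bar is never below the true random expectation; exact grid values
  (0.5) are kept.
* **SEDI.** Computed from hit rate H and false-alarm rate F; undefined
  (NaN) whenever H or F lies on {0, 1}, e.g. months with no false
  positives. Equitability (expected 0 for random forecasts) is verified by
  simulation at event frequencies 0.2–0.5.
* **Bootstrap significance.** Null forecasts are binary vectors resampled
  with replacement from the observed event labels (equivalent to Bernoulli
  at the observed frequency; a label-permutation null is available as a
  config switch), scored against the fixed observations, 1000 times. Skill
  is significant when it strictly exceeds the null's 97.5th percentile. If
  the metric is undefined in more than half the draws, significance is not
  assessed. With short series the discreteness of accuracy makes the strict
  test conservative (empirically ~1.5–2% false-positive rate instead of
  2.5% at n ≈ 100–400); calibration checks therefore use series long enough
  for atoms to be small.

## The synthetic ocean

The generator emulates the statistical structure the analysis relies on,
not ocean physics.

* **Observed SST** = latitude-dependent mean (default 14 °C at 40°N,
  −0.35 °C/degree poleward) + sinusoidal seasonal cycle (amplitude 3 °C,
  peak August) + a single domain-scale AR(1) monthly anomaly (lag-1
  autocorrelation 0.6, stationary sd 0.6 °C — ballpark California Current
  monthly SSTA persistence and spread) + optional per-cell white noise
  (0.1 °C) + additive heatwaves (+2 °C over a stated window, domain-wide by
  default, the 2014–2016 Northeast Pacific analog).
* **Forecast members.** Member anomaly at lead L =
  ρ(L)·(observed anomaly) + √(1−ρ(L)²)·η + drift·L + member offset, with η
  domain-coherent, independent across (init, lead, member), and scaled to
  the observed domain-mean anomaly sd so the realized anomaly correlation
  equals ρ(L). Defaults: ρ(L) = 0.9·0.95^L (multiplicative decay; a linear
  option clips at 0), drift 0.1 °C per lead month, member-offset sd 0.2 °C.
  Members are exchangeable; ensemble-mean noise shrinks as 1/√n.
* **Geometry.** The default coastline is the meridian at the eastern edge
  of the requested domain, with every cell ocean. A meridian placed inside
  the domain (cells east of it land) and explicit land masks are supported,
  but an interior meridian cannot be the default because the Southern
  California Bight box (31–34°N, 120–116°W) must be ocean — in reality the
  coast bends east south of Point Conception, which a single meridian
  cannot represent. Distances are haversine (R = 6371 km) minimized over
  densely sampled coastline points (0.05° spacing).

What the generator does **not** emulate: spatial structure of forecast
skill (skill is uniform over the domain), multi-model differences beyond
labels, seasonality of predictability (ρ depends on lead only), ENSO-like
teleconnections, realistic coastline shape, and observation error. Passing
tests therefore demonstrate that the *pipeline* — drift correction, index
construction, event classification, verification — behaves correctly and
that its statistics are calibrated; they do not certify skill levels of any
real forecast system.

## Experiment design

* **Ensemble size vs member skill.** Two synthetic forecast systems share
  each observed world: a "global" system (73 members, member correlation
  0.4·0.9^L) and a "downscaled" system (3 members, 0.95, no decay). The
  profiles were fixed from the analytic ensemble-mean correlation
  ρ_ens = ρ/√(ρ² + (1−ρ²)/n): with these values the 73-member mean beats
  its own 3-member subset at every lead by a wide margin, while the
  3-member high-skill system beats all 73 by ≥ 0.02 at every lead — so both
  orderings (more members win; better members win) are demonstrable in one
  design. Verification counts month × lead cells over replicate worlds.
* **Heatwave forewarning.** One world receives a 2-year +2 °C extreme
  (2011-03 to 2013-02) and defines closure thresholds from four in-extreme
  closure months (mirroring how the real threshold was set from historical
  closures); a control world shares the same seed without the extreme and
  is judged with the same percentile rule. Forecast member correlation is
  0.9·0.985^L (≥ 0.76 at the longest lead).

## Problem sizes and numerics

Tests and the acceptance script use a 1° grid over 30–42°N, 126–115.5°W
(12 × 10 cells; the 75 km and 150 km bands contain the two nearshore
columns), 31–40-year records, 3–73 members, and 10–20 replicate worlds for
Monte-Carlo orderings — sizes at which every statistic of interest is
measurable with comfortable margins while a full run stays in seconds to
minutes on one CPU. Forecast arrays are float32 (values are °C with ~1e-3
noise floors; verification is done on across-year series where float32
rounding is negligible). Quantiles use linear interpolation; percentile of
a score uses the weak (≤) definition; NaN pairs are dropped before any
metric; all random draws flow from a single seed through spawned
`SeedSequence` children, so every artifact is bit-reproducible from
config + seed.

## Known limitations

* The closure indicator's combined January/July bookkeeping averages window
  months across initializations; alternative conventions (e.g. labelling by
  the oldest contributing initialization) would shift lead labels by up to
  6 months but not the values.
* The long-term event reference for forecasts is a single scalar per lead
  (not per calendar month); with strong seasonal skill differences a
  monthly reference could classify differently.
* SEDI significance is frequently unassessable in small samples (undefined
  null draws); this is reported, not imputed.
* Synthetic worlds share one domain-scale anomaly process; real fields have
  richer spatial degrees of freedom, so real-data N_eff behavior can differ
  from the synthetic calibration.
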
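# Methods

This note documents the models, conventions, and numerical choices behind
`fleetsentinel`, and what the synthetic scenarios do and do not demonstrate
about real fisheries data.

## The study system being emulated

The package targets the analysis pattern of a temperate tuna troll fleet on
an eastern-boundary coast: ~hourly VMS pings per vessel, one landings
receipt per trip, a July–October fishing season, a multi-year record
(default 2010–2024) containing a multi-year marine heatwave (default
2014–2016) during which preferred habitat shifts poleward and inshore and
catch rates fall. The confidential inputs of such an analysis (vessel-level
pings and fish tickets) are replaced by a generator with known truth; the
gridded fields (SST, habitat suitability) are consumed as inputs in both
the real and synthetic settings, so the pipeline is agnostic about where
they come from.

## Linkage model

- **Receipt filter.** A ticket is retained iff albacore pounds / total
  pounds ≥ 0.9, inclusive at the boundary. Tickets with zero total weight
  have an undefined share and are excluded with a log message. A vessel
  participates if it has at least one qualifying receipt (the alternative —
  requiring all receipts to qualify — is a one-line change in `link`).
- **Trip cap.** The 75th percentile (nearest-rank) of per-vessel
  inter-receipt durations; the reference value for the real fleet is 16 d,
  which is also the fallback when no durations are computable.
- **Assignment window.** Ping t belongs to receipt R iff
  max(t_prev, t_R − cap) < t ≤ t_R. The half-open interval prevents a ping
  at exactly the previous receipt's timestamp from joining two trips. Two
  receipts of one vessel at the identical timestamp are processed in
  ticket-id order and the later ticket takes the boundary instant (logged).
- **Fishing filters.** Drop flagged pings, non-at-sea event types,
  time-forward > 121 min (strict: 121 min itself is kept), and speeds
  ≥ 3.74 kn (strict less-than is fishing; the equality case is undefined in
  the field convention and is exposed as a parameter). The rules intersect,
  so order is irrelevant and the filter is idempotent.
- **Allocation.** pounds_i = albacore_pounds · tf_i / Σ tf within each
  ticket. Conservation is exact up to floating rounding (tested at
  rtol 1e−9). Receipts whose pings all have tf = 0 cannot be allocated and
  are dropped with a warning.

## Indicator chain

All daily series run through the same fixed order — raw → anomaly →
smoothing → season restriction — because a 30-day right-aligned mean at
early-July days must see June data; restricting first would corrupt
season-edge values (a regression test enforces this).

- **Anomalies** are relative to a monthly climatology (mean over all days of
  that calendar month in the climatology period, default the full record).
  Monthly rather than daily baselines keep the climatology estimable from
  ~15 values per day of year.
- **Smoothing** is a 30-day right-aligned rolling mean; a value is emitted
  only when ≥ 15 of the 30 window days are present (configurable). The
  choice of half-window coverage trades bias at data gaps against series
  completeness.
- **Percentiles** use one definition everywhere: nearest-rank (inverse
  empirical CDF, numpy's `inverted_cdf`).
- **Effort kernel.** A weighted Gaussian KDE over ping positions
  (weights = time-forward) with a full anisotropic bandwidth matrix — the
  weighted data covariance scaled by Scott's factor — evaluated at grid-cell
  centres, normalized, ranked descending, and cut at 75% cumulative
  probability of use. The kernel is estimated once from all pings pooled
  (a static footprint); per-year masks are possible by calling the function
  on subsets. Ping sets larger than 20,000 are deterministically subsampled
  before the KDE; the 75%-mass property is insensitive to this.
- **SSTa** is the area mean over the kernel mask, then anomalized and
  smoothed. The climatology is computed after area-averaging; with a static
  mask and complete fields the order is immaterial.
- **Habitat indicators** mask suitability to the EEZ polygon, threshold each
  day at that day's 75th percentile of masked values (cells strictly above
  are "core"), and summarise core cells by suitability-weighted mean
  latitude and mean distance to shore. The per-day threshold tracks the
  shape of the distribution rather than its absolute level; a pooled
  threshold is available via `per_day=False`. A uniform field has an empty
  core under the strict rule and yields a missing day.
- **Distance to shore** is the great-circle distance to a coastline
  polyline densified to ≤ 1 km vertex spacing (vertex-nearest, so accurate
  to ~0.5 km). Latitudinal centroids are weighted means of latitude in
  degrees, unprojected.
- **Effort grid.** Time-forward hours summed on a 0.1° grid; cells with
  fewer than four distinct vessels are suppressed (confidentiality
  convention) and the suppressed share of effort-hours is reported.
- **Annual CPUE** is the July–October mean of daily CPUE per year, with
  anomalies relative to the across-year mean of those annual values.

## SEDI

Events are "value strictly above the pooled nearest-rank percentile
threshold" over all non-missing seasonal days, pooled across years — an
extreme is rare over the record, not within each year. For a 2×2 table with
hit ratio H and false-alarm rate F,

SEDI = [ln F − ln H − ln(1−F) + ln(1−H)] / [ln F + ln H + ln(1−F) + ln(1−H)].

The score is invariant to the log base (numerator and denominator scale
together); natural logs are used. Rates of exactly 0 or 1 sit on log
singularities; they are clamped to [ε, 1−ε] with ε = 1e−9 and the result is
flagged degenerate rather than dropped, so skill grids stay complete when
extremes are rare. Tables with an empty margin (no observed events, or no
non-events) have undefined rates and return NaN. The implementation is
verified against an independent formula evaluation by exhaustive
enumeration of tables with margins up to 20, including the sign property
(SEDI > 0 ⇔ H > F) and monotonicity in H.

Uncertainty: a percentile bootstrap that resamples whole years with
replacement. Smoothed anomalies are strongly autocorrelated within a
season, so day-level resampling would fake precision; with only ~15 seasons
the year-block interval is honest about how few independent climate events
the record contains. At least 3 years are required.

## Driver attribution

Response and predictors are z-scored over complete cases (sample sd), so
OLS coefficients are standardized effects β comparable across drivers.
Plain OLS p-values are reported by default, matching common practice for
this analysis; a Newey–West (HAC) option exists but is off by default.
Missing driver days are gap-filled by linear interpolation strictly inside
the observed range (no extrapolation at the ends). Rank-deficient designs
raise an error naming the most collinear pairs.

## The synthetic generator

Fixed domain: a 124–131°W × 38–49°N box with a straight meridional
coastline at 124°W and a rectangular EEZ extending to 130°W. Defaults (all
in `ScenarioConfig`):

| parameter | default | meaning |
|---|---|---|
| years | 2010–2024 | record length (15 y) |
| heatwave_years | 2014–2016 | seasons with warm anomaly and habitat shift |
| ssta_amplitude | 1.5 °C | season-mean warm anomaly in heatwave years |
| habitat_shift_lat | 1.5° | northward habitat-centre shift in heatwave years |
| habitat_shift_shore | 30 km | inshore habitat shift in heatwave years |
| effort_tracking | 0.8 | fraction of trips placed on habitat vs uniform |
| cpue_base | 7.8 lbs/min | baseline catch per fishing minute |
| cpue_heatwave_factor | 0.54 | heatwave multiplier (a ~46% drop) |
| ping_interval | 60 min | nominal transponder cadence |
| n_vessels, trips_per_season, mean_trip_days | 25, 6, 7 | fleet size and activity, chosen to give ~400k pings over 15 y — large enough for stable daily indicators while keeping a full pipeline run under a minute |

SST is a seasonal cycle plus a meridional gradient, AR(1) day-to-day noise,
and the heatwave anomaly applied at full amplitude through July–October with
linear shoulders over June and November (so the in-season mean equals the
configured amplitude exactly). Habitat suitability is a Gaussian blob per
species whose centre migrates seasonally, wanders with small AR(1) jitter,
and shifts north/inshore under the heatwave weight. Vessels run
port → transit (fast) → fishing (slow, clustered on a per-trip ground) →
return trips; grounds follow the habitat centre with probability
`effort_tracking`, otherwise they are uniform in the domain. Receipt pounds
are, by construction, exactly the catch rate times the trip's
filter-surviving fishing minutes, so the linkage chain can be validated to
machine precision. Quality pathologies — GIS flags, in-port pings,
multi-ping signal breaks (> 121 min), receipts failing the 90% rule — are
injected at configurable rates to exercise every filter.

Driver series are AR(1) processes (fuel ~3.5 USD/gal, alert area ~5000 km²,
price ~2.5 USD/lb) with missing days injected for interpolation testing.
Known driver effects exist in two forms: `gen_regression_case` composes a
response from standardized drivers with exact β (the quantitative recovery
contract), and `ScenarioConfig.driver_betas` shifts fishing-ground latitude
by scaled driver z-scores to exercise the end-to-end plumbing.

### What passing tests do and do not show

The generator's fleet is behaviourally simple: trips are independent, the
ground is a single point per trip, speeds are cleanly separated between
fishing and transit, and there is no port economics, weather avoidance, or
preferential-sampling feedback. Passing the sentinel-signal test therefore
shows the *pipeline* correctly recovers a planted signal of realistic size
and structure — it does not show that a real fleet carries such a signal,
which is exactly the empirical question the real-data analysis answers.
Note also that a fleet that tracks habitat makes the null scenario subtle:
even with no heatwave, the fleet follows day-to-day habitat jitter, so the
null SEDI point estimate need not be near zero — only statistically
indistinguishable from it, which is what the year-block bootstrap checks.

## Numerical conventions and degenerate inputs

- Timestamps are UTC; daily bins are UTC calendar days.
- Great-circle distances use a spherical Earth of radius 6371.0088 km.
- Weighted means over all-zero weights yield missing values, never NaN
  propagation or division errors.
- A degenerate ping cloud (zero variance) gets a tiny jitter floor before
  the KDE, with a warning.
- Determinism: a scenario is byte-identical across runs for a given seed;
  KDE subsampling and the bootstrap take explicit seeds.

## Known limitations

- The coastline is straight and meridional; distance-to-shore geometry on
  real coasts (bays, islands) is supported by the same code but untested
  against surveyed distances.
- The KDE bandwidth is Scott's-rule full covariance, a plug-in of a simpler
  kind than pilot-based selectors; footprint boundaries differ in detail
  from those, though the 75%-mass property holds for either.
- Regression p-values ignore serial correlation unless `robust=True`.
- Habitat suitability is consumed as given; no species distribution model
  is fitted here.
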
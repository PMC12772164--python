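# fleetsentinel

Commercial fishing fleets are, in effect, instrumented apex predators:
government-mandated Vessel Monitoring System (VMS) transponders report every
vessel's position roughly hourly, and shoreside landings receipts record what
each trip caught. Because profit depends on finding the target species,
where the fleet fishes — and how much it lands per minute of fishing —
carries near-real-time information about where the fish are. `fleetsentinel`
is a library for testing that idea quantitatively: can fleet-movement
indicators act as *ecosystem sentinels* of climate-driven shifts in species
such as albacore and bluefin tuna, and can they flag collapsing availability
before the paperwork does?

The confidential nature of vessel-level VMS and fish-ticket data means the
package ships a first-class synthetic-data module: it generates whole
scenario bundles (pings, receipts, gridded SST and habitat-suitability
fields, economic driver series, coastline/EEZ geometry) with known ground
truth, so the complete analysis chain is testable end-to-end.

## What it computes

1. **Linkage** — fish tickets that are ≥ 90% albacore by weight are joined to
   the vessel's pings backward in time (up to the previous receipt or a
   trip-length cap, nominally the 75th percentile of inter-receipt trip
   lengths, 16 d); flagged, in-port and signal-break pings
   (time-forward > 121 min) are dropped; pings slower than 3.74 knots are
   classified as fishing; and each receipt's albacore pounds are distributed
   over its fishing pings proportionally to each ping's time-forward.
2. **Indicators** — daily pounds-weighted fleet Y centroid, distance to
   shore, and CPUE (lbs/minute); SST anomaly averaged over the fleet's 75%
   kernel-density effort footprint; habitat-suitability centroids over core
   habitat (cells above the daily 75th-percentile threshold inside the EEZ).
   Every series follows one chain: monthly-climatology anomaly → 30-day
   right-aligned rolling mean → July–October season restriction.
3. **Skill** — extreme events are defined by percentile thresholds
   (70th–95th in 0.05 steps) on the pooled seasonal anomalies and scored
   with the Symmetric Extremal Dependence Index,

   SEDI = [ln F − ln H − ln(1−F) + ln(1−H)] / [ln F + ln H + ln(1−F) + ln(1−H)],

   with hit ratio H = TP/(TP+FN) and false-alarm rate F = FP/(FP+TN).
   SEDI ∈ [−1, 1]; 0 is random, 1 perfect, and it stays stable as events
   become rare. Uncertainty comes from a year-block bootstrap.
4. **Drivers** — OLS on z-scored variables attributes fleet-movement
   variability to ecological drivers (habitat shift, SSTa) versus economic
   ones (fuel price, weather-alert area, ex-vessel price), via standardized
   effect sizes β.

## Worked example

```bash
python examples/04_sedi_skill.py
```

simulates the default 15-year scenario (heatwave years 2014–2016 shift
albacore habitat 1.5° north; the fleet follows habitat with weight 0.8),
links pings to receipts, builds the fleet-centroid and habitat-centroid
anomaly series, and prints the SEDI grid:

```
 percentile  sedi  tp  fp  fn   tn
       0.70 0.775 402 150 149 1140
       0.75 0.880 371  89  88 1293
       0.80 0.977 346  22  23 1450
       0.85 0.880 213  63  63 1502
       0.90 0.869 135  49  49 1608
       0.95 0.695  44  48  48 1701

SEDI at the 90th percentile with a year-block bootstrap 95% CI: [0.73, 0.98]
```

Each row scores how well extreme northward fleet shifts (anomalies above
that percentile) predict extreme northward habitat shifts: at the 90th
percentile, 135 of 184 extreme habitat days were also extreme fleet days,
giving SEDI 0.87 — far better than random — while the no-heatwave null
scenario's bootstrap interval covers zero.

`examples/03_build_indicators.py` shows the availability side: the
heatwave-year CPUE in the default scenario drops 46% below the cross-year
July–October mean, visible the October the season ends. The other examples
cover scenario generation, linkage filters, and driver attribution.

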
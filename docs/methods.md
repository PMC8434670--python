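# Methods

This note records the models, estimators, numerical choices and known
limitations of `silogrowth`, in the order the pipeline applies them.

## Setting and conventions

A fattening batch starts at the earliest entry of animals and runs 17–20
weeks. All timestamps are naive UTC; farmer-entered dates mean midnight
UTC. Week indices are 0-based over half-open weeks `[7t, 7t+7)` from the
batch start, and "a quantity at week t" always means its value at the *end*
of week t (so week 0 covers seven full days). Entries and departures take
effect at the start of their day, which keeps per-animal intake
denominators conservative.

## Intake and growth curves

Per-animal accumulated feed intake (AFI, kg) is logistic in age `a`
(weeks): `afi(a) = A_f / (1 + exp(-b_f a))`, increasing to the adult
asymptote `A_f`. Because animals arrive with a feeding history, the
theoretical *on-farm* intake of a subgroup entering at age `a0` after `w`
weeks on farm is the increment `afi(a0 + w) − afi(a0)`; that is the curve
the sensor-based series is compared against. The sensor-based series
divides the batch's daily consumption by the head count present that day
and accumulates.

Average body weight is Gompertz in accumulated intake:
`aw = A · exp(−exp(b − k·afi))`, where `afi` here is the absolute
accumulated intake (entry-age logistic value plus on-farm accumulation).
Weight dispersion between animals grows with time; the variance (kg²) of a
subgroup is a cubic polynomial `c0 + c1 t + c2 t² + c3 t³` in weeks `t`
since that subgroup's entry, validated positive over weeks 0–25 at
configuration load. The week since entry is used as the polynomial's
argument because it is the monotone proxy available for every subgroup.

All five curve parameters and the variance coefficients are configuration
inputs with no library defaults: they are farm- and breed-specific fitted
constants. ADG (average daily gain, kg/day) and FCR (feed conversion
ratio, kg feed per kg gain) feed a secondary straight-line cross-check
`afi_lin(t) = ADG·FCR·7(t+1)`, reported alongside the logistic curve; the
end-of-week day count keeps it on the same convention as the other
columns.

A batch mixes one Normal component per entry subgroup, weighted by head
count. Departures do not say which entry the removed animals belonged to,
so they are attributed proportionally to current subgroup sizes. Expected
counts per 5-kg bin are CDF differences; bins are aligned to multiples of
the bin width and cover every component mean ± 4 sd of the widest
component, so the untallied tail is below 1e-4 of the head count.
Components are not truncated at 0 kg (the sub-zero tail mass is reported
in the run summary; for realistic parameters it is ≈ 0).

## From level readings to consumption

1. **Geometry.** Level fraction → occupied volume. `linear` geometry maps
   proportionally to the usable volume; `cylinder_cone` treats the
   fraction as fill height over total height, filling the bottom cone
   (apex down) first, with the closed forms validated against the declared
   usable volume to 0.1% at load.
2. **Refill detection.** On a median-despiked copy of the volume series
   (kernel 5 readings; 1 disables), maximal runs of consecutive increases
   whose cumulative gain reaches the threshold (default 1 m³) are refill
   candidates. Each event is then pinned to the reading with the largest
   single-interval *raw* increase near the run: the raw jump of a real
   truckload (~9 m³) dwarfs reading noise, and pinning removes the
   half-kernel timing jitter the median filter can introduce. Increases
   below threshold are left to the smoother as surface noise.
3. **Jump size and local trend fits.** The apparent reading-to-reading
   jump understates the delivered volume by the consumption of the refill
   interval and carries two readings' noise. The jump is therefore
   re-estimated as the difference of two local trend fits (default window
   36 readings ≈ 3 days per side, one-reading guard band on the pre side)
   extrapolated to the refill instant. Each fit selects between a straight
   line and a continuous piecewise-linear spline with knots at UTC
   midnights: feed rationing changes at the daily granularity, so the true
   depletion trend is a daily-knot spline, but each of its slopes rests on
   at most 12 readings and extrapolates poorly under noise, while the
   day-to-day ration drift (~1–2%/day) is far below any measurable reading
   noise. The spline is therefore kept only when it explains the window
   essentially exactly (residual sum of squares at numerical precision —
   the noise-free regime); otherwise the straight line is used. Under 1%
   -of-capacity noise this puts the per-load volume (hence density) error
   at ~1% on average.
4. **Density.** A declared truckload weight over the fitted volume jump
   calibrates that load's density; without a declaration the configured
   default applies. The post-refill segment density is total mass over
   total volume of residual feed plus load (a mass-weighted *harmonic*
   mean of the densities — the sensor measures volume and both mass and
   volume are conserved, so an arithmetic blend would break mass balance).
   A declared refill dated at or before the first reading is treated as
   the opening fill and calibrates the opening density against the
   trend-fitted opening volume; declaring the first load is part of
   setting up a batch and pins the whole mass balance.
5. **Cleaning.** Per segment (never across a refill): gaps of up to 6
   missing readings (12 h) are linearly interpolated on time — longer gaps
   are left out, and the consumption bridging them is attributed to the
   day the gap ends; a centered moving average of 13 readings (≈ one day,
   truncated symmetrically at segment edges) removes surface noise; the
   pool-adjacent-violators projection in the antitonic direction restores
   the physical non-increasing shape exactly. Segment endpoints are then
   re-anchored on the local trend fits from step 3: symmetric truncation
   leaves edges almost unsmoothed, and refill-boundary consumption depends
   on exactly those points.
6. **Consumption.** Within segments, consecutive differences; across a
   refill boundary, `max(0, pre − (post − refill weight))`, floored at
   zero with a warning when sensor error exceeds the interval's
   consumption. Regular intervals aggregate to the day of their midpoint;
   gap-spanning intervals to the day of their end.

Total consumption telescopes to the anchored endpoints plus declared
weights, so with declared refills the estimate is exact on noise-free
traces (≲1e-10 kg observed) regardless of smoothing.

## Alerting

The growth rule flags a run of at least 2 consecutive weeks (configurable)
with |relative deviation| > 0.10 (configurable) and raises one alert per
run, at its first week. The deviation fed to the rule is computed on
*weekly intake increments* by default: an underfeeding episode shifts the
weekly increment immediately, while the cumulative curves — which the
`deviation_series` helper also supports, and which the weekly output table
reports — dilute a 20% weekly deficit by the weeks already accumulated and
can take a month to cross any threshold. Data accuracy is checked first:
if the affected span contains a refill without a declared weight, a
*verify refill data* alert replaces the growth alert for that span, since
a missing declaration biases the intake estimate in exactly the observed
direction. A separate rule flags weeks with more than 25% missing
readings. Delivery goes through a `send(message)` notifier contract
(default: structured log); failures are recorded per alert and never abort
processing.

## The digital twin

`simulate()` generates the study conditions end to end: per-animal daily
intake is the day-differenced logistic curve at each subgroup's age,
scaled by injected anomaly multipliers; subgroup weights follow the
Gompertz curve at the (actual) accumulated intake; departures are
scheduled in truckload groups once the marketing weight is crossed. The
silo opens at 92% fill at a drawn density; consumption is constant within
each calendar day (rations change daily); whenever the delivery-hour
(10:00) reading finds the level at or below the reorder fraction (25%), a
6,000 kg truckload at a density drawn uniformly from 600–680 kg/m³ is
added with mass-weighted blending. Readings get additive Gaussian level
noise (sd as a fraction of capacity, default 1%) and are dropped as
missing with probability 0.02 (never the first reading, which anchors the
declared opening fill). One seeded stream drives all draws in documented
order (opening density, then per-reading noise/missingness interleaved
with per-refill densities), so traces are bit-reproducible.

Default parameters describe a plausible commercial fattening batch: 600
pigs entering at age 10 weeks and 25 kg; `A_f = 1000` kg, `b_f = 0.12`;
`A = 160` kg, `b = 6.76`, `k = 0.008` (entry ≈ 25 kg, ≈ 110 kg after 18
weeks, average intake ≈ 1.6 kg/day); variance cubic `(6, 2, 0.3, 0)` (sd
2.4 → 11.8 kg over 18 weeks); ADG 0.67 kg/day and FCR 2.35 consistent with
those curves; a 24 m³ silo (≈ 15,400 kg at the default 640 kg/m³).

What the twin does *not* emulate: feed bridging/rat-holing in the cone,
laser-spot geometry, diurnal feeding rhythms finer than daily rations,
correlated sensor drift, wastage (all discharged feed counts as consumed),
and real per-load density variability (the uniform 600–680 kg/m³ range is
a placeholder exposed in configuration). Passing recovery tests therefore
demonstrates correctness of the estimation chain under these idealised
noise and missingness models, not field accuracy.

## Numerical choices and degenerate inputs

* Smoothing window 13 readings, refill threshold 1 m³, despike kernel 5,
  fit window 36 readings, refill-declaration matching tolerance ±6 h — all
  in `CleaningConfig`.
* Segments shorter than 2 readings pass through the cleaner unchanged with
  a warning; series shorter than one week produce header-only weekly
  outputs, no distribution and no alerts.
* A refill detected with no declared weight within tolerance falls back to
  the default density and is a candidate for the data-accuracy alert;
  a declared refill with no detected jump is ignored with a warning.
* Negative boundary consumption (sensor error larger than consumption
  across a refill) is floored at zero with a warning.
* Deviations at weeks with zero theoretical intake are defined as 0.
* Byte-level determinism of all outputs: floats are written with 12
  significant digits (round trips reproduce values to better than 1e-9
  relative), and identical inputs yield identical bytes.

## Known limitations

* The level-noise model is additive Gaussian on the fill fraction; real
  laser sensors show occasional large spikes, which the median despike
  tolerates but the tests do not exercise beyond the uniform ±0.05 m³
  case.
* Endpoint extrapolation of the local trend fits has standard error
  ≈ 0.35× the reading noise; an unlucky draw can push a single week's
  intake recovery error toward 2% at 1%-of-capacity noise.
* Subgroup-level sensor AFI for batches with several entries uses the
  batch-average per-animal intake since each entry's arrival; individual
  subgroup appetites are not separable from a single silo signal.
* Growth/variance parameters are taken as given; fitting them from
  historical batches is out of scope.
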
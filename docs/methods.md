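# Methods

This note records the models and procedures implemented in `aeropollen`,
the assumptions behind them, the defaults that matter, and the choices made
where the standard aerobiological definitions leave room.

## Concentration conversion

A Hirst-type volumetric trap draws air at `flow_rate` L/min (default 10)
onto a moving tape; one daily slide represents `sampling_minutes` of air
(default 1440) and only a fraction `counted_fraction` of its surface is
examined (default 0.125, the midpoint of the 12–13% covered by four
horizontal transects). The concentration is

    C [grains/m³] = count / counted_fraction / (flow_rate × sampling_minutes / 1000).

Tape geometry (transect width, tape advance) is deliberately not modelled:
the factor is reconstructed from flow × fraction only, and all three
parameters are exposed in `TrapConfig` so a lab's own calibration can be
substituted.

## Annual Pollen Integral and the 90% season

APIn is the mean of the *observed* daily concentrations multiplied by the
number of calendar days in the period. With complete data this is the plain
daily sum; with gaps it scales the mean up to the full period, which is the
reading implied by "average daily concentration × duration". Both
conventions are implemented (`apin_mode="mean_times_days" | "sum"`);
mean × days is the default.

The Main Pollen Season uses the 90% method: start = first day the
cumulative sum reaches 5% of the annual total, end = first day it reaches
95%. Specific decisions:

* threshold crossing is `≥` (the first day *reaching* the quantile), with a
  relative tolerance of 1e-12 × total so exact fractional crossings are not
  lost to floating-point drift;
* `duration_days = end − start` (exclusive difference), verified against
  seven printed taxon-year rows of the motivating monitoring campaign
  (e.g. 03/02→31/03 = 56, 14/01→02/04 = 78, 14/02→09/07 = 145);
* missing days contribute zero to the cumulative sum — no interpolation;
  years with more than 25% of days unobserved carry a `quality_warning`;
* peak ties break to the earliest date, so output is deterministic;
* a zero-total year returns a flagged, undefined season rather than raising.

On synthetic seasons (gamma mean curve, negative-binomial noise,
dispersion 5, peak ≥ 100 grains/m³) the recovered start/end sit within a
median 1 day of the noise-free truth (40 seeds; recomputed by
`scripts/acceptance.py`).

## Pollen calendar

The climatology averages each calendar day across years (Feb 29 only over
leap years; a year missing a day simply drops out of that day's
denominator). Months are split into five sections; because "five 6-day
sections" cannot hold for 28/29/31-day months, sections 1–4 are exact
(days 1–6, …, 19–24) and section 5 absorbs the remainder (4–7 days). The
section mean over defined days, weighted by the number of defined days,
exactly reconstructs the climatology's annual mean (conservation, checked
to 1e-9).

Flowering classes come from the cumulative fraction F(d) of the
climatology's annual integral: *main* runs from the first day F ≥ 10%
through the first day F ≥ 90% (both inclusive — the day the curve reaches
90% ends the period); *early* is before main with F > 0.5%; *late* after
main with F < 99.5%; *possible* is any other day with pollen observed
(strict climatology > 0); everything else is *none*. Every day gets exactly
one class. A section displays the highest-ranking class among its days
(main > late > early > possible > none), so any main-period day makes the
section main. Intervals are computed on the multi-year climatology, not per
year and then averaged.

Allergenicity (high/moderate/low) is user configuration: it is a judgement
from the clinical literature, not derivable from counts. A default table
for common NW-European taxa ships with the package and is meant to be
edited.

## Wind source-receptor estimation

Wind directions are meteorological ("from", 0° = N, clockwise); all angular
arithmetic is wrapped. The per-period direction variability is the
single-pass Yamartino estimator,

    ε = sqrt(1 − (mean sin θ)² − (mean cos θ)²),
    σ = asin(ε) · (1 + (2/√3 − 1) ε³),

bounded by 90°·2/√3 ≈ 103.92°, and agreeing with the two-pass circular SD
to within 2% at moderate spreads (checked against a brute-force oracle).

NWR estimates the expected concentration at a polar point as a kernel
weighted mean: wrapped Gaussian in direction (default bandwidth 15°) ×
Gaussian in speed (default 2 km/h), on a 72 × (0.5 km/h) grid up to the
observed maximum speed. Cells with total kernel weight below `weight_floor`
(1e-3) are undefined. Every defined cell is a convex combination of the
observed concentrations.

SWIM multiplies each observation's kernel weight by σ̄/σᵢ, up-weighting
sustained (low-variability) winds. One published rendering of the SWIM
equation glosses its symbols as "wind speed, wind direction, and wind
direction standard deviation"; this conflicts with the NWR/SWIM literature
it builds on, where the numerator variable is the measured *concentration*.
The implementation follows the literature construction (concentration ×
kernel weight, scaled by σ̄/σᵢ, optionally max-normalised to [0, 1]); the
discrepancy is documented here rather than resolved. A σᵢ = 0 observation
would carry infinite weight and is replaced by the smallest positive σ
observed, with a warning.

Dominant sectors use compass sectors *centred* on the compass points
(N spans 337.5°–22.5°), the standard rose convention; ties break to the
lowest speed band, then the first sector clockwise from N. Wind speeds
archived in knots are converted at 1 kt = 1.852 km/h; rose speed rings
default to 2/4/8/12 km/h.

## Meteorological screening

Daily pollen data are not normal, so association is measured by Spearman
rank correlation (average ranks for ties, t-approximation p with n − 2 df);
the Lilliefors screen (KS distance to a normal with estimated mean/SD,
table-based p, or a seeded Monte-Carlo null of 10⁴ replicates) is reported
but never gates the pipeline. Season-scale screening restricts to the days
of each taxon's MPS; monthly screening requires at least 10 paired days per
month — below that, rank statistics are noise. Fewer than 3 complete pairs
or zero rank variance yields a flagged undefined result, never a silent
drop. α defaults to 0.05 with no multiple-testing correction (matching
per-pair reporting conventions); Benjamini–Hochberg is available but off by
default.

## Diurnal profiles

A day qualifies for the diurnal average when at least 12 of its hours are
observed. Percent mode (default) rescales each qualifying day to percent of
its own total before averaging — removing abundance swings so the diurnal
shape dominates — and excludes zero-total days; absolute mode averages raw
concentrations per hour. Peak windows are maximal contiguous runs at
≥ 80% of the profile maximum, computed on the 24-hour circle so a window
may cross midnight; bimodal profiles return two windows. Hours are local
clock hours as recorded; no daylight-saving adjustment is applied.

## Synthetic data

The generators emulate the structure the analysis assumes, with ground
truth recorded for every fixture:

* **Seasons**: a gamma kernel anchored at the season start with its mode at
  the peak day; the decay scale is (length − mode)/4 so essentially the
  whole curve fits in the stated season length. The curve is normalised to
  the target APIn. Daily noise is negative-binomial with dispersion k
  (variance μ + μ²/k, default k = 5): aerobiological counts are
  overdispersed, and the Poisson limit is reachable by raising k;
  `dispersion=None` returns the exact noise-free curve.
* **Bimodal year**: a default bundle of seven tree taxa (Jan–May) and four
  grass/herb taxa (Jun–Aug) with APIn magnitudes of the order observed in
  urban NW-European records (grass/nettle ~10⁴, birch/cypress ~10³), so the
  summed series is bimodal with the summer mode dominant.
* **Wind plumes**: directions uniform on the circle, speeds gamma(2, 4 km/h);
  concentration elevated (default 50 vs base 2 grains/m³) only when the
  wind comes from within ±10° of the source at 8–12 km/h. Source days draw
  σ in 5–15° (a sustained plume), others 15–60°, which is precisely the
  contrast SWIM exploits.
* **Meteorological association**: a Gaussian copula — pollen ranks mapped
  to normal scores and mixed with noise at Pearson 2·sin(πρ/6), the value
  whose induced Spearman correlation equals the target ρ, so the
  calibration is exact in expectation.
* **Hourly allocation**: each day's total distributed multinomially over a
  24-weight template, then rescaled so the daily mean is preserved exactly.

What the generators do *not* emulate: weather-driven day-to-day
autocorrelation, rain washout, multi-day pollen release episodes, trap
efficiency drift, or correlated noise between taxa. Passing recovery tests
therefore shows the estimators are correct under the stated stochastic
model, not that real monitoring data meet that model.

## Problem sizes and determinism

The test suite and acceptance script use 1,000 random series for the season
oracle comparison, 40 seeds for season recovery, 20 seeded plume
simulations (730 days each) for SWIM recovery, and 100 seeds (n = 365) for
Spearman calibration — sizes at which the Monte-Carlo bands in the checks
are comfortably stable while the whole suite runs in well under a minute.
All randomness flows through explicit `numpy.random.default_rng` seeds; the
CLI writes text outputs with fixed float formatting, so a rerun under the
same seed is byte-identical.

## Known limitations

* The MPS is only the 90% (5–95%) quantile-pair definition (the pair is
  configurable); threshold-day and logistic-fit season definitions are out
  of scope.
* SWIM/NWR infer direction-of-origin at the receptor; they are not a
  transport model and cannot separate distance, nor attribute long-range
  sources beyond a wind-sector statement.
* The calendar's variable-length fifth section means section means are not
  all 6-day means; the `n_days` column carries the weights needed for any
  downstream re-aggregation.
* A true single-pass per-day Yamartino σ requires sub-daily direction
  samples; the package computes σ from whatever within-period samples the
  user supplies and otherwise accepts σ as an input column.
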
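# Methods

This note documents the models, conventions, numerical choices and known
limitations of `heatrhythm`, in the order the pipeline runs them.

## The estimator

The core regression treats hourly outdoor-activity counts as log-linear in
binned temperature with four fixed-effect (FE) dimensions:

```
log(Y_ict + 1) = f(Temp_ict) + X_ict γ + δ_i + η_h + θ_dow + μ_cm + ε_ct
```

* **Outcome.** `log(Y + 1)`; adding one keeps zero-count hours (rare in
  realistic panels: ~0.002% on the bundled configuration) in the sample.
* **Bins.** Half-open 5 °C intervals on a grid aligned at 0 °C, resolved
  from the observed range; 20–25 °C is the omitted reference. For a 3 °C
  grid the reference is the bin containing 22.5 °C. `merge_below` /
  `merge_above` collapse the tails into terminal open bins — the calibrated
  analyses merge below 0 °C and above 35 °C so the fitted grid matches the
  generator's effect grid and "<0" / ">35" are single reported bins.
  Empty non-reference bins are dropped with a warning rather than erroring,
  since the grid is range-dependent.
* **FE absorption.** Alternating within-group demeaning over
  park / hour-of-day / day-of-week (or calendar date) / city × month, swept
  until the largest absolute adjustment in a full sweep is below `tol`
  (default 1e-8, max 10,000 sweeps; a non-convergence error carries the last
  residual). On balanced panels this converges in a handful of sweeps.
  Equivalence with explicit dummy-variable OLS is tested to 1e-6 on small
  panels.
* **Inference.** CR1 cluster sandwich by city:
  `V = c (X'X)⁻¹ [Σ_g s_g s_g'] (X'X)⁻¹` with
  `c = G/(G−1) · (N−1)/(N−K)`, where `K` counts the slope parameters plus
  absorbed FE levels (sum of group counts minus the shared intercepts — an
  approximation; exact redundancy detection is out of scope). Critical
  values are normal for G ≥ 50 and t with G−1 degrees of freedom below
  that. Percentage effects `e^β − 1` and their CIs are endpoint transforms
  of the Wald interval (no delta method), so the monotone-transform
  invariant holds exactly.
  A caveat the test suite encodes: when a bin's observations concentrate in
  one or two cities (terminal bins under a wide climate spread),
  cluster-robust intervals undercover; nominal-coverage checks are therefore
  run on interior bins with broad cluster support.
* **Variants.** Daily aggregates reduce temperature by min/mean/max over
  the 6 AM–10 PM window, sum visits (outcome `log(Σ visits + 1)` — the daily
  outcome construction is this package's choice) and drop the hour FE.
  Period regressions sum visits within morning (6–9 AM), noon (10 AM–2 PM),
  late afternoon (3–6 PM) and evening (7–10 PM) — the 2–3 PM hour is
  assigned to the noon (hot) set for contiguity — and use binned daily mean
  temperature as the regressor. Hourly profiles replace the temperature
  bins with hour dummies (1 PM reference) fitted separately per
  daily-temperature group; covariates that are degenerate inside a group
  subsample (e.g. no holidays among the hottest days) are dropped with a
  warning instead of aborting. Stratified fits run the merged-bin model
  independently per stratum, skipping strata with fewer than two clusters.

## The time-shift statistic

The within-day profile's 17 hourly magnitudes `e^{β_h}` (hours 6..22) are
treated as a piecewise-constant density on the 16 unit intervals
[k, k+1), k = 6..21; the hour-22 coefficient closes the activity window at
10 PM (it marks the endpoint and carries no interval of its own). This
makes the after-`h` share

```
r(h) = ∫_h^22 e^β dh / ∫_6^22 e^β dh
```

piecewise linear, so the equation

```
r(ref; base) · q(base) = r(ref + Δ; T) · q(T)
```

is inverted *exactly* by locating the bracketing integer breakpoints and
solving the linear segment — no iterative root-finding error. Negative
shifts are permitted; if the right-hand side cannot reach the target even
at 6 AM (q(T) below the target level) an explicit unsolvable error is
raised rather than returning a clipped extreme. A consequence of the
convention worth knowing: only whole-hour translations of a profile are
represented exactly; sub-hour translations are approximated through the
hourly discretisation.

`q(T)` comes from the daily-aggregate fit as `e^{β_T − β_base}` (baseline
15–20 °C pinned at exactly 1, with the SE of the difference taken from the
clustered covariance).

**Uncertainty.** Both inputs are estimated curves. Each curve is moved
*jointly* to 25 equally spaced probability levels `p = 1/26 … 25/26` of its
coefficients' normal sampling distribution (one grid dimension per input
object, mirroring the 21 × 25 = 525 arithmetic of the projection); the
shift is re-solved on the 25 × 25 grid and the empirical 2.5/97.5
percentiles form the CI. Whether the quantile sampling should move each
hour's coefficient independently or the whole curve jointly is ambiguous;
joint movement was chosen as the interpretation consistent with the printed
grid sizes. Unsolvable grid cells are excluded with a logged count; more
than 10% unsolvable sets a warning flag on the result.

## Exposure summary

For days whose daytime (6 AM–10 PM) mean falls in a requested bin, hourly
temperatures are summarised within the hot period (10 AM–6 PM, the union of
noon and late afternoon including the 2–3 PM gap) and the cool periods
(6–9 AM ∪ 7–10 PM). Means are day-weighted (duplicate park rows collapsed);
an activity-weighted variant accepts per-hour weights. The partition
identity (whole-day mean = duration-weighted combination of period means)
and shift invariance of the reduction are tested.

## Projection

* **Spline.** Natural cubic through (bin midpoint, β); terminal open bins
  get midpoint = edge ± half a bin width. Beyond the terminal midpoints the
  curve is held constant — cubic extrapolation at unobserved temperatures
  is deliberately avoided. Fewer than four knots raises an error suggesting
  the quadratic fit.
* **Disaggregation.** `T_hmy = T_hm,base + ΔT_my`: the same monthly delta is
  added to every hour (per-hour differential warming is not resolved by the
  inputs); monthly-mean conservation is exact and tested.
* **Activity change.** Per cell-month,
  `100 · [mean_h e^{f(T_proj)} − mean_h e^{f(T_base)}] / mean_h e^{f(T_base)}`
  — exponentiate first, average over the 17 daytime hours, then difference,
  because activity is multiplicative in the log model.
* **Time-shift change.** A spline through the per-bin Δt(T) curve evaluated
  at the daytime-mean temperature of each month's representative day,
  averaged over the requested months (summer = June–August,
  winter = December–February).
* **Monte Carlo.** The climate dimension enumerates models (not resampled);
  the coefficient dimension moves all spline knots jointly to each of 25
  normal quantiles. 21 models × 25 quantiles = 525 draws per cell-month;
  CIs are empirical 2.5/97.5 percentiles. Models with incomplete month
  coverage are excluded with a warning. Note that with *equal* knot SEs a
  joint shift cancels exactly in the percentage change — the spread of the
  coefficient dimension comes from the SE differences across bins, which is
  the realistic case.

## The synthetic generator and its calibration

The generator emulates the study conditions, not any real data set:

* **Climate.** Per city: mean + seasonal sinusoid (warmest ≈ late July) +
  diurnal sinusoid (warmest 3 PM, coldest pre-dawn) + hourly AR(1) noise
  (stationary sd `ar1_sd_c`, ρ = 0.9). Cities differ only by a mean offset;
  there is no cross-city spatial correlation. Covariates (precipitation,
  wind, humidity, pressure, cloud, AQI) are drawn independently of
  temperature — exogeneity by construction. Holidays are national Bernoulli
  draws per date.
* **Counts.** Poisson by default (negative binomial optional via a gamma
  mixture); the hourly mean multiplies a daily intercept (default 2,500
  expected visits/park/day), the day's within-day share profile, the
  structural temperature response, FE draws and covariate effects.
* **Redistribution.** On a day with daytime mean `T`, the share profile is
  the convex mixture `(1−w)·baseline + w·delayed` with
  `w = mix_max · logistic((T − 27)/2.5)`. The delayed profile moves 45% of
  the baseline's 10 AM–6 PM mass into 6–9 AM (30%) and 7–10 PM (70%), the
  evening allocation tilted later by the evening-delay parameter. The
  mixture conserves within-day mass exactly for every temperature.
* **Bundled configuration** (`study_2017`): 20 cities with mean offsets
  spanning −12 … +11 °C around 16 °C, 10 parks each, 120 days from
  1 February — the winter-to-early-summer sweep across a wide latitude
  range populates every bin from below 0 to above 35 °C in one season of
  data.

**Why the calibration exists.** Hot hourly bins occur at midday on exactly
the days that redistribute activity, so the hourly regression's estimand
for the hot bins combines the structural hourly response with the
substitution pattern — which is precisely the scientific point of hourly
resolution. The configuration therefore distinguishes `bin_effects` (the
reduced-form truths the estimator should recover; these carry the headline
numbers) from `direct_bin_effects` (the structural multipliers inside the
generator). `scripts/calibrate_study.py` computes the population estimand
of the hourly regression on a large replicated noise-free climate sample
(48 replicates, fixed seeds, the same absorption machinery, no count
noise), including an expected-`log1p` correction for the gap between
`E[log(1+Y)]` and `log λ` at low counts (exact Poisson summation averaged
over the generator's FE/covariate offset distribution — without it the
cold-bin estimand is biased by ~0.3 pp because dawn hours on cold days have
the smallest counts), and iterates the direct effects until the estimand
matches the targets. A scalar root-find on `mix_max` simultaneously sets
the implied >30 °C time shift at 8 PM to 27 minutes. The calibrated
constants and the frozen ground truth (profiles, quantity ratios and shifts
per daily group, evaluated on an independent 72-replicate sample) are plain
literals in `heatrhythm.fixtures`.

**Oracle.** `true_timeshift` solves the shift equation on the noise-free
expected profiles by dense-grid accumulation (step 0.05 min) — a code path
independent of the production solver; the two agree to < 0.1 min and both
are compared against the frozen truth.

**What passing tests do and do not show.** Recovery on this generator
demonstrates the estimator and solver are correct for a data-generating
process with exogenous weather, independent covariates, balanced complete
panels and no spatial correlation. Real visitation data has none of these
guarantees — endogenous pollution, missing park-hours, park-level
composition changes across days, and within-city spatial structure are all
outside what these tests certify. The Poisson default is a stand-in: the
dispersion of real visitation counts is unknown, and the estimator (OLS on
`log(Y+1)`) does not rely on it.

## Problem sizes and runtime

The recovery analyses use ten seeds of the full bundled panel
(20 × 10 × 120 × 17 = 408,000 rows each); one simulate-fit-shift cycle takes
roughly five seconds, the ten-seed suite under a minute on one CPU. Test
configurations elsewhere use 2–12 cities and 8–120 days, chosen as the
smallest sizes at which the tested property is statistically unambiguous.

## Known limitations

* Absorbed-FE degrees of freedom use the approximate redundancy count
  (dimensions minus one); exotic FE graphs with extra redundancies would
  overstate `K` slightly.
* One-way clustering only; no two-way or wild-cluster bootstrap inference.
* The daily-group grid is resolved from the realized daily-mean range, so
  group labels on very narrow climates differ from the canonical 5 °C
  labels.
* Terminal-bin inference inherits the few-effective-clusters problem noted
  above.
* The projection consumes monthly deltas already on the analysis grid;
  downscaling, gridding and population weighting of climate-model output
  are out of scope.
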
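# heatrhythm

Intraday heat adaptation in outdoor activity: when the day is hot, people do
not simply stay home — they move their outdoor time out of the midday heat
and into the morning and evening. Activity data observed only at daily or
monthly resolution misses this margin; hourly data reveals both a larger
activity-depressing effect of heat and a health-relevant delay of evening
activity toward bedtime.

`heatrhythm` is a tested, reusable implementation of that analysis for
researchers in environmental epidemiology and climate econometrics. It
provides:

* **A binned fixed-effects dose–response estimator.** For park *i* in city
  *c* at hour *t*,

  ```
  log(Y_ict + 1) = f(Temp_ict) + X_ict γ + δ_i + η_h + θ_dow + μ_cm + ε_ct
  ```

  where `f` assigns an indicator to each 5 °C temperature bin (20–25 °C is
  the omitted comfort reference), `X` holds weather, air-quality and holiday
  controls, and `δ_i, η_h, θ_dow, μ_cm` are park, hour-of-day, day-of-week
  and city-by-month fixed effects absorbed by alternating projections.
  Standard errors are clustered at the city level (CR1 sandwich); bin
  coefficients are reported as percentage effects `e^β − 1`. Variants:
  quadratic polynomial, 3 °C bins, calendar-date fixed effects, daily
  aggregates (min/mean/max), period-of-day regressions, within-day hourly
  profiles and stratified fits with merged terminal bins.

* **The activity time-shift statistic.** With `r(h)` the share of a day's
  activity after hour `h` (the hourly profile treated as a piecewise-constant
  density) and `q(T)` the relative daily quantity versus 15–20 °C days, the
  shift Δt solves

  ```
  r(20:00; 15–20 °C) · q(15–20 °C) = r(20:00 + Δt; T) · q(T)
  ```

  exactly (r is piecewise linear), with a Monte-Carlo confidence interval
  over a 25 × 25 grid of coefficient quantiles.

* **Exposure arithmetic**: mean temperature in hot periods (10 AM–6 PM)
  versus cool periods (6–9 AM, 7–10 PM) on days in a given daily bin — the
  exposure reduction available from rescheduling.

* **Climate projection**: a natural cubic spline through the bin
  coefficients, monthly warming deltas added uniformly to the hours of a
  baseline year (`T_hmy = T_hm,base + ΔT_my`), and uncertainty propagated
  over climate models × coefficient quantiles (21 × 25 = 525 draws per
  cell-month).

* **A synthetic panel generator** with known ground truth: city-level
  seasonal/diurnal/AR(1) weather, Poisson or negative-binomial counts on a
  log-linear mean with all four fixed-effect dimensions, an inverted-U
  temperature response, and a heat-triggered mass-conserving redistribution
  of within-day activity with a parameterised evening delay — plus an
  analytic oracle for the implied time shift. The bundled `study_2017`
  configuration is calibrated so that the estimator's reduced-form truth is
  a 13% / 5% / 20% visitation reduction for >35 °C / 30–35 °C / <0 °C and
  the >30 °C time shift at 8 PM is 27 minutes.

## Worked example

```python
from dataclasses import replace
from heatrhythm.fixtures import study_2017_config, FIT_BINS
from heatrhythm import synth, estimator, timeshift

config = study_2017_config()
panel, truth = synth.generate_panel(config, seed=1)   # 408,000 park-hours

spec = estimator.ModelSpec(temperature=FIT_BINS)
fit = estimator.fit(panel, spec)
table = fit.bin_table()
for b in ("<0", "30-35", ">35"):
    row = table.loc[b]
    print(f"{b:>6}: {100*row.pct:+.1f}%  (95% CI {100*row.pct_low:+.1f} "
          f"to {100*row.pct_high:+.1f})")

daily_bins = estimator.BinSpec(reference=(15, 20), merge_below=0.0, merge_above=30.0)
daily_fit = estimator.fit_daily(panel, replace(spec, temperature=daily_bins))
q = timeshift.daily_quantity_curve(daily_fit)
profile = estimator.fit_hourly_profile(panel, spec, temp_groups=["15-20", ">30"])
res = timeshift.timeshift_ci(profile, q, comparison_group=">30")
print(f"time shift >30 degC at 8 PM: {res.dt_minutes:.1f} min "
      f"(95% CI {res.ci_minutes[0]:.1f} to {res.ci_minutes[1]:.1f})")
```

prints

```
    <0: -20.0%  (95% CI -23.2 to -16.7)
 30-35: -5.2%  (95% CI -6.4 to -3.9)
   >35: -13.5%  (95% CI -15.4 to -11.6)
time shift >30 degC at 8 PM: 26.9 min (95% CI 26.6 to 27.1)
```

Hourly temperatures above 35 °C depress visitation by about 13% relative to
the 20–25 °C reference, sub-zero hours by about 20%, and on days whose
daytime mean exceeds 30 °C the amount of activity still outstanding at
8:27 PM equals what is outstanding at 8:00 PM on a comfortable day — an
evening delay with potential consequences for sleep. Each value recovers
the generator's configured ground truth (`truth` above) within sampling
noise.

The same pipeline is available from a shell:

```bash
heatrhythm simulate --seed 1 --out run/
heatrhythm fit --panel run/panel.csv --out run/ --merge-extremes
heatrhythm run --seed 1 --out run_full/     # all five stages + manifest
```

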
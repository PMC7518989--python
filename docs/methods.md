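# Methods

This note documents the model, its parameters, the synthetic data the
package runs on, and the numerical and design choices a user refitting or
extending the simulator should know about.

## Model structure

The simulator is a one-stock system-dynamics model advanced by explicit
(forward) Euler at Δt = 1 day, matching the daily resolution of mortality
surveillance data; no sub-stepping is performed. The stock is the affected
population AP (persons currently ill from heat exposure). Flows, all in
persons/day:

| flow | form | role |
|---|---|---|
| APF (inflow) | (pop/10⁷)·(r_base + β·max(0, Tmax − t_morb)) · (allowance/ref)^(−v) | exposure–response |
| TPF (outflow) | min(AP · AF, beds · c) | treatment |
| D (outflow) | AP · μ · MA(Tmax) · HDAF(hot days) | heat-attributable deaths |

with AF = min(af_cap, af₀ · EC · HF · GF). EC, HF and GF are weighted
power laws (Cobb–Douglas) of indicator/reference ratios — e.g.
HF = (staff/staff_ref)^w_staff · (beds/beds_ref)^w_beds ·
(hospitals/hosp_ref)^w_hosp — so each equals exactly 1 at the reference
city, is dimensionless and monotone in every indicator with positive
weight. Ratios are floored at 10⁻³ and each factor capped at 10 to keep
degenerate profiles from zeroing or exploding treatment.

If the outflow demand TPF + D ever exceeds AP + APF, both outflows are
scaled by the same factor so the stock stays non-negative and the
treatment:death ratio is preserved. Mass balance —
initial AP + ΣAPF = final AP + ΣTPF + ΣD — holds to 10⁻⁹ relative at all
times and is enforced by a property test.

Reported daily deaths add a constant background (persons per ten million
per day, times population) to D, so simulated trajectories are on the scale
of observed all-cause summer death counts. Scenario comparisons operate on
these totals.

Two structural choices deserve emphasis, because the printed equations of
this model family contain only APF, TPF and a multiplicative AF:

* **Death outflow.** A stock–flow model without a death outflow cannot emit
  a death toll; D = AP·μ·CF is the minimal linear closure, with CF carrying
  all temperature and duration dependence and the mortality threshold
  (37.6 °C) expressed through an MA table equal to 1 below it.
* **Bed capacity and allowance exposure.** A pure AF-multiplier treatment
  channel bounds the effect of any 20% indicator improvement at
  1.2^w ≤ 1.2, which caps single-day death reductions well below the
  15–22% range mitigation measures achieve, and makes bed and allowance
  scenarios formally identical (both are AF multipliers). Two mechanisms
  the underlying framework describes verbally are therefore modelled
  explicitly: hospital beds impose an absolute daily treatment throughput
  (beds · c, persons/day), so the health system saturates during the crest
  of a severe wave and readying 20% more beds relieves precisely that
  bottleneck; and the minimum living allowance scales the exposed
  vulnerable population (APF × (allowance/ref)^(−v)), since a higher income
  floor lets poor households afford cooling and care. These give the two
  mitigation scenarios their distinct temporal signatures: bed readiness
  acts while the system is saturated (mid-episode), the allowance acts on
  exposure from day one and compounds through the episode.

## Scenarios

Scenarios are declarative transformations applied before integration:

* `temp_offset` — add δ °C to every day's maximum temperature (marginal
  warming experiments; hot-day counters are recomputed on the shifted
  series);
* `bed_readiness` — beds × (1 + fraction), default 0.20, from
  `warning_day` (default 0: the measure is active for the whole episode,
  i.e. the warning arrives before the wave);
* `allowance_increase` — allowance × multiplier, default 1.20, from
  `warning_day`.

`compare` reports per-day absolute and percentage reductions of total
deaths (percentage is null on days with zero baseline deaths), and the
peak-reduction days in 1-based "day N within episode" numbering.
Monotonicity is guaranteed and property-tested: with monotone tables,
mitigation never increases and warming never decreases any day's deaths.

## Episode detection

The CMA operational definition, with "exceeding" read strictly
(Tmax > threshold): a maximal run of consecutive days above 35 °C is a
strong heat wave if it lasts ≥ 5 days or contains ≥ 2 consecutive days
above 38 °C, and extreme if ≥ 8 days or ≥ 3 consecutive days above 38 °C;
a run meeting both grades is labelled extreme. A single cool day ends an
episode and resets the hot-day counter. Both thresholds are arguments with
defaults 35/38 °C.

## Parameters and the shipped calibration

All coefficients live in one YAML document (`heatsd/data/default_params.yaml`):

* `t_morb` = 36.6 °C, `t_mort` = 37.6 °C — empirical morbidity/mortality
  thresholds for the region; fixed.
* `beta_morb` (persons per 10⁷ per °C per day), `r_base` (persons per 10⁷
  per day), `mu` (day⁻¹), `af0` (day⁻¹), the MA/HDAF table heights, the
  indicator weights, `bed_capacity` (persons/day/bed) and
  `allowance_elasticity` — calibrated.
* `background_rate` is derived, not free: it equals the observed cool-day
  mortality level (114 per ten million per day) minus the model's own
  cool-day equilibrium death flow μ·r_base/(af₀+μ) per ten million, so
  simulated cool-day totals sit at the observed level without double
  counting.

The original model's coefficients and table functions were never published,
and the daily temperature trace of the July-2013 episode is likewise
unavailable. The shipped calibration was therefore produced by fitting the
free coefficients — jointly with the stylized within-plateau temperature
curve of the 2013-like fixture — by least squares against the published
scenario outcomes (percentage reductions on the named episode days under
both mitigation measures, and the mean +1 °C/+2 °C effects), subject to the
day-ordering of the peak reductions and to the constraint that treatment
saturates only around the episode crest, never on cool days. Both artifacts
are versioned: the parameter YAML and the plateau curve in
`heatsd.synth._HW2013_PLATEAU`. The calibration reproduces all six
quantities within 0.5 percentage points. It should be read as *a*
calibration consistent with the published behaviour of the system, not as
recovered true coefficients: with six fitted quantities and more free
coefficients, it is deliberately over-parameterised, and other solutions
exist.

Optional switches, both off by default and excluded from the calibration:
`cf_on_apf` routes the climate factor into the inflow (sensitivity
analysis); `tpf_delay` delays the treated outflow by one day (one candidate
explanation for the 1-day peak lag seen in validation-type comparisons).

## Synthetic data

The generators emulate the statistical structure the pipeline needs, not
historical records:

* **Heat-wave fixtures** — shoulder days at 32 °C and a contiguous plateau
  of exactly `plateau_days` days above 35 °C (19 days for the 2003-like
  preset, peak 39.8 °C; 15 days for the 2013-like preset, peak 40.5 °C on
  plateau day 7 with a secondary crest on day 12). Seeded uniform jitter of
  ±0.3 °C adds texture and is clipped so no day crosses the 35 °C threshold
  and the plateau maximum stays exact — episode durations are therefore
  exact by construction for every seed, which the tests assert.
* **City profiles** — fixed documented indicator sets; the 2013-like
  profile carries the two published anchors (24.1 million residents,
  allowance 790/month), all other values are plausible yearbook-scale
  constants. The 2003-like profile differs only in the capacity indicators
  (fewer beds/staff, lower AC rate, income, allowance, insurance).
* **Daily deaths** — Poisson counts around the two-level background
  (114 per ten million per day at Tmax ≤ 35 °C, 124 above), and a
  forward-simulation generator that runs the model with known parameters
  and applies Poisson or no noise, for calibration-recovery experiments.

What passing tests on these fixtures show — and do not show: they verify
the mechanics (integration, detection, scenario algebra, calibration
machinery) and that the committed calibration reproduces the published
scenario behaviour on the packaged fixture. They cannot validate the model
against real station data or CDC mortality records, which are not
redistributable; absolute death tolls on real data would require refitting.

## Calibration and validation machinery

`calibrate` minimises the SSE (or RMSE) between simulated and observed
total daily deaths over any named subset of coefficients, using bounded
Nelder–Mead restarted from seeded random initial points (default 8; the
first start at the bound midpoints). The objective is cheap but non-smooth
(capacity clamp, AF cap, table kinks), which is why a derivative-free
method is the default; any bounded optimiser meeting the bookkeeping
property (returned optimum ≤ every restart's optimum) is acceptable.
`validate` reports RMSE, relative peak-value error
|max(sim) − max(obs)|/max(obs), and peak lag argmax(sim) − argmax(obs) in
days, with ties broken to the earliest day (the lag metric depends on this
choice, so it is fixed and documented).

**Identifiability.** At quasi-equilibrium daily deaths are
μ·CF·APF/(af₀ + μ·CF), which is invariant under (μ, af₀) → (kμ, k·af₀):
on a single short episode the pair is identified only through multi-day
transients, and Poisson noise at realistic count levels leaves ~20%
uncertainty along this ridge. The packaged recovery experiment therefore
uses a 377-day multi-summer series (twenty waves of varied length and
intensity — the data scale a multi-year calibration would actually use) and
a truth with slower relaxation (af₀ = 0.3, μ = 0.1), where all three
headline parameters are recovered within 10% under Poisson noise and within
0.2% at zero noise. Users fitting a single episode should fix either μ or
af₀.

## Numerical and interface conventions

* Indices are 0-based internally; every human-facing output (CLI, compare
  tables, reports) uses 1-based "day N within episode".
* Deaths are kept as continuous flows in the state and all comparisons;
  rounding (half-up) happens only in the integer death-count generators.
* Table functions interpolate linearly between breakpoints and clamp
  (constant extrapolation) outside the breakpoint range, preventing
  negative or explosive factors outside the calibrated domain; evaluation
  at a breakpoint returns its height exactly.
* All file writes are atomic (write-then-rename): an output file is either
  fully written or absent.
* All randomness flows through explicit integer seeds; every generator is a
  pure function of (spec, seed).

## Known limitations

* No humidity or apparent-temperature index: maximum temperature and
  duration are the only climate drivers.
* No distributed-lag exposure modelling and no mortality-displacement
  (harvesting) adjustment; deaths respond to same-day temperature through
  the stock.
* Single city, single station: no spatial heterogeneity.
* The deterministic engine has no process noise; uncertainty enters only
  through the synthetic observation generators.
* The shipped calibration is over-parameterised relative to its six fitted
  targets (see above) and is tied to the packaged 2013-like fixture.
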
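# eabsim

Deterministic bioeconomic simulation of late-stage emerald ash borer (EAB)
management for a municipal tree population. The package models an urban ash
population as annual cohorts, runs seven declarative management scenarios
(injection, preemptive removal, replanting and combinations) over a 20-year
horizon, prices every management event (removal+stumping, pruning cycles,
insecticide injection cycles, planting and warranty replacement), appraises
the standing population with the CTLA trunk formula, and sweeps the four key
management decisions for sensitivity analysis.

## Model in brief

* **Demography** — a single pre-existing ash cohort plus planted non-ash
  cohorts. Survivor counts use a ceiling convention at every cohort-year:
  `N' = ceil(N * survival)`. Uninjected ash die at 20%/yr, injected ash at
  2.8%/yr, background mortality is 0.85%/yr, and newly planted trees follow
  a four-year post-planting survival schedule (91.5 / 88.3 / 95.8 / 93.9%).
  DBH grows linearly (ash 0.3 cm/yr, non-ash 0.47 cm/yr, growth counted in
  the planting year). The initial median ash DBH (27.181 cm) is a calibrated
  constant; `calibrate_initial_dbh` re-derives it from a Year-1 basal area.
* **Scenarios** — seven built-ins, from remove-dead-only (control) to
  injection in perpetuity with replanting. Preemptive removal years suppress
  EAB mortality (scheduled removals subsume the dying trees). Replanting
  either matches ash losses (same year or lagged one year) or plants
  proactively at a fixed rate with a cumulative cap.
* **Economics** — DBH-bracketed removal and pruning prices, $3.325/cm
  injections billed on a 2-year cycle (half the injected population per
  year), pruning on a 4-year cycle (a quarter of all living trees per year),
  $849.91 per planting (free within the 2-year warranty), CTLA trunk-formula
  value at $4.50/cm², and present value via a compound
  `(1.02 / 1.0283)^t` inflation/discount factor.
* **Metrics & sensitivity** — basal area in printed units (cm²/1000), net
  value, cost per tree / per basal unit, ratios to control, rankings under
  five management objectives, and one-at-a-time or factorial sweeps over
  injection end year, removal start year, removal rate, and planting rate.

## CLI

```bash
# run all seven scenarios with the reference parameterization
eabsim run --out out --report-years 1,5,10,15,20

# run from a YAML config (an empty file means "all defaults")
eabsim run --config config.yaml --out out

# sweep the removal rate of a base scenario
eabsim sweep --scenario "Preemptive Removal then Replant" \
    --removal-rate 100,200,300,400,500,600,700,800,900,1000 --out out

# recover the calibrated initial DBH from a printed Year-1 basal area
eabsim calibrate --basal 707.0 --count 1192 --growth 0.3
```

Outputs are CSV (`counts_basal.csv`, `economics.csv`, `sweep.csv`) plus a
JSON `manifest.json` recording every resolved parameter. Runs are fully
deterministic: repeated invocations are byte-identical.

Configuration is YAML (JSON accepted); every key has a package default. Set
`discount_override: 0` to produce the undiscounted (future-value) variant.

## Known conventions and caveats

* The ceiling rounding convention is what makes the integer reference
  trajectories exact; it is applied at every cohort-year transition.
* The proactive-planting scenario ("Replant, Inject, then Preemptive
  Removal") caps cumulative plantings at a 1:1 replacement of the initial
  1,490 ash by default; its reference non-ash counts are not reproducible
  under any natural cap, so the cap is exposed as configuration.
* Reported dollar magnitudes depend on unstated billing conventions
  (median-DBH vs per-cohort billing, Year-1 discounting); the engine uses
  per-cohort DBH and end-of-year discounting, and validates cost *orderings*
  (e.g. the control has the lowest cumulative discounted cost) rather than
  dollar totals.
* Warranty replacement of young dead trees is a cost-only event: counts
  decline by the raw survival schedule while replacement charges apply only
  post-warranty.
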
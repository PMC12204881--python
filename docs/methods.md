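# Methods

## Model

`meicost` is a per-patient Monte-Carlo cost model.  One run represents one
patient; a cohort is 10,000 independent runs (the package's study scale).
A run starts from the patient's age at first intervention (`AFI`) and a
fixed life expectancy `LEX = 81` years; the total observation period is
`TOP = LEX − AFI`, an integer between 1 and `LEX − MIA = 76` (`MIA = 5` is
the minimum implantation age).  Costs arise from discrete events —
surgeries, implantations, revisions, processor upgrades, annual check-ups —
scheduled by the run's random durations, and are discounted to present
value at `DIR = 5 %` per year.  Health outcomes (audiometric gain, quality
of life) are outside the model's scope: treatment success within the
modelled durations is assumed comparable across pathways, which is what
makes a pure cost comparison meaningful.

### Age cascade

`AFI` is drawn three times (i.i.d.) from a three-parameter Weibull; the
candidate `round(LEX − AFIa)` falls back to the second and third draw when
it exceeds the upper check (the literal constant 77, kept verbatim from the
original worksheet even though the final clamp is 76) or falls below 1, and
is finally floored at 1 and clamped at `LEX − MIA`.  `round` is
spreadsheet rounding — half away from zero — everywhere in the package.

### Pathways

**Group 1 (direct implant).**  The first implantation costs `ISB + 3·FOA`
(device plus three outpatient appointments) at year 0.  Device lifetimes
`LTS1..LTS3` are triangular(−3, 0, 400) draws floored at 0; each failure
before `TOP` (at most two) triggers a re-implantation costing `ISB + 2·FOA`
discounted at the event year.  Revision intervals `TTR1..TTR4` are
triangular(−3, 0, 140), at most three revisions at `REV + FOA` each.
Processor upgrades happen every `TAP = round(TTUa + TTUb)` years (6-year
reimbursement minimum plus an exponential extra), at most twelve, costing
`APU` at years `k·TAP`.  Annual check-ups contribute the closed-form
annuity `FOA·((1+d)^(TOP−1) − 1)/((1+d)^(TOP−1)·d)` (its `d → 0` limit is
`FOA·(TOP−1)`).

**Group 2 (surgeries then implant).**  The horizon splits into a surgical
phase `THI = min(round(THIt), TOP, 25)` and an implant phase
`TSB = TOP − THI`.  During `THI`, hearing-improvement surgeries recur when
the cumulative success duration (`DSH` draws, shifted Weibull) stays below
`THI`, capped at six including the initial one; each further surgery costs
`HISk + FOA` at its event year.  The implant is charged (`ISB + 2·FOA`)
at year `THI` — unconditionally, even if `TSB = 0` — and the group-1
event logic then runs over horizon `TSB` with all discount exponents
shifted by `THI`.

**Group 3 (surgeries only).**  The surgery sequence runs over the whole of
`TOP`, capped at fifteen surgeries including the first.

Event years enter discount exponents as `round(t − 0.5)` clamped at 0 (an
event at exactly `t = 0` — possible because the triangular lower bounds are
negative and draws are floored, about 0.7 % of device lifetimes — would
otherwise yield exponent −1).  One `ISB` and one `REV` draw per run are
reused across that run's re-implantations and revisions, mirroring the
original worksheet's symbol reuse; a per-event-draw variant is a declared
configuration stub (`independent_event_costs`) and not modelled.  Two
printed quirks are kept verbatim: the group-2/3 charge condition for the
first follow-up surgery uses the unrounded cumulative duration while later
ones round it first, and the 77-vs-76 upper check above.

### Error and capability metrics

Each capped sequence reports the signed years by which it fails to cover
its horizon, e.g. `EP_NHI_G3 = TOP − Σ DSH1..15`; the share of runs with a
positive value is the pathway's model-error rate, and `max(0, EP_NHI)` is
the run's care gap (years without successful treatment).  A run's
successful years are `TOP − care gap`.  `DR_*` rates are the shares of
runs whose rounded first failure/revision year falls strictly below a
given year; for the triangular inputs these have closed forms (e.g.
`P(first failure < 10) = 1 − 390²/(403·400) ≈ 5.65 %`) used as oracles.

### Input distributions

The sampler is inverse-CDF based; each symbol consumes one uniform from a
per-run `numpy` substream (`SeedSequence(seed).spawn(n)`), so cohorts are
reproducible from one root seed, run `i` of a longer cohort equals run `i`
of a shorter one, and the same run index sees the same draws in every
pathway (common random numbers across groups).  Negative triangular draws
are *not* truncated at sampling time; the model equations floor them.
Closed-form means/SDs for all five families back the validation checks.
Defaults (packaged in `data/default_params.yaml`): see the YAML for the
full parameter set; they are the published inputs of the original analysis
and are not tuning knobs.

## Statistics

* Cohort summaries report mean, sample SD (n−1), median and the casemix
  *cost homogeneity* `mean/(mean + sd)` — chosen because it reproduces the
  original analysis's printed homogeneities exactly; the coefficient is 1
  iff costs are deterministic and falls with dispersion.
* Mean contrasts use Welch's unequal-variance t-test (variances differ
  between pathways by construction); dispersion contrasts use Bonett's
  (2006) test for equality of two standard deviations — a Layard-type
  statistic on the log variance ratio with pooled kurtosis about trimmed
  means (trim `1/(2√(n−4))`).  The small-sample constant correction is
  omitted; all package uses have n in the hundreds or more, and the test's
  type-I error is verified by simulation in the suite.  P-values are
  reported to three significant digits with a `<0.001` floor.
* Cost per successfully treated year is a ratio of sums, `Σ cost / Σ
  successful years`, not a mean of per-run ratios.
* Stratified tables condition on exact equality (`TOP = 10/20/30`;
  pre-implant surgery count 1..5, with level 0 the direct-implant cohort
  and the capped sixth level excluded).  Empty strata are omitted.
* Crossing points between two per-duration cost curves are the first grid
  point at which the sign of the difference changes; no sub-year
  interpolation.  For the per-successful-year comparison the surgery-only
  pathway is stratified by its *successful* years rather than by `TOP`:
  runs the surgery cap cannot cover should not be credited with their
  uncovered years, and this is the stratification under which the
  advantage point of the implant is stable at 14–15 years.

## Treatment strategy

The age-threshold policy routes each run by its remaining lifetime:
surgery-only when `TOP < 14`; direct implant when `TOP > 35`; otherwise one
hearing-improvement surgery, and at the second intervention — the event
year of the first surgery's success duration — a switch to the implant iff
more than 13 years remain at that date.  When the switch happens, the run
is evaluated as group 2 with the surgical phase forced to
`THI = round(DSH1)`, the same rounding that turns `THIt` into `THI` in the
standard group-2 model; when it does not, the run stays group 3.  These two
conventions (decision clock = event year; phase length = rounded duration)
were the open mechanical choices; both follow the model's own conventions
for the corresponding quantity.  Degenerate thresholds reproduce the pure
cohorts exactly under the same seed, which the suite asserts.

## Problem sizes and precision

Cohort-level checks run at the study scale, n = 10,000 — also the scale of
the reference duration-stratified tables, whose ~200–320-run strata carry
Monte-Carlo noise of the same order as the comparison bands, so
like-for-like comparison at that scale is the meaningful one.  The
curve-shape checks (crossing points, surgery-count gradient) instead use
n = 50,000: near the crossing the group-1/group-3 difference curve is
almost flat (roughly −300 €/yr slope against ~500 € stratum noise at the
study scale), and locating its zero needs tighter strata; at 50,000 the
estimate is stable across seeds.  The engine-vs-interpreter agreement check
runs 1,000 runs per group at 10⁻⁹ relative tolerance; sampler moments are
checked on 100,000 draws within four standard errors.

## What the generator emulates — and what it does not

The sampler reproduces the *fitted input distributions* of a real clinical
cohort, not the raw data: passing tests show the pipeline implements this
model exactly and reproduces its published outputs, not that the model
captures any specific patient population.  Real-world features outside the
model: mortality variation (fixed `LEX = 81`), hearing outcomes and
quality of life, hearing-aid provision costs during and after surgical
management, cost inflation or DRG catalogue drift, correlation between a
patient's event durations (all draws are independent), and continuous-time
discounting (costs move in whole-year steps).

## Known limitations

* Lifetime cost is *not* monotone in `TOP` for group 2: a longer horizon
  can push the (unconditionally charged) implant later and shrink its
  present value by more than the added costs.  This follows the original
  equations; the suite contains a characterization test.
* With `TSB = 0` the implant is still charged at the end of life — verbatim
  model behaviour whose real-world counterpart is questionable.
* The group-2 care gap (`max(0, EP_NHI_G2)`) mirrors the group-3
  convention; the original analysis implies but never states it.
* The first-event-year rates use the clamped event year, so a device
  failing at exactly time 0 counts as year 0; the original boundary
  convention may differ marginally (its printed one-year revision rate is
  slightly below the triangular closed form).
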
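# Methods

## The decision problem

Automated departure routing at LaGuardia Airport made a runway-13 departure
route (the "TNNIS climb") a year-round route instead of one used only during
the U.S. Open. The route reduces flight delays but raises day-night average
sound levels above 60 dB over densely populated parts of Queens, NY. The
package compares two policies for the people inside the 60-dB noise contour:

* **limited** route use (the old status quo): delay costs persist, no
  year-round noise exposure;
* **year_round** route use (the current status quo): delay costs avoided,
  noise exposure raises cardiovascular-disease (CVD) and generalized-anxiety
  risks.

Outcomes are lifetime discounted costs (2016 US$, societal perspective:
direct medical plus productivity costs) and quality-adjusted life years
(QALYs) per exposed person, combined into an incremental
cost-effectiveness ratio (ICER) of limited vs. year-round use.

## Delay costs

For each arm *i*, annual operating cost and productivity loss are

    C_i = delay_hours_i x cruise_speed x CASM x seats x flights_i
    P_i = delay_hours_i x wage x seats x flights_i

with delay per delayed flight 45.7 min (limited) vs. 25.3 min (year-round),
204 vs. 12 delayed flights per 5-day observation window annualized by 73
(= 365/5), cruise speed 900 km/h, CASM $0.116 per available seat mile, and
176 seats. All delay time is assigned to the cruise phase (the conservative,
maximum-saving assumption for year-round use).

Two numerical choices are exposed rather than hidden:

* **km-to-mile factor** — with the standard 0.621371 the incremental
  operating cost is $125.29M, 1.4% below the reported $127,040,655; the
  original conversion is unrecoverable, so `calibrate_km_to_mile` can solve
  for the factor (~0.63007) that closes the gap exactly.
* **wage** — the mean traveler wage behind P_i is never reported. The
  default is calibrated from the reported incremental productivity total:
  $19,956,042 over 1.931M incremental person-hours = $10.333/h.
  `mean_hourly_wage` derives a wage from any four-bracket income
  distribution (annual income / 2080 h); the bundled distribution is a
  synthetic stand-in.

Totals divided by the exposed population (83,807 within the 60-dB contour)
give the annual per-person exposure cost of the limited arm,
$1,516 + $238 = $1,754, rounded to whole dollars only at reporting time.

## Cohort model

A three-state annual-cycle Markov cohort ("no prior CVD", "prior CVD",
"dead") starts at age 41 with 35% CVD prevalence and runs to the life-table
terminal age (110). Per cycle and alive state:

* CVD event with probability = age-banded baseline (0.0015 at 35-44 rising
  to 0.0681 at 85+) x 1.965 if prior CVD x 1.14 in the exposed arm;
* anxiety event with probability = 0.18 x 1.66 if prior CVD x 1.79 in the
  exposed arm (memoryless, so anxiety can recur yearly — the single annual
  probability supports no more structure);
* a CVD event is fatal with the case-fatality probability (constant 0.10 in
  the bundled table; configurable or age-specific via the life-table
  column); background mortality applies to everyone; combined death
  probability is `1 - (1 - q_all)(1 - p_event * cf)`;
* event order: incidence first, then death, so fatal events still accrue
  that cycle's event cost and disutility;
* rewards on start-of-cycle occupancy (no half-cycle correction): utility
  1.0 (healthy) or 0.844 (prior CVD), minus 0.283 for the CVD-event
  fraction and 0.16 for the anxiety-only fraction (CVD takes precedence
  when both events fall in one cycle); costs are CVD event costs
  ($23,229 + $12,837), anxiety costs ($2,814 + $313), and the limited arm's
  $1,754 exposure cost on the alive fraction;
* discounting at 3%/yr with the first cycle undiscounted.

CVD costs are charged in event years only; no chronic annual maintenance
cost is modelled (none is reported — see "fidelity" below for what this
implies). Prior-CVD excess all-cause mortality defaults to none
(`prior_cvd_mort_multiplier = 1.0`, exposed).

## Parameter uncertainty

Each stochastic input carries a distribution fitted from its reported
summary: beta by method of moments for probabilities and utilities, gamma
by method of moments for costs, log-normal for relative risks with sigma =
(log CI width)/(2x1.96) and mu at the log-interval midpoint (keeping the
fitted 95% interval exactly at the reported range; for the anxiety-noise
relative risk this puts the sampling median at 1.749 while deterministic
runs use the reported mean 1.79). The anxiety disutility SE (0.04) encodes
the reported 25% coefficient of variation. Parameters are sampled
independently (no correlation structure is reported). The odds-ratio to
relative-risk conversion `RR = OR/(1 - p0 + p0 OR)` is provided as a
utility; the reported RR of 1.79 (consistent with OR 2 at p0 ~ 0.117) is
taken as the operative parameter rather than re-derived, since the original
baseline risk is unstated.

The PSA (default 10,000 draws, seeded, vectorized across draws) shares one
parameter draw between both arms. The acceptability curve counts draws with
positive net monetary benefit `NMB(w) = w dQ - dC`, which handles all four
cost-effectiveness-plane quadrants; cost-saving draws are classified by
dC < 0 and dQ > 0. One-way analyses pin one parameter at each bound of its
range (defaults mirror the published ranges) with everything else at base
case, reporting the sorted ICER pair; rows are ordered by descending
spread. The 65-dB scenario divides the same delay-cost totals by the
(smaller) 65-dB contour population, so it reduces to the base case when
given the 60-dB population; the 65-dB population itself is not published
and must be supplied.

## Synthetic inputs

The cited mortality sources (U.S. life tables, CVD mortality from an
American Heart Association report) are not reproduced in the source
analysis, so the bundled life table is synthetic: Gompertz annual hazard
`a exp(bx)` with b = 0.095 and a = 2.71447e-5 calibrated once so that
undiscounted life expectancy at 41 is 40.0 years (keeping lifetime QALY
magnitudes realistic for a U.S. adult cohort), terminal age 110, and a
constant 0.10 CVD case-fatality column as the concrete, tunable stand-in
for unpublished CVD mortality. The generator emulates adult mortality
curvature; it does not reproduce infant mortality structure, period-table
irregularities, or cause-of-death composition, so absolute lifetime totals
carry the fixture's imprint even where increments are faithful.

`generate_perturbed_inputs` applies seeded multiplicative perturbations
(re-drawn on invariant violations) for property tests.
`generate_microsim_population` replays the cohort engine's hazards
person-by-person; its sample means converge to the cohort trace at the
Monte Carlo rate and serve as an independent oracle for the expected-value
engine (checked at n = 200,000 within 3 standard errors).

## Fidelity to the published results, and what the tests show

The desk-scale quantities reproduce exactly or within the conversion gap:
per-person exposure costs round to $1,516 and $238, and the incremental
operating cost lands within 1.4% of $127,040,655 (exactly, in calibration
mode). Lifetime QALYs (20.09 limited, 19.32 year-round) fall within 15% of
the reported 18.72 and 17.6, and every sign, ordering and dominance
classification matches: limited use costs more and gains health; removing
the anxiety-noise association multiplies the ICER by ~9; raising it to 3.06
drives the ICER to ~$1,800/QALY.

The incremental magnitudes do not reproduce: this implementation gives
dC = $23,960, dQ = 0.77, ICER = $31,051/QALY against the reported $11,288,
1.13 and $10,006/QALY, and the PSA cost-saving fraction is ~4% against the
reported 25%. The gap is structural, not a mortality-fixture artifact: the
reported lifetime cost totals (~$656k per person) exceed anything the
published per-event cost inputs can generate (~$75k here; ~$414k even if
CVD costs are charged chronically per prevalent patient-year, a variant we
evaluated and rejected because it still fails to match totals or increments
while contradicting the reported structure). The reported increments imply
an anxiety-side burden roughly twice what the published parameter table
supports under any coherent reading we tested. The original model is not
available, so this package documents the discrepancy rather than tuning
parameters to mask it; all headline comparisons live in
`tests/test_acceptance.py`, where the irreproducible magnitudes fail
visibly instead of being silently relaxed.

## Problem sizes and numerical notes

Default runs use the full lifetime horizon (70 cycles), 10,000 PSA draws
and a 200,000-person microsimulation for the oracle check; the whole test
suite runs in a few seconds. Occupancy conservation is enforced each cycle
at 1e-12; probabilities are capped at 1 after multiplication; life-table
CSV IO uses round-trip float parsing so write/read cycles are bit-exact;
all randomness flows through seeded `numpy.random.Generator` instances, so
every analysis is bit-reproducible given its seed.

## Limitations

Only CVD and generalized anxiety are modelled (no sleep, cognitive or
air-pollution endpoints); exposure relative risks apply for the whole
lifetime (continuous residence); anxiety recurrence and the CVD death
mechanism are this package's documented choices where the original is
silent; no parameter correlations; no value-of-information analysis.
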
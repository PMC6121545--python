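# noisecea

Cost-effectiveness analysis of aircraft-noise exposure from flight routing,
for health-economics and environmental-health researchers. The case study
built in: LaGuardia Airport's runway-13 departure route (the "TNNIS climb"),
which automation turned from a tennis-tournament exception into a year-round
route, cutting flight delays while pushing day-night sound levels above
60 dB over ~84,000 residents of Queens, NY.

The package weighs those delay savings against the health burden of chronic
noise with a three-state Markov cohort model ("no prior CVD" / "prior CVD" /
"dead", annual cycles, cohort age 41 to 110). Noise exposure multiplies the
age-banded cardiovascular event risk by 1.14 and the annual
generalized-anxiety risk by 1.79; events carry costs and utility decrements;
flight delays are priced by

    C_i = DELAY_i x SPEED x CASM x SEAT x FLIGHT_i      (operating cost)
    P_i = DELAY_i x WAGE x SEAT x FLIGHT_i              (productivity loss)

per arm *i* (limited vs. year-round route use). Lifetime discounted costs
and QALYs per exposed person feed the incremental cost-effectiveness ratio

    ICER = (C_limited - C_year_round) / (Q_limited - Q_year_round),

with probabilistic sensitivity analysis (beta/gamma/log-normal parameter
distributions, net-monetary-benefit acceptability curve), one-way tornado
analysis, and a 65-dB-contour scenario. Because the original mortality
inputs are unpublished, a synthetic Gompertz life table (life expectancy
40 y at age 41) is bundled, and a person-level microsimulation oracle
validates the cohort engine.

## Worked example

```python
from noisecea import NoiseExposureCEA

model = NoiseExposureCEA.default()   # bundled parameters + life table
print(model.fit().summary())
```

```
Noise-exposure cost-effectiveness: base case
============================================================
Arm                         Cost ($)       QALYs
limited                       75,302       20.09
year_round                    51,342       19.32
------------------------------------------------------------
Incremental cost   : $23,960
Incremental QALYs  : 0.77
ICER               : $31,051/QALY
```

Limiting route use costs $23,960 more per exposed person over a lifetime
(delay costs outweigh the avoided CVD/anxiety care) but yields 0.77 extra
QALYs, i.e. $31,051 per QALY gained — well under conventional $50,000 to
$100,000 willingness-to-pay thresholds, so restricting the route is
cost-effective under these inputs. Parameter uncertainty:

```python
psa = model.fit_psa(n_draws=10_000, seed=0)
print(psa.summary())
```

```
Noise-exposure cost-effectiveness: probabilistic analysis
============================================================
Draws                         : 10000
Seed                          : 0
P(cost-saving)                : 3.9%
P(ICER < $100,000/QALY)       : 86.7%
CEAC at $0/QALY               : 3.9%
CEAC at $50,000/QALY          : 65.4%
CEAC at $100,000/QALY         : 86.7%
```

`model.fit_owsa()` returns the tornado table (the anxiety-noise relative
risk dominates: pinning it at 1.0 vs. 3.06 moves the ICER from ~$280,000 to
~$1,800 per QALY), and `model.fit_scenario(population_65)` re-runs the model
with the delay totals spread over a 65-dB contour population. The same
analyses are available from the shell:

```sh
noisecea base --out out/
noisecea psa --draws 10000 --seed 0 --plots --out out/
noisecea owsa --out out/
noisecea gen-fixtures --out fixtures/
```

See `docs/methods.md` for the model mechanics, every default and
calibration, and a frank account of which published quantities this
reimplementation does and does not reproduce.

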
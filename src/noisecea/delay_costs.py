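"""Flight-delay cost equations.

Two departure-route policies are compared at LaGuardia: limited use of the
TNNIS climb (delays concentrate at nearby airports) versus year-round use
(fewer delays, more ground-level noise).  Annual delay costs per arm come
from two products over the delayed flights of that arm:

* operating cost  C_i = delay_hours * cruise_speed * CASM * seats * flights_i
  (delay distance priced at the airline cost per available seat mile), and
* productivity loss  P_i = delay_hours * wage * seats * flights_i
  (passenger time priced at a mean traveler wage).

Flight counts observed over a 5-day route test are annualized by a factor of
73 (= 365/5).  Totals divided by the noise-exposed population give the
annual per-person exposure cost carried by the Markov model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "DelayScenario",
    "IncomeDistribution",
    "IncomeBracket",
    "annual_delayed_flights",
    "operating_cost_annual",
    "productivity_loss_annual",
    "mean_hourly_wage",
    "per_person",
    "incremental_operating_cost",
    "incremental_productivity_loss",
    "calibrate_km_to_mile",
    "calibrate_hourly_wage",
    "default_scenarios",
    "default_income_distribution",
    "KM_TO_MILE",
    "CALIBRATED_HOURLY_WAGE",
]

#: statute miles per kilometre
KM_TO_MILE = 0.621371

#: mean traveler wage implied by the published incremental productivity-loss
#: total over the incremental delay person-hours of the route test
CALIBRATED_HOURLY_WAGE = 19_956_042.0 / (
    (45.7 / 60.0 * 176 * 204 * 73) - (25.3 / 60.0 * 176 * 12 * 73)
)


@dataclass(frozen=True)
class DelayScenario:
    """Delay inputs for one comparison arm."""

    label: str
    delay_min: float  # minutes per delayed flight
    delayed_per_5day: float  # delayed flights per 5-day observation window
    annualization: float = 73.0
    speed_kmh: float = 900.0
    casm_usd_per_seat_mile: float = 0.116
    seats: float = 176.0
    km_to_mile: float = KM_TO_MILE
    hourly_wage_usd: float | None = CALIBRATED_HOURLY_WAGE
    population: int = 83_807

    def __post_init__(self) -> None:
        for name in (
            "delay_min",
            "annualization",
            "speed_kmh",
            "casm_usd_per_seat_mile",
            "seats",
            "population",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.delayed_per_5day < 0:
            raise ValueError("delayed_per_5day must be >= 0")
        if not 0.6 < self.km_to_mile < 0.65:
            raise ValueError(
                f"km_to_mile={self.km_to_mile} outside the plausible (0.6, 0.65)"
            )


@dataclass(frozen=True)
class IncomeBracket:
    label: str
    share: float
    mean_annual_income: float


@dataclass(frozen=True)
class IncomeDistribution:
    """Traveler income shares over four brackets (<25K ... >=100K)."""

    brackets: tuple[IncomeBracket, ...]

    def __post_init__(self) -> None:
        total = sum(b.share for b in self.brackets)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"income shares sum to {total}, not 1")
        incomes = [b.mean_annual_income for b in self.brackets]
        if any(x <= 0 for x in incomes):
            raise ValueError("incomes must be positive")
        if any(lo >= hi for lo, hi in zip(incomes, incomes[1:])):
            raise ValueError("bracket incomes must increase")

    @property
    def mean_annual_income(self) -> float:
        return sum(b.share * b.mean_annual_income for b in self.brackets)


def annual_delayed_flights(scenario: DelayScenario) -> float:
    """Delayed flights per year: 5-day count times the annualization factor."""
    return scenario.delayed_per_5day * scenario.annualization


def operating_cost_annual(scenario: DelayScenario) -> float:
    """Annual airline operating cost of delays ($/year).

    Delay time is assumed to accrue in the cruise phase, so the delay
    distance is ``delay_hours * cruise_speed`` (converted to statute miles)
    priced at CASM per seat over all seats and delayed flights.
    """
    delay_hours = scenario.delay_min / 60.0
    delay_miles = delay_hours * scenario.speed_kmh * scenario.km_to_mile
    return (
        delay_miles
        * scenario.casm_usd_per_seat_mile
        * scenario.seats
        * annual_delayed_flights(scenario)
    )


def productivity_loss_annual(scenario: DelayScenario) -> float:
    """Annual passenger productivity loss of delays ($/year)."""
    if scenario.hourly_wage_usd is None:
        raise ValueError(f"scenario {scenario.label!r}: hourly wage is unset")
    delay_hours = scenario.delay_min / 60.0
    return (
        delay_hours
        * scenario.hourly_wage_usd
        * scenario.seats
        * annual_delayed_flights(scenario)
    )


def mean_hourly_wage(dist: IncomeDistribution, hours_per_year: float = 2080.0) -> float:
    """Share-weighted mean annual income divided by annual work hours."""
    if hours_per_year <= 0:
        raise ValueError("hours_per_year must be > 0")
    return dist.mean_annual_income / hours_per_year


def per_person(total: float, population: int) -> float:
    """Annual total converted to a per-exposed-person amount."""
    if population <= 0:
        raise ValueError("population must be > 0")
    return total / population


def incremental_operating_cost(limited: DelayScenario, year_round: DelayScenario) -> float:
    return operating_cost_annual(limited) - operating_cost_annual(year_round)


def incremental_productivity_loss(
    limited: DelayScenario, year_round: DelayScenario
) -> float:
    return productivity_loss_annual(limited) - productivity_loss_annual(year_round)


def calibrate_km_to_mile(
    limited: DelayScenario, year_round: DelayScenario, target_incremental: float
) -> float:
    """Unit-conversion factor that reproduces a target incremental operating cost.

    The operating-cost equation is linear in the km->mile factor, so the
    calibrated factor is the current factor scaled by the ratio of the target
    to the currently implied incremental total.
    """
    current = incremental_operating_cost(limited, year_round)
    if current == 0.0:
        raise ValueError("incremental operating cost is zero; cannot calibrate")
    return limited.km_to_mile * target_incremental / current


def calibrate_hourly_wage(
    limited: DelayScenario, year_round: DelayScenario, target_incremental: float
) -> float:
    """Hourly wage that reproduces a target incremental productivity loss."""
    hours = (
        limited.delay_min / 60.0 * limited.seats * annual_delayed_flights(limited)
        - year_round.delay_min
        / 60.0
        * year_round.seats
        * annual_delayed_flights(year_round)
    )
    if hours == 0.0:
        raise ValueError("incremental delay person-hours are zero; cannot calibrate")
    return target_incremental / hours


def default_scenarios(
    km_to_mile: float = KM_TO_MILE,
    hourly_wage_usd: float | None = CALIBRATED_HOURLY_WAGE,
) -> tuple[DelayScenario, DelayScenario]:
    """The (limited, year_round) arms of the 5-day route test."""
    limited = DelayScenario(
        "limited",
        delay_min=45.7,
        delayed_per_5day=204,
        km_to_mile=km_to_mile,
        hourly_wage_usd=hourly_wage_usd,
    )
    year_round = replace(limited, label="year_round", delay_min=25.3, delayed_per_5day=12)
    return limited, year_round


def default_income_distribution() -> IncomeDistribution:
    """Synthetic four-bracket traveler income distribution.

    A stand-in with plausible air-traveler shares and bracket means; the
    pipeline's default wage is instead calibrated to the published
    productivity-loss total (see :data:`CALIBRATED_HOURLY_WAGE`).
    """
    return IncomeDistribution(
        (
            IncomeBracket("<25K", 0.13, 15_600.0),
            IncomeBracket("25-<50K", 0.21, 37_000.0),
            IncomeBracket("50-<100K", 0.35, 72_000.0),
            IncomeBracket(">=100K", 0.31, 151_000.0),
        )
    )
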
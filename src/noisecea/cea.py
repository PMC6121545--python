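"""Cost-effectiveness analysis layer.

Base-case ICER with dominance classification, probabilistic sensitivity
analysis (PSA) over the parameter distributions, the cost-effectiveness
acceptability curve (CEAC) computed from net monetary benefit, one-way
(tornado) sensitivity analysis, and the 65-dB noise-contour scenario.

Throughout, the *reference* strategy is the limited use of the departure
route (higher delay costs, no noise exposure) and the *comparator* its
year-round use; incremental quantities are reference minus comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .markov import arms_from_params, cohort_totals_vectorized, run_cohort
from .params import ParameterSet, draw_parameter_arrays

__all__ = [
    "ArmTotals",
    "CEAResult",
    "PSAResult",
    "TornadoRow",
    "icer",
    "base_case",
    "run_psa",
    "ceac",
    "one_way",
    "tornado",
    "scenario_65db",
    "DEFAULT_WTP_GRID",
    "DEFAULT_OWSA_RANGES",
]

#: default willingness-to-pay grid, $0 to $200,000/QALY in $1,000 steps
DEFAULT_WTP_GRID = np.arange(0, 200_001, 1_000)

#: one-way ranges for the core model inputs (parameter -> (low, high))
DEFAULT_OWSA_RANGES: dict[str, tuple[float, float]] = {
    "rr_anx_noise": (1.00, 3.06),
    "p_anxiety_base": (0.08, 0.28),
    "exposure_op_cost_pp": (1137.0, 1895.0),
    "disutil_anxiety": (0.06, 0.26),
    "rr_cvd_noise": (1.00, 1.18),
    "cost_anx_direct": (2111.0, 3518.0),
    "cost_cvd_direct": (17_422.0, 29_036.0),
    "rr_anx_cvd": (1.49, 1.82),
    "cvd_prevalence_init": (0.25, 0.45),
    "start_age": (31, 51),
    "exposure_prod_loss_pp": (178.5, 297.5),
    "cost_cvd_indirect": (9628.0, 16_046.0),
    "disutil_cvd_event": (0.18, 0.38),
    "u_prior_cvd": (0.74, 0.94),
    "cost_anx_indirect": (235.0, 391.0),
    "rr_cvd_prior": (1.70, 2.30),
    "discount_rate": (0.00, 0.05),
}


@dataclass(frozen=True)
class ArmTotals:
    label: str
    cost: float
    qalys: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of two strategies."""

    reference: ArmTotals
    comparator: ArmTotals

    @property
    def incremental_cost(self) -> float:
        return self.reference.cost - self.comparator.cost

    @property
    def incremental_qalys(self) -> float:
        return self.reference.qalys - self.comparator.qalys

    @property
    def dominance(self) -> str:
        dc, dq = self.incremental_cost, self.incremental_qalys
        if dc < 0.0 and dq > 0.0:
            return "dominant"
        if dc > 0.0 and dq < 0.0:
            return "dominated"
        if dq == 0.0:
            return "dominated" if dc > 0 else ("dominant" if dc < 0 else "equivalent")
        return "tradeoff"

    @property
    def icer(self) -> float:
        """Incremental cost per incremental QALY.

        Only meaningful for the ``tradeoff`` class; for dominance the raw
        (negative) ratio is still exposed for table comparability, and NaN is
        returned when the QALY increment is exactly zero.
        """
        if self.incremental_qalys == 0.0:
            return math.nan
        return self.incremental_cost / self.incremental_qalys


def icer(reference: ArmTotals, comparator: ArmTotals) -> CEAResult:
    for tot in (reference, comparator):
        if not (math.isfinite(tot.cost) and math.isfinite(tot.qalys)):
            raise ValueError(f"non-finite totals for arm {tot.label!r}")
    return CEAResult(reference, comparator)


def base_case(
    params: ParameterSet, table: LifeTable, horizon: int | None = None
) -> tuple[CEAResult, dict]:
    """Deterministic run of both arms at the base-case parameter values.

    Returns the incremental result plus the two traces keyed by arm label.
    """
    limited, year_round = arms_from_params(params)
    traces = {
        arm.label: run_cohort(params, arm, table, horizon=horizon)
        for arm in (limited, year_round)
    }
    totals = {
        label: ArmTotals(label, tr.total_cost, tr.total_qalys)
        for label, tr in traces.items()
    }
    return icer(totals["limited"], totals["year_round"]), traces


class PSAResult:
    """Monte Carlo draws of the incremental cost and QALYs.

    ``samples`` holds one row per draw with per-arm totals and increments;
    ``nmb(wtp)`` and ``ceac(grid)`` derive net-monetary-benefit quantities.
    """

    def __init__(self, samples: pd.DataFrame, seed: int):
        self.samples = samples
        self.seed = seed

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def nmb(self, wtp: float) -> np.ndarray:
        return (
            wtp * self.samples["dqalys"].to_numpy()
            - self.samples["dcost"].to_numpy()
        )

    def prob_cost_saving(self) -> float:
        s = self.samples
        return float(((s["dcost"] < 0) & (s["dqalys"] > 0)).mean())

    def prob_icer_below(self, wtp: float) -> float:
        """Fraction of draws whose ICER falls below ``wtp``.

        Dominant draws (more health for less money) count as below any
        threshold; dominated draws never do; trade-off draws compare the
        ratio.
        """
        dc = self.samples["dcost"].to_numpy()
        dq = self.samples["dqalys"].to_numpy()
        dominant = (dc < 0) & (dq > 0)
        dominated = (dc >= 0) & (dq <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_ok = np.where(dq > 0, dc < wtp * dq, False)
        return float((dominant | (~dominated & ratio_ok)).mean())

    def ceac(self, wtp_grid=DEFAULT_WTP_GRID) -> pd.DataFrame:
        return ceac(self, wtp_grid)


def run_psa(
    params: ParameterSet,
    table: LifeTable,
    n_draws: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each draw samples one shared parameter vector from the distributions in
    ``params`` and evaluates both arms on it; results are reproducible given
    the seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = draw_parameter_arrays(params, n_draws, rng)
    cost_lim, q_lim = cohort_totals_vectorized(draws, params, table, exposed=False)
    cost_yr, q_yr = cohort_totals_vectorized(draws, params, table, exposed=True)
    samples = pd.DataFrame(
        {
            "draw": np.arange(n_draws),
            "cost_limited": cost_lim,
            "qalys_limited": q_lim,
            "cost_year_round": cost_yr,
            "qalys_year_round": q_yr,
            "dcost": cost_lim - cost_yr,
            "dqalys": q_lim - q_yr,
        }
    )
    return PSAResult(samples, seed)


def ceac(psa: PSAResult, wtp_grid=DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Probability the reference arm is cost-effective at each WTP value.

    A draw counts as cost-effective at willingness-to-pay ``w`` when its net
    monetary benefit ``w * dQALY - dCost`` is positive, which handles all
    four cost-effectiveness-plane quadrants.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("the willingness-to-pay grid is empty")
    if psa.n_draws == 0:
        raise ValueError("no PSA samples")
    dq = psa.samples["dqalys"].to_numpy()
    dc = psa.samples["dcost"].to_numpy()
    prob = [(w * dq - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": prob})


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low_value: float
    high_value: float
    icer_min: float
    icer_max: float
    result_at_low: CEAResult
    result_at_high: CEAResult

    @property
    def spread(self) -> float:
        return abs(self.icer_max - self.icer_min)


def _pin(params: ParameterSet, name: str, value) -> ParameterSet:
    if name == "start_age":
        return params.replace(start_age=int(value))
    if not hasattr(params, name):
        raise ValueError(f"unknown parameter {name!r}")
    return params.replace(**{name: value})


def one_way(
    params: ParameterSet,
    table: LifeTable,
    name: str,
    low: float,
    high: float,
) -> TornadoRow:
    """Two deterministic runs with one parameter pinned at each bound.

    The reported ICER pair is sorted ascending; it need not follow the
    parameter's own low/high order.
    """
    if low > high:
        raise ValueError(f"one-way range for {name!r} has low > high")
    res_low, _ = base_case(_pin(params, name, low), table)
    res_high, _ = base_case(_pin(params, name, high), table)
    icer_lo, icer_hi = sorted([res_low.icer, res_high.icer])
    return TornadoRow(name, low, high, icer_lo, icer_hi, res_low, res_high)


def tornado(
    params: ParameterSet,
    table: LifeTable,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One-way analysis over many parameters, widest ICER spread first."""
    if ranges is None:
        ranges = DEFAULT_OWSA_RANGES
    rows = [one_way(params, table, name, lo, hi) for name, (lo, hi) in ranges.items()]
    rows.sort(key=lambda r: r.spread, reverse=True)
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "low_value": [r.low_value for r in rows],
            "high_value": [r.high_value for r in rows],
            "icer_min": [r.icer_min for r in rows],
            "icer_max": [r.icer_max for r in rows],
            "spread": [r.spread for r in rows],
        }
    )


def scenario_65db(
    params: ParameterSet,
    table: LifeTable,
    population_65: int,
    total_operating: float | None = None,
    total_productivity: float | None = None,
) -> CEAResult:
    """Restrict the exposed population to the 65-dB noise contour.

    The same incremental delay-cost totals are spread over the (smaller)
    65-dB population, raising the per-person exposure cost; the health model
    is unchanged.  By default the totals are the ones implied by the base
    case (per-person exposure costs times the 60-dB population), so setting
    ``population_65`` equal to the 60-dB population reproduces the base case
    exactly.
    """
    if population_65 <= 0:
        raise ValueError("population_65 must be > 0")
    if total_operating is None:
        total_operating = params.exposure_op_cost_pp * params.population_60db
    if total_productivity is None:
        total_productivity = params.exposure_prod_loss_pp * params.population_60db
    op_pp = total_operating / population_65
    prod_pp = total_productivity / population_65
    scen = params.replace(
        exposure_op_cost_pp=op_pp,
        exposure_prod_loss_pp=prod_pp,
        population_65db=population_65,
    )
    result, _ = base_case(scen, table)
    return result
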
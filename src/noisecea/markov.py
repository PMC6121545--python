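"""Three-state annual-cycle Markov cohort engine.

States: ``no_prior_cvd`` -> ``prior_cvd`` -> ``dead``.  Each one-year cycle a
member of an alive state may suffer a cardiovascular (CVD) event (annual
probability from an age-banded baseline, multiplied by a prior-disease
relative risk and, in the noise-exposed arm, the noise relative risk) and,
independently, an anxiety-disorder event (baseline probability with its own
prior-CVD and noise multipliers).  A CVD event is fatal with the age-specific
case-fatality probability; background all-cause mortality applies to
everyone; the combined death probability is
``1 - (1 - q_background)(1 - p_event * case_fatality)``.

Rewards accrue on start-of-cycle occupancy (no half-cycle correction, so the
fatal fraction still collects that cycle's event cost and disutility):
utility is the state utility minus the CVD event decrement for the event
fraction and the anxiety decrement for the anxiety-only fraction (CVD takes
precedence when both events fall in one cycle); costs are CVD event costs,
anxiety costs, and the arm's annual per-person exposure (delay) cost on the
alive fraction.  Costs and QALYs are discounted at the annual rate with the
first cycle undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .params import ParameterSet

__all__ = [
    "ArmSpec",
    "CycleRecord",
    "MarkovTrace",
    "arms_from_params",
    "cvd_event_prob",
    "anxiety_event_prob",
    "run_cohort",
    "discounted_totals",
]

_OCC_TOL = 1e-12


@dataclass(frozen=True)
class ArmSpec:
    """Exposure multipliers and exposure cost of one comparison arm."""

    label: str
    rr_cvd_exposure: float = 1.0
    rr_anx_exposure: float = 1.0
    annual_exposure_cost_pp: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_cvd_exposure <= 0 or self.rr_anx_exposure <= 0:
            raise ValueError("exposure relative risks must be > 0")
        if self.annual_exposure_cost_pp < 0:
            raise ValueError("exposure cost must be >= 0")


def arms_from_params(params: ParameterSet) -> tuple[ArmSpec, ArmSpec]:
    """Build the (limited, year_round) arms.

    The limited arm carries the annual per-person delay cost and no noise
    risk; the year-round arm carries the noise relative risks and no delay
    cost.
    """
    limited = ArmSpec("limited", 1.0, 1.0, params.exposure_cost_pp)
    year_round = ArmSpec(
        "year_round", params.rr_cvd_noise, params.rr_anx_noise, 0.0
    )
    return limited, year_round


def cvd_event_prob(
    age: float, has_prior: bool, arm: ArmSpec, params: ParameterSet
) -> float:
    """Annual CVD event probability for one state in one arm, capped at 1."""
    base = params.cvd_risk.probability(age)
    rr = (params.rr_cvd_prior if has_prior else 1.0) * arm.rr_cvd_exposure
    return min(1.0, base * rr)


def anxiety_event_prob(
    has_prior_cvd: bool, arm: ArmSpec, params: ParameterSet
) -> float:
    """Annual anxiety-disorder event probability, capped at 1."""
    rr = (params.rr_anx_cvd if has_prior_cvd else 1.0) * arm.rr_anx_exposure
    return min(1.0, params.p_anxiety_base * rr)


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    age: int
    occ_no_prior: float
    occ_prior: float
    occ_dead: float
    cvd_events: float
    anxiety_events: float
    cost: float
    cost_discounted: float
    qalys: float
    qalys_discounted: float


@dataclass
class MarkovTrace:
    """Per-cycle occupancy, events and rewards for one arm."""

    arm: str
    records: list[CycleRecord] = field(default_factory=list)

    @property
    def total_cost(self) -> float:
        return sum(r.cost_discounted for r in self.records)

    @property
    def total_qalys(self) -> float:
        return sum(r.qalys_discounted for r in self.records)

    @property
    def total_cost_undiscounted(self) -> float:
        return sum(r.cost for r in self.records)

    @property
    def total_qalys_undiscounted(self) -> float:
        return sum(r.qalys for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def run_cohort(
    params: ParameterSet,
    arm: ArmSpec,
    table: LifeTable,
    horizon: int | None = None,
) -> MarkovTrace:
    """Run the cohort from the start age to the life-table terminal age.

    ``horizon`` (cycles) may truncate the run; by default the cohort is
    followed until the terminal age, where the whole cohort dies.
    """
    start = params.start_age
    if start < table.min_age:
        raise ValueError(
            f"start age {start} below life-table coverage ({table.min_age}+)"
        )
    if horizon is None:
        horizon = table.max_age - start + 1
    if horizon < 0:
        raise ValueError("horizon must be >= 0")

    c_cvd = params.cost_cvd_direct + params.cost_cvd_indirect
    c_anx = params.cost_anx_direct + params.cost_anx_indirect
    r = params.discount_rate

    n, p, d = 1.0 - params.cvd_prevalence_init, params.cvd_prevalence_init, 0.0
    trace = MarkovTrace(arm.label)
    for t in range(horizon):
        age = start + t
        q_all = table.mortality_at(age)
        cf = (
            params.cvd_case_fatality
            if params.cvd_case_fatality is not None
            else table.case_fatality_at(age)
        )
        pc_n = cvd_event_prob(age, False, arm, params)
        pc_p = cvd_event_prob(age, True, arm, params)
        pa_n = anxiety_event_prob(False, arm, params)
        pa_p = anxiety_event_prob(True, arm, params)

        alive = n + p
        cvd_events = n * pc_n + p * pc_p
        anx_events = n * pa_n + p * pa_p
        anx_only = n * pa_n * (1.0 - pc_n) + p * pa_p * (1.0 - pc_p)
        qalys = (
            n * params.u_no_cvd
            + p * params.u_prior_cvd
            - cvd_events * params.disutil_cvd_event
            - anx_only * params.disutil_anxiety
        )
        cost = (
            cvd_events * c_cvd
            + anx_events * c_anx
            + alive * arm.annual_exposure_cost_pp
        )
        df = (1.0 + r) ** (-t)
        trace.records.append(
            CycleRecord(
                cycle=t,
                age=age,
                occ_no_prior=n,
                occ_prior=p,
                occ_dead=d,
                cvd_events=cvd_events,
                anxiety_events=anx_events,
                cost=cost,
                cost_discounted=cost * df,
                qalys=qalys,
                qalys_discounted=qalys * df,
            )
        )

        qb_n = q_all
        qb_p = min(1.0, q_all * params.prior_cvd_mort_multiplier)
        die_n = pc_n * cf + (1.0 - pc_n * cf) * qb_n
        die_p = pc_p * cf + (1.0 - pc_p * cf) * qb_p
        n_next = n * (1.0 - pc_n) * (1.0 - qb_n)
        p_next = n * pc_n * (1.0 - cf) * (1.0 - qb_n) + p * (1.0 - die_p)
        d_next = d + n * die_n + p * die_p
        if abs(n_next + p_next + d_next - 1.0) > _OCC_TOL:
            raise RuntimeError(
                f"occupancy not conserved at cycle {t} "
                f"(sum={n_next + p_next + d_next!r})"
            )
        if d_next < d - _OCC_TOL:
            raise RuntimeError(f"dead occupancy decreased at cycle {t}")
        n, p, d = n_next, p_next, d_next
    return trace


def discounted_totals(trace: MarkovTrace) -> tuple[float, float]:
    """(discounted lifetime cost, discounted lifetime QALYs) of a trace."""
    return trace.total_cost, trace.total_qalys


# ---------------------------------------------------------------------------
# vectorized totals across parameter draws (probabilistic analysis fast path)


def cohort_totals_vectorized(
    draws: dict[str, np.ndarray],
    params: ParameterSet,
    table: LifeTable,
    exposed: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Discounted (costs, QALYs) arrays for many parameter draws at once.

    ``draws`` comes from :func:`noisecea.params.draw_parameter_arrays`.
    ``exposed=False`` is the limited arm (delay cost, no noise risk);
    ``exposed=True`` the year-round arm.  Non-sampled settings (start age,
    discount rate, initial prevalence, case fatality, healthy utility) are
    taken from ``params``.  The stepping mechanics mirror
    :func:`run_cohort` exactly.
    """
    n_draws = draws["p_anxiety_base"].size
    band = draws["cvd_band_probs"]
    rr_cvd_exp = draws["rr_cvd_noise"] if exposed else 1.0
    rr_anx_exp = draws["rr_anx_noise"] if exposed else 1.0
    exp_cost = (
        0.0
        if exposed
        else draws["exposure_op_cost_pp"] + draws["exposure_prod_loss_pp"]
    )
    c_cvd = draws["cost_cvd_direct"] + draws["cost_cvd_indirect"]
    c_anx = draws["cost_anx_direct"] + draws["cost_anx_indirect"]
    u_prior = draws["u_prior_cvd"]
    du_cvd = draws["disutil_cvd_event"]
    du_anx = draws["disutil_anxiety"]
    p_anx = draws["p_anxiety_base"]
    rr_prior = draws["rr_cvd_prior"]
    rr_anx_cvd = draws["rr_anx_cvd"]

    start = params.start_age
    horizon = table.max_age - start + 1
    r = params.discount_rate
    ones = np.ones(n_draws)
    n = (1.0 - params.cvd_prevalence_init) * ones
    p = params.cvd_prevalence_init * ones
    cost_tot = np.zeros(n_draws)
    qaly_tot = np.zeros(n_draws)
    for t in range(horizon):
        age = start + t
        q_all = table.mortality_at(age)
        cf = (
            params.cvd_case_fatality
            if params.cvd_case_fatality is not None
            else table.case_fatality_at(age)
        )
        base = band[:, params.cvd_risk.band_index(age)]
        pc_n = np.minimum(1.0, base * rr_cvd_exp)
        pc_p = np.minimum(1.0, base * rr_prior * rr_cvd_exp)
        pa_n = np.minimum(1.0, p_anx * rr_anx_exp)
        pa_p = np.minimum(1.0, p_anx * rr_anx_cvd * rr_anx_exp)

        cvd_events = n * pc_n + p * pc_p
        anx_events = n * pa_n + p * pa_p
        anx_only = n * pa_n * (1.0 - pc_n) + p * pa_p * (1.0 - pc_p)
        df = (1.0 + r) ** (-t)
        qaly_tot += df * (
            n * params.u_no_cvd
            + p * u_prior
            - cvd_events * du_cvd
            - anx_only * du_anx
        )
        cost_tot += df * (
            cvd_events * c_cvd + anx_events * c_anx + (n + p) * exp_cost
        )

        qb_p = min(1.0, q_all * params.prior_cvd_mort_multiplier)
        die_p = pc_p * cf + (1.0 - pc_p * cf) * qb_p
        n_new = n * (1.0 - pc_n) * (1.0 - q_all)
        p_new = n * pc_n * (1.0 - cf) * (1.0 - q_all) + p * (1.0 - die_p)
        n, p = n_new, p_new
    return cost_tot, qaly_tot
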
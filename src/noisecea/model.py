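"""Model facade: build once, then fit base case, PSA, tornado or scenario.

Follows the model/results idiom of statistical modelling packages: a
:class:`NoiseExposureCEA` is constructed from its inputs (parameter set,
life table, delay scenarios); ``fit()`` evaluates the deterministic base
case and returns a results object with the estimates, a ``summary()`` table
and the per-cycle traces; ``fit_psa`` / ``fit_owsa`` / ``fit_scenario``
return results objects for the probabilistic, one-way and 65-dB analyses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cea, delay_costs
from .cea import CEAResult, PSAResult
from .life_tables import LifeTable, load_life_table
from .markov import MarkovTrace
from .params import ParameterSet, load_parameters

__all__ = ["NoiseExposureCEA", "BaseCaseResults", "PSAResults", "TornadoResults"]


def _fmt_money(x: float) -> str:
    return f"{x:,.0f}"


class NoiseExposureCEA:
    """Cost-effectiveness model of limited vs. year-round route use.

    Parameters
    ----------
    params : ParameterSet
        Model inputs (risks, relative risks, costs, utilities, settings).
    life_table : LifeTable
        Background mortality (and optional CVD case fatality) by age.
    scenarios : (DelayScenario, DelayScenario), optional
        The (limited, year_round) flight-delay arms; defaults to the 5-day
        route-test inputs.
    """

    def __init__(self, params: ParameterSet, life_table: LifeTable, scenarios=None):
        self.params = params
        self.life_table = life_table
        if scenarios is None:
            scenarios = delay_costs.default_scenarios()
        self.scenario_limited, self.scenario_year_round = scenarios

    @classmethod
    def from_files(cls, params_path, life_table_path) -> "NoiseExposureCEA":
        return cls(load_parameters(params_path), load_life_table(life_table_path))

    @classmethod
    def default(cls) -> "NoiseExposureCEA":
        from .synthetic import generate_reference_inputs

        truth = generate_reference_inputs()
        return cls(truth.params, truth.life_table)

    def fit(self, horizon: int | None = None) -> "BaseCaseResults":
        """Deterministic base-case evaluation of both arms."""
        result, traces = cea.base_case(self.params, self.life_table, horizon=horizon)
        return BaseCaseResults(self, result, traces)

    def fit_psa(self, n_draws: int = 10_000, seed: int = 0) -> "PSAResults":
        """Probabilistic sensitivity analysis with ``n_draws`` Monte Carlo draws."""
        psa = cea.run_psa(self.params, self.life_table, n_draws=n_draws, seed=seed)
        return PSAResults(self, psa)

    def fit_owsa(self, ranges: dict | None = None) -> "TornadoResults":
        """One-way (tornado) sensitivity analysis over ``ranges``."""
        base = self.fit()
        table = cea.tornado(self.params, self.life_table, ranges)
        return TornadoResults(self, table, base.result.icer)

    def fit_scenario(self, population_65: int) -> "BaseCaseResults":
        """65-dB contour scenario: delay totals spread over a smaller population."""
        if population_65 <= 0:
            raise ValueError("population_65 must be > 0")
        scen_params = self.params.replace(
            population_65db=population_65,
            exposure_op_cost_pp=self.params.exposure_op_cost_pp
            * self.params.population_60db
            / population_65,
            exposure_prod_loss_pp=self.params.exposure_prod_loss_pp
            * self.params.population_60db
            / population_65,
        )
        res, traces = cea.base_case(scen_params, self.life_table)
        return BaseCaseResults(self, res, traces)


@dataclass
class BaseCaseResults:
    """Deterministic lifetime totals, increments and ICER."""

    model: NoiseExposureCEA
    result: CEAResult
    traces: dict[str, MarkovTrace]

    @property
    def icer(self) -> float:
        return self.result.icer

    @property
    def incremental_cost(self) -> float:
        return self.result.incremental_cost

    @property
    def incremental_qalys(self) -> float:
        return self.result.incremental_qalys

    def arm_frame(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            {
                "arm": [r.reference.label, r.comparator.label],
                "cost": [r.reference.cost, r.comparator.cost],
                "qalys": [r.reference.qalys, r.comparator.qalys],
            }
        )

    def summary(self) -> str:
        r = self.result
        buf = io.StringIO()
        w = buf.write
        w("Noise-exposure cost-effectiveness: base case\n")
        w("=" * 60 + "\n")
        w(f"{'Arm':<22}{'Cost ($)':>14}{'QALYs':>12}\n")
        for tot in (r.reference, r.comparator):
            w(f"{tot.label:<22}{_fmt_money(tot.cost):>14}{tot.qalys:>12.2f}\n")
        w("-" * 60 + "\n")
        w(f"Incremental cost   : ${_fmt_money(r.incremental_cost)}\n")
        w(f"Incremental QALYs  : {r.incremental_qalys:.2f}\n")
        if r.dominance == "tradeoff":
            w(f"ICER               : ${_fmt_money(r.icer)}/QALY\n")
        else:
            w(f"Dominance          : {r.dominance} (raw ratio {r.icer:,.0f})\n")
        return buf.getvalue()


@dataclass
class PSAResults:
    """Probabilistic draws with CEAC and cost-effectiveness-plane helpers."""

    model: NoiseExposureCEA
    psa: PSAResult

    @property
    def samples(self) -> pd.DataFrame:
        return self.psa.samples

    def ceac(self, wtp_grid=cea.DEFAULT_WTP_GRID) -> pd.DataFrame:
        return self.psa.ceac(wtp_grid)

    def prob_cost_saving(self) -> float:
        return self.psa.prob_cost_saving()

    def prob_icer_below(self, wtp: float) -> float:
        return self.psa.prob_icer_below(wtp)

    def summary(self) -> str:
        curve = self.ceac(np.array([0.0, 50_000.0, 100_000.0]))
        p0, p50, p100 = curve["prob_cost_effective"]
        lines = [
            "Noise-exposure cost-effectiveness: probabilistic analysis",
            "=" * 60,
            f"Draws                         : {self.psa.n_draws}",
            f"Seed                          : {self.psa.seed}",
            f"P(cost-saving)                : {self.prob_cost_saving():.1%}",
            f"P(ICER < $100,000/QALY)       : {self.prob_icer_below(100_000):.1%}",
            f"CEAC at $0/QALY               : {p0:.1%}",
            f"CEAC at $50,000/QALY          : {p50:.1%}",
            f"CEAC at $100,000/QALY         : {p100:.1%}",
        ]
        return "\n".join(lines) + "\n"

    def plot_ce_plane(self, ax=None):
        """Scatter of the incremental cost/QALY cloud (one point per draw)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        s = self.samples
        ax.scatter(s["dqalys"], s["dcost"], s=4, alpha=0.25, linewidths=0)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("Incremental QALYs (limited - year-round)")
        ax.set_ylabel("Incremental cost ($)")
        ax.set_title("Cost-effectiveness plane")
        return ax

    def plot_ceac(self, wtp_grid=cea.DEFAULT_WTP_GRID, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        curve = self.ceac(wtp_grid)
        ax.plot(curve["wtp"], curve["prob_cost_effective"])
        ax.set_ylim(0, 1)
        ax.set_xlabel("Willingness to pay ($/QALY)")
        ax.set_ylabel("P(limited use cost-effective)")
        ax.set_title("Cost-effectiveness acceptability curve")
        return ax


@dataclass
class TornadoResults:
    """Sorted one-way sensitivity table."""

    model: NoiseExposureCEA
    table: pd.DataFrame
    base_icer: float

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("One-way sensitivity analysis (widest ICER spread first)\n")
        buf.write("=" * 72 + "\n")
        buf.write(f"Base-case ICER: ${self.base_icer:,.0f}/QALY\n\n")
        buf.write(self.table.to_string(index=False, float_format=lambda v: f"{v:,.1f}"))
        buf.write("\n")
        return buf.getvalue()
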
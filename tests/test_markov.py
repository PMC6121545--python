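"""Cohort engine: event probabilities, stepping mechanics, invariants."""

import numpy as np
import pytest

from noisecea.markov import (
    ArmSpec,
    anxiety_event_prob,
    arms_from_params,
    cohort_totals_vectorized,
    cvd_event_prob,
    discounted_totals,
    run_cohort,
)
from noisecea.params import ParameterSet


class TestEventProbabilities:
    def test_base_risk_without_multipliers(self, params, arms):
        limited, _ = arms
        assert cvd_event_prob(50, False, limited, params) == 0.0071

    def test_prior_disease_and_noise_multiply(self, params, arms):
        _, year_round = arms
        expected = 0.0071 * 1.965 * 1.14
        assert cvd_event_prob(50, True, year_round, params) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(0.01590, abs=5e-5)

    def test_unit_multipliers_recover_base_risk(self, params):
        neutral = ArmSpec("neutral", 1.0, 1.0, 0.0)
        for age in (41, 60, 80, 100):
            assert cvd_event_prob(age, False, neutral, params) == (
                params.cvd_risk.probability(age)
            )

    def test_anxiety_probabilities(self, params, arms):
        limited, year_round = arms
        assert anxiety_event_prob(False, limited, params) == 0.18
        assert anxiety_event_prob(True, year_round, params) == pytest.approx(
            0.18 * 1.66 * 1.79
        )
        assert anxiety_event_prob(False, year_round, params) == pytest.approx(0.3222)

    def test_probabilities_capped_at_one(self, params):
        extreme = ArmSpec("extreme", 1.0, 50.0, 0.0)
        assert anxiety_event_prob(True, extreme, params) == 1.0


class TestRunCohort:
    def test_occupancy_conserved_and_death_monotone(self, base_results):
        _, traces = base_results
        for trace in traces.values():
            occ = trace.to_frame()[["occ_no_prior", "occ_prior", "occ_dead"]]
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(occ["occ_dead"]) >= -1e-12)

    def test_cohort_is_extinct_at_terminal_age(self, params, arms, life_table):
        trace = run_cohort(params, arms[0], life_table)
        last = trace.records[-1]
        assert last.age == life_table.max_age

    def test_discounted_rewards_non_negative(self, base_results):
        _, traces = base_results
        for trace in traces.values():
            df = trace.to_frame()
            assert (df["qalys_discounted"] >= 0).all()
            assert (df["cost_discounted"] >= 0).all()

    def test_zero_utilities_give_zero_qalys(self, params, arms, life_table):
        dead_utilities = params.replace(
            u_no_cvd=0.0, u_prior_cvd=0.0, disutil_cvd_event=0.0, disutil_anxiety=0.0
        )
        trace = run_cohort(dead_utilities, arms[0], life_table)
        assert trace.total_qalys == 0.0

    def test_zero_discount_rate_identity(self, params, arms, life_table):
        flat = params.replace(discount_rate=0.0)
        trace = run_cohort(flat, arms[0], life_table)
        assert trace.total_cost == pytest.approx(
            trace.total_cost_undiscounted, rel=1e-12
        )
        assert trace.total_qalys == pytest.approx(
            trace.total_qalys_undiscounted, rel=1e-12
        )

    def test_empty_horizon_gives_zero_totals(self, params, arms, life_table):
        trace = run_cohort(params, arms[0], life_table, horizon=0)
        assert discounted_totals(trace) == (0.0, 0.0)

    def test_totals_equal_cycle_sums(self, base_results):
        _, traces = base_results
        for trace in traces.values():
            df = trace.to_frame()
            assert trace.total_cost == pytest.approx(
                df["cost_discounted"].sum(), rel=1e-9
            )
            assert trace.total_qalys == pytest.approx(
                df["qalys_discounted"].sum(), rel=1e-9
            )

    def test_null_exposure_makes_arms_identical(self, params, life_table):
        neutral = params.replace(
            rr_cvd_noise=1.0,
            rr_anx_noise=1.0,
            exposure_op_cost_pp=0.0,
            exposure_prod_loss_pp=0.0,
        )
        limited, year_round = arms_from_params(neutral)
        t1 = run_cohort(neutral, limited, life_table)
        t2 = run_cohort(neutral, year_round, life_table)
        assert abs(t1.total_cost - t2.total_cost) < 1e-12 * max(1, t1.total_cost)
        assert abs(t1.total_qalys - t2.total_qalys) < 1e-12 * t1.total_qalys

    def test_noise_anxiety_risk_worsens_exposed_arm_monotonically(
        self, params, life_table
    ):
        costs, qalys = [], []
        for rr in (1.0, 1.5, 2.0, 2.5, 3.0):
            p = params.replace(rr_anx_noise=rr)
            trace = run_cohort(p, arms_from_params(p)[1], life_table)
            costs.append(trace.total_cost)
            qalys.append(trace.total_qalys)
        assert all(a < b for a, b in zip(costs, costs[1:]))
        assert all(a > b for a, b in zip(qalys, qalys[1:]))

    def test_start_age_outside_life_table_raises(self, params):
        from noisecea.life_tables import make_gompertz_life_table

        short = make_gompertz_life_table(1e-5, 0.095, max_age=110, min_age=50)
        with pytest.raises(ValueError, match="below life-table coverage"):
            run_cohort(params, ArmSpec("x"), short)


class TestVectorizedEngine:
    def test_matches_scalar_trace_at_base_values(self, params, life_table, base_results):
        result, _ = base_results
        n = 4
        draws = {
            name: np.full(n, getattr(params, name))
            for name in ParameterSet.STOCHASTIC_FIELDS
        }
        draws["cvd_band_probs"] = np.tile(
            [b.probability for b in params.cvd_risk.bands], (n, 1)
        )
        cost_lim, q_lim = cohort_totals_vectorized(draws, params, life_table, False)
        cost_yr, q_yr = cohort_totals_vectorized(draws, params, life_table, True)
        assert cost_lim[0] == pytest.approx(result.reference.cost, rel=1e-12)
        assert q_lim[0] == pytest.approx(result.reference.qalys, rel=1e-12)
        assert cost_yr[0] == pytest.approx(result.comparator.cost, rel=1e-12)
        assert q_yr[0] == pytest.approx(result.comparator.qalys, rel=1e-12)
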
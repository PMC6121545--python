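"""ICER arithmetic, PSA reproducibility, CEAC identities, tornado, scenario."""

import math

import numpy as np
import pandas as pd
import pytest

from noisecea.cea import (
    ArmTotals,
    ceac,
    icer,
    one_way,
    run_psa,
    scenario_65db,
    tornado,
)


class TestIcer:
    def test_ratio_of_increments(self):
        res = icer(ArmTotals("a", 11_288.0, 1.13), ArmTotals("b", 0.0, 0.0))
        assert res.icer == pytest.approx(9_989.38, abs=0.01)
        assert res.dominance == "tradeoff"

    def test_cost_saving_is_dominant(self):
        res = icer(ArmTotals("a", -5.0, 1.0), ArmTotals("b", 0.0, 0.0))
        assert res.dominance == "dominant"

    def test_costlier_and_worse_is_dominated(self):
        res = icer(ArmTotals("a", 5.0, -1.0), ArmTotals("b", 0.0, 0.0))
        assert res.dominance == "dominated"

    def test_zero_qaly_increment_has_no_ratio(self):
        res = icer(ArmTotals("a", 5.0, 1.0), ArmTotals("b", 0.0, 1.0))
        assert math.isnan(res.icer)
        assert res.dominance == "dominated"

    def test_non_finite_totals_raise(self):
        with pytest.raises(ValueError, match="non-finite"):
            icer(ArmTotals("a", math.nan, 1.0), ArmTotals("b", 0.0, 0.0))

    def test_shared_cost_shift_leaves_increments_unchanged(self, base_results):
        result, _ = base_results
        shifted = icer(
            ArmTotals("a", result.reference.cost + 1e4, result.reference.qalys),
            ArmTotals("b", result.comparator.cost + 1e4, result.comparator.qalys),
        )
        assert shifted.incremental_cost == pytest.approx(
            result.incremental_cost, rel=1e-9
        )
        assert shifted.icer == pytest.approx(result.icer, rel=1e-9)


@pytest.fixture(scope="module")
def psa(params, life_table):
    return run_psa(params, life_table, n_draws=2_000, seed=7)


class TestPSA:
    def test_fixed_seed_is_bit_reproducible(self, params, life_table, psa):
        again = run_psa(params, life_table, n_draws=2_000, seed=7)
        pd.testing.assert_frame_equal(psa.samples, again.samples)

    def test_single_draw_equals_seeded_deterministic_run(self, params, life_table):
        from noisecea.cea import base_case
        from noisecea.params import sample_parameter_set

        psa1 = run_psa(params, life_table, n_draws=1, seed=123)
        sampled = sample_parameter_set(params, 123)
        result, _ = base_case(sampled, life_table)
        row = psa1.samples.iloc[0]
        assert row["dcost"] == pytest.approx(result.incremental_cost, rel=1e-9)
        assert row["dqalys"] == pytest.approx(result.incremental_qalys, rel=1e-9)

    def test_ceac_equals_brute_force_nmb_count(self, psa):
        grid = [0.0, 20_000.0, 50_000.0, 100_000.0]
        curve = ceac(psa, grid)
        for wtp, prob in zip(curve["wtp"], curve["prob_cost_effective"]):
            count = sum(
                1
                for _, r in psa.samples.iterrows()
                if wtp * r["dqalys"] - r["dcost"] > 0
            )
            assert prob == pytest.approx(count / psa.n_draws)

    def test_ceac_limits(self, psa):
        dq = psa.samples["dqalys"].to_numpy()
        dc = psa.samples["dcost"].to_numpy()
        at_zero = ceac(psa, [0.0])["prob_cost_effective"][0]
        assert at_zero == pytest.approx((dc < 0).mean())
        at_inf = ceac(psa, [1e15])["prob_cost_effective"][0]
        assert at_inf == pytest.approx((dq > 0).mean())

    def test_all_dominant_draws_give_certain_acceptance(self, psa):
        forced = psa.samples.copy()
        forced["dcost"] = -1.0
        forced["dqalys"] = 1.0
        from noisecea.cea import PSAResult

        curve = ceac(PSAResult(forced, 0), [0.0, 50_000.0])
        assert (curve["prob_cost_effective"] == 1.0).all()

    def test_empty_wtp_grid_raises(self, psa):
        with pytest.raises(ValueError, match="grid"):
            ceac(psa, [])

    def test_invalid_draw_count_raises(self, params, life_table):
        with pytest.raises(ValueError, match="n_draws"):
            run_psa(params, life_table, n_draws=0)


class TestOneWay:
    def test_pinning_at_base_value_reproduces_base_icer(
        self, params, life_table, base_results
    ):
        result, _ = base_results
        row = one_way(params, life_table, "rr_anx_noise", 1.79, 1.79)
        assert row.icer_min == row.icer_max == pytest.approx(result.icer, rel=1e-12)

    def test_icer_pair_sorted_ascending(self, params, life_table):
        row = one_way(params, life_table, "discount_rate", 0.0, 0.05)
        assert row.icer_min <= row.icer_max

    def test_unknown_parameter_raises(self, params, life_table):
        with pytest.raises(ValueError, match="unknown parameter"):
            one_way(params, life_table, "not_a_parameter", 0, 1)

    def test_inverted_range_raises(self, params, life_table):
        with pytest.raises(ValueError, match="low > high"):
            one_way(params, life_table, "discount_rate", 0.05, 0.0)

    def test_tornado_sorted_by_descending_spread(self, params, life_table):
        table = tornado(
            params,
            life_table,
            {
                "rr_anx_noise": (1.0, 3.06),
                "discount_rate": (0.0, 0.05),
                "u_prior_cvd": (0.74, 0.94),
            },
        )
        spreads = table["spread"].to_numpy()
        assert np.all(np.diff(spreads) <= 0)
        assert table.iloc[0]["parameter"] == "rr_anx_noise"


class TestScenario65db:
    def test_same_population_reproduces_base_case(
        self, params, life_table, base_results
    ):
        result, _ = base_results
        scen = scenario_65db(params, life_table, params.population_60db)
        assert scen.incremental_cost == pytest.approx(
            result.incremental_cost, rel=1e-12
        )
        assert scen.icer == pytest.approx(result.icer, rel=1e-12)

    def test_halving_population_doubles_exposure_cost_per_person(
        self, params, life_table
    ):
        half = params.population_60db // 2
        scen_full = scenario_65db(params, life_table, params.population_60db)
        scen_half = scenario_65db(params, life_table, half)
        # the limited arm carries the exposure cost, so its cost rises
        extra_full = scen_full.reference.cost - scen_full.comparator.cost
        extra_half = scen_half.reference.cost - scen_half.comparator.cost
        assert extra_half > extra_full
        # per-person exposure cost scales inversely with population
        pp_full = params.exposure_cost_pp
        pp_half = params.exposure_cost_pp * params.population_60db / half
        assert pp_half == pytest.approx(2 * pp_full, rel=1e-3)

    def test_smaller_population_raises_icer(self, params, life_table, base_results):
        result, _ = base_results
        scen = scenario_65db(params, life_table, params.population_60db // 7)
        assert scen.icer > result.icer

    def test_zero_population_raises(self, params, life_table):
        with pytest.raises(ValueError, match="population"):
            scenario_65db(params, life_table, 0)
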
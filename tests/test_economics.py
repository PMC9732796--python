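"""ICER/NMB algebra, strategy comparison, threshold and scenario analysis."""

import dataclasses

import numpy as np
import pytest

from dfu_heor import (
    DomainError,
    IcerCategory,
    NoThresholdError,
    StrategyResult,
    ThresholdStatus,
    ValidationError,
    evaluate_strategies,
    icer,
    nmb,
    run_scenarios,
    threshold_rr,
)
from dfu_heor.synthetic import generate_transition_params


def _sr(label, q, c):
    return StrategyResult(label, q, c)


class TestIcer:
    def test_northeast_quadrant_ratio(self):
        res = icer(_sr("a", 11.0, 40_000.0), _sr("b", 10.0, 20_000.0))
        assert res.category is IcerCategory.ICER
        assert res.icer == pytest.approx(20_000.0)

    def test_cheaper_and_better_dominates(self):
        res = icer(_sr("a", 10.01, 19_990.0), _sr("b", 10.0, 20_000.0))
        assert res.category is IcerCategory.DOMINANT and res.icer is None

    def test_costlier_and_worse_is_dominated(self):
        res = icer(_sr("a", 9.9, 20_500.0), _sr("b", 10.0, 20_000.0))
        assert res.category is IcerCategory.DOMINATED

    def test_no_qaly_difference_never_divides(self):
        res = icer(_sr("a", 10.0, 20_500.0), _sr("b", 10.0, 20_000.0))
        assert res.category is IcerCategory.ZERO_EFFECT and res.icer is None

    def test_southwest_quadrant_is_flagged(self):
        res = icer(_sr("a", 9.0, 10_000.0), _sr("b", 10.0, 20_000.0))
        assert res.category is IcerCategory.ICER and res.southwest
        assert res.icer == pytest.approx(10_000.0)


class TestNmb:
    def test_zero_at_the_threshold_point(self):
        assert nmb(_sr("a", 11.0, 40_000.0), _sr("b", 10.0, 20_000.0),
                   20_000.0) == pytest.approx(0.0)

    def test_pure_cost_difference(self):
        assert nmb(_sr("a", 10.0, 50.0), _sr("b", 10.0, 0.0), 20_000.0) == -50.0

    def test_affine_combination(self):
        assert nmb(_sr("a", 10.05, 400.0), _sr("b", 10.0, 0.0),
                   20_000.0) == pytest.approx(600.0)

    def test_negative_wtp_rejected(self):
        with pytest.raises(DomainError):
            nmb(_sr("a", 1, 1), _sr("b", 1, 1), -5.0)


class TestEvaluateStrategies:
    def test_no_effect_free_app_arms_identical(self, placeholder_params, econ,
                                               short_config):
        econ0 = dataclasses.replace(econ, app_price_monthly=0.0)
        interv, comp = evaluate_strategies(placeholder_params, econ0,
                                           short_config, rr=1.0)
        assert interv.discounted_qalys == pytest.approx(comp.discounted_qalys,
                                                        abs=1e-12)
        assert interv.discounted_costs == pytest.approx(comp.discounted_costs,
                                                        abs=1e-9)

    def test_no_effect_priced_app_is_pure_cost(self, placeholder_params, econ,
                                               short_config):
        interv, comp = evaluate_strategies(placeholder_params, econ,
                                           short_config, rr=1.0)
        assert interv.discounted_qalys == pytest.approx(comp.discounted_qalys,
                                                        abs=1e-12)
        assert interv.discounted_costs > comp.discounted_costs

    def test_halved_recurrence_gains_qalys(self, placeholder_params, econ):
        interv, comp = evaluate_strategies(placeholder_params, econ, rr=0.5)
        assert interv.discounted_qalys > comp.discounted_qalys


class TestThreshold:
    def test_free_app_is_dominant_at_boundary(self, placeholder_params, econ):
        econ0 = dataclasses.replace(econ, app_price_monthly=0.0)
        t = threshold_rr(placeholder_params, econ0)
        assert t.status is ThresholdStatus.DOMINANT_AT_RR1 and t.rr == 1.0

    def test_zero_compliance_has_no_threshold(self, placeholder_params, econ):
        econ0 = dataclasses.replace(econ, compliance=0.0)
        with pytest.raises(NoThresholdError) as err:
            threshold_rr(placeholder_params, econ0)
        assert "no threshold" in str(err.value)
        assert err.value.diagnostics["compliance"] == 0.0

    def test_icer_at_threshold_hits_target(self, placeholder_params, econ):
        t = threshold_rr(placeholder_params, econ, target_icer=20_000.0)
        assert t.status is ThresholdStatus.FOUND
        assert abs(t.icer_at_rr - 20_000.0) / 20_000.0 < 1e-4

    def test_round_trip_at_full_compliance(self, placeholder_params, econ):
        econ1 = dataclasses.replace(econ, compliance=1.0)
        t = threshold_rr(placeholder_params, econ1, target_icer=20_000.0,
                         rr_tol=1e-9)
        res = icer(*evaluate_strategies(placeholder_params, econ1, rr=t.rr))
        assert abs(res.icer - 20_000.0) / 20_000.0 < 1e-6

    def test_matches_grid_search_oracle(self, placeholder_params, econ):
        t = threshold_rr(placeholder_params, econ)
        grid = np.arange(0.001, 1.0005, 0.001)
        f = np.array([
            nmb(*evaluate_strategies(placeholder_params, econ, rr=r), 20_000.0)
            for r in grid
        ])
        # largest grid rr still cost-effective brackets the threshold
        rr_grid = grid[np.where(f >= 0)[0][-1]]
        assert abs(t.rr - rr_grid) <= 0.001 + 1e-12

    def test_bad_target_rejected(self, placeholder_params, econ):
        with pytest.raises(DomainError):
            threshold_rr(placeholder_params, econ, target_icer=0.0)


class TestScenarios:
    def test_cheaper_app_needs_less_effect(self, placeholder_params, econ):
        table = run_scenarios(placeholder_params, econ,
                              pricings=("free", "annual", "monthly"))
        by = table.set_index("scenario")["threshold_rr"]
        assert by["free"] >= by["annual"] >= by["monthly"]

    def test_unknown_pricing_lists_valid_options(self, placeholder_params, econ):
        with pytest.raises(ValidationError, match="annual"):
            run_scenarios(placeholder_params, econ, pricings=("weekly",))

    def test_identical_scenarios_are_deterministic(self, placeholder_params, econ,
                                                   short_config):
        a = run_scenarios(placeholder_params, econ, short_config, ("monthly",))
        b = run_scenarios(placeholder_params, econ, short_config, ("monthly",))
        assert a.equals(b)


@pytest.mark.parametrize("seed", [3, 7])
def test_threshold_oracle_on_random_parameter_sets(seed, econ):
    """Bisection agrees with a coarse grid oracle on random transition sets."""
    params = generate_transition_params(seed)
    t = threshold_rr(params, econ)
    grid = np.arange(0.005, 1.0025, 0.005)
    f = np.array([
        nmb(*evaluate_strategies(params, econ, rr=r), 20_000.0) for r in grid
    ])
    rr_grid = grid[np.where(f >= 0)[0][-1]]
    assert abs(t.rr - rr_grid) <= 0.005 + 1e-12
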
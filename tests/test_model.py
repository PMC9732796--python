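"""Markov engine: validation, intervention scaling, trace, discounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfu_heor import (
    DomainError,
    EconomicParameters,
    HealthState,
    ModelConfig,
    StructuralViolationError,
    TransitionParameters,
    ValidationError,
    accumulate_outcomes,
    apply_intervention,
    discount_factor,
    run_cohort_trace,
    validate_transitions,
)
from dfu_heor.synthetic import generate_transition_params

from conftest import identity_params

S = HealthState


class TestValidateTransitions:
    def test_all_outflows_zero_gives_identity_chain(self):
        p = identity_params()
        assert np.allclose(p.matrix, np.eye(6))

    def test_unspecified_amputation_outflow_defaults_to_tunnel(self):
        p = validate_transitions(TransitionParameters.from_outflows({}))
        assert p.matrix[S.AMPUTATION, S.POST_AMPUTATION] == 1.0
        assert p.matrix[S.AMPUTATION, S.AMPUTATION] == 0.0

    @pytest.mark.parametrize(
        "outflows",
        [
            {(S.POST_DFU, S.DEATH): 1.1},
            {(S.POST_DFU, S.NONSEVERE_DFU): 0.6, (S.POST_DFU, S.DEATH): 0.6},
            {(S.POST_DFU, S.SEVERE_DFU): -0.1},
        ],
    )
    def test_row_bound_violations_rejected(self, outflows):
        with pytest.raises(ValidationError):
            validate_transitions(TransitionParameters.from_outflows(outflows))

    def test_death_from_nonsevere_is_a_structural_violation(self):
        tp = TransitionParameters.from_outflows(
            {(S.NONSEVERE_DFU, S.DEATH): 0.01}
        )
        with pytest.raises(StructuralViolationError, match="NONSEVERE_DFU->DEATH"):
            validate_transitions(tp)

    def test_death_row_is_absorbing(self, placeholder_params):
        row = placeholder_params.matrix[S.DEATH]
        assert row[S.DEATH] == 1.0 and row.sum() == 1.0

    def test_rows_are_stochastic(self, placeholder_params):
        assert np.allclose(placeholder_params.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_amputation_death_requires_opt_in(self):
        with pytest.raises(StructuralViolationError):
            validate_transitions(
                TransitionParameters.from_outflows({(S.AMPUTATION, S.DEATH): 0.05})
            )
        p = validate_transitions(
            TransitionParameters.from_outflows(
                {(S.AMPUTATION, S.DEATH): 0.05,
                 (S.AMPUTATION, S.POST_AMPUTATION): 0.95},
                allow_amputation_death=True,
            )
        )
        assert p.matrix[S.AMPUTATION, S.DEATH] == 0.05


class TestApplyIntervention:
    def test_rr_one_is_identity(self, placeholder_params):
        out = apply_intervention(placeholder_params, 1.0, 0.37)
        assert np.allclose(out.matrix, placeholder_params.matrix)

    def test_full_compliance_scales_directly(self):
        p = validate_transitions(
            TransitionParameters.from_outflows({(S.POST_DFU, S.NONSEVERE_DFU): 0.10})
        )
        out = apply_intervention(p, 0.95, 1.0)
        assert out.matrix[S.POST_DFU, S.NONSEVERE_DFU] == pytest.approx(0.095)

    def test_partial_compliance_blends_effect(self):
        # rr_eff = 0.9 * 0.9 + 0.1 = 0.91, so 0.10 -> 0.091
        p = validate_transitions(
            TransitionParameters.from_outflows({(S.POST_DFU, S.NONSEVERE_DFU): 0.10})
        )
        out = apply_intervention(p, 0.90, 0.90)
        assert out.matrix[S.POST_DFU, S.NONSEVERE_DFU] == pytest.approx(0.091)

    def test_freed_mass_returns_to_self_transition(self, placeholder_params):
        out = apply_intervention(placeholder_params, 0.5, 1.0)
        assert np.allclose(out.matrix.sum(axis=1), 1.0)
        assert (
            out.matrix[S.POST_DFU, S.POST_DFU]
            > placeholder_params.matrix[S.POST_DFU, S.POST_DFU]
        )

    @pytest.mark.parametrize("rr", [0.0, -0.2, 1.5])
    def test_out_of_domain_rr_rejected(self, placeholder_params, rr):
        with pytest.raises(DomainError):
            apply_intervention(placeholder_params, rr, 0.9)

    def test_non_recurrence_rows_untouched(self, placeholder_params):
        out = apply_intervention(placeholder_params, 0.7, 0.9)
        keep = [s for s in S if s != S.POST_DFU]
        assert np.allclose(
            out.matrix[keep], placeholder_params.matrix[keep]
        )


class TestRunCohortTrace:
    def test_identity_matrix_keeps_cohort_in_post_dfu(self):
        trace = run_cohort_trace(identity_params(), ModelConfig(max_age_years=70))
        assert np.all(trace.occupancy[:, S.POST_DFU] == 1.0)

    def test_certain_death_absorbs_after_first_cycle(self):
        p = validate_transitions(
            TransitionParameters.from_outflows({(S.POST_DFU, S.DEATH): 1.0})
        )
        trace = run_cohort_trace(p, ModelConfig(max_age_years=70))
        assert trace.occupancy[1, S.DEATH] == 1.0
        # residual tolerance stops the trace once everyone is dead
        assert trace.n_cycles == 1

    def test_two_state_survival_matches_geometric_closed_form(self):
        q = 0.01
        p = validate_transitions(
            TransitionParameters.from_outflows({(S.POST_DFU, S.DEATH): q})
        )
        trace = run_cohort_trace(
            p, ModelConfig(max_age_years=77, residual_alive_tolerance=0.0)
        )
        c = np.arange(trace.occupancy.shape[0])
        assert np.allclose(trace.alive_fraction, (1 - q) ** c, atol=1e-12)

    def test_unvalidated_params_rejected(self):
        with pytest.raises(ValidationError):
            run_cohort_trace(TransitionParameters.from_outflows({}))

    def test_mass_conserved_and_death_monotone(self, placeholder_params):
        trace = run_cohort_trace(placeholder_params)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        death = trace.occupancy[:, S.DEATH]
        assert np.all(np.diff(death) >= -1e-15)


class TestDiscounting:
    def test_cycle_zero_and_zero_rate_are_unity(self):
        assert discount_factor(0, 0.035) == 1.0
        assert discount_factor(240, 0.0) == 1.0

    def test_one_year_at_base_rate(self):
        assert discount_factor(12, 0.035) == pytest.approx(1 / 1.035, rel=1e-12)

    def test_annual_step_convention_holds_within_each_year(self):
        assert discount_factor(11, 0.035, annual_step=True) == 1.0
        assert discount_factor(12, 0.035, annual_step=True) == pytest.approx(1 / 1.035)

    def test_negative_cycle_rejected(self):
        with pytest.raises(DomainError):
            discount_factor(-1, 0.035)


def _pinned_immortal_setup(app_price=4.99):
    params = identity_params()
    config = ModelConfig(
        max_age_years=68.0, half_cycle_correction=False,
        residual_alive_tolerance=0.0,
    )
    econ = EconomicParameters(
        utility=[0.64, 0.61, 0.47, 0.34, 0.47, 0.0],
        monthly_cost=[180.70, 453.83, 972.30, 1106.19, 311.96, 0.0],
        app_price_monthly=app_price,
        annual_discount_rate_costs=0.0,
        annual_discount_rate_outcomes=0.0,
    )
    return run_cohort_trace(params, config), econ


class TestAccumulateOutcomes:
    def test_zero_utilities_and_costs_give_zero(self):
        trace, econ = _pinned_immortal_setup()
        zero = EconomicParameters(
            utility=np.zeros(6), monthly_cost=np.zeros(6), app_price_monthly=0.0,
            annual_discount_rate_costs=0.0, annual_discount_rate_outcomes=0.0,
        )
        assert accumulate_outcomes(trace, zero) == (0.0, 0.0)

    def test_one_undiscounted_year_pinned_in_post_dfu(self):
        trace, econ = _pinned_immortal_setup()
        q, c = accumulate_outcomes(trace, econ, include_app_cost=False)
        assert q == pytest.approx(0.64, abs=1e-12)
        assert c == pytest.approx(12 * 180.70, abs=1e-9)

    def test_app_subscription_charged_to_alive_cohort(self):
        trace, econ = _pinned_immortal_setup(app_price=4.99)
        _, c = accumulate_outcomes(trace, econ, include_app_cost=True)
        assert c == pytest.approx(12 * 180.70 + 12 * 4.99, abs=1e-9)

    def test_half_cycle_correction_averages_adjacent_rows(self):
        q = 0.5  # half die each month
        p = validate_transitions(
            TransitionParameters.from_outflows({(S.POST_DFU, S.DEATH): q})
        )
        config = ModelConfig(max_age_years=68, residual_alive_tolerance=0.0)
        trace = run_cohort_trace(p, config)
        econ = EconomicParameters(
            utility=[1.0, 0, 0, 0, 0, 0], monthly_cost=np.zeros(6),
            annual_discount_rate_outcomes=0.0, annual_discount_rate_costs=0.0,
        )
        q_hcc, _ = accumulate_outcomes(trace, econ)
        alive = trace.alive_fraction
        expected = np.sum(0.5 * (alive[:-1] + alive[1:])) / 12.0
        assert q_hcc == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    q=st.floats(min_value=1e-4, max_value=0.2),
    r=st.floats(min_value=0.0, max_value=0.2),
)
def test_discounted_life_years_match_geometric_series(q, r):
    """Two-state reduction: discounted life-years equal the closed form
    sum_c (1-q)^c (1+r)^(-c/12) / 12 (half-cycle correction off)."""
    p = validate_transitions(
        TransitionParameters.from_outflows({(S.POST_DFU, S.DEATH): q})
    )
    config = ModelConfig(
        max_age_years=87, half_cycle_correction=False, residual_alive_tolerance=0.0
    )
    trace = run_cohort_trace(p, config)
    econ = EconomicParameters(
        utility=[1.0, 0, 0, 0, 0, 0], monthly_cost=np.zeros(6),
        annual_discount_rate_outcomes=r, annual_discount_rate_costs=r,
    )
    got, _ = accumulate_outcomes(trace, econ)
    c = np.arange(trace.n_cycles)
    closed = np.sum((1 - q) ** c * (1 + r) ** (-c / 12)) / 12.0
    assert got == pytest.approx(closed, abs=1e-9)


@pytest.mark.parametrize("seed", range(12))
def test_random_parameter_sets_conserve_mass_and_absorb(seed):
    params = generate_transition_params(seed)
    trace = run_cohort_trace(params)
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((trace.occupancy >= -1e-15) & (trace.occupancy <= 1 + 1e-15))
    assert np.all(np.diff(trace.occupancy[:, S.DEATH]) >= -1e-15)


def test_qalys_non_increasing_in_mortality(econ):
    """Raising any death probability cannot raise total discounted QALYs."""
    from dfu_heor.model import PLACEHOLDER_OUTFLOWS

    base_out = dict(PLACEHOLDER_OUTFLOWS)
    base = validate_transitions(TransitionParameters.from_outflows(base_out))
    q_base, _ = accumulate_outcomes(run_cohort_trace(base), econ)
    for pair in [
        (S.POST_DFU, S.DEATH),
        (S.SEVERE_DFU, S.DEATH),
        (S.POST_AMPUTATION, S.DEATH),
    ]:
        bumped = dict(base_out)
        bumped[pair] = base_out[pair] + 0.05
        p = validate_transitions(TransitionParameters.from_outflows(bumped))
        q, _ = accumulate_outcomes(run_cohort_trace(p), econ)
        assert q <= q_base + 1e-12
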
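"""Cohort engine: matrix construction, propagation, discounting, accrual."""

import numpy as np
import pytest

from lbpcea import (
    DTC,
    TAU,
    accrue_values,
    build_transition_matrix,
    discount_factor,
    run_cohort,
    run_strategy,
    start_vector,
)
from lbpcea.engine import (
    HEALTHY,
    HIGH,
    LOW,
    REMISSION,
    RESIDUAL_POLICIES,
    T_W1_4,
    T_W4_8,
    T_W8_12,
    CohortTrace,
    Conventions,
    ValueSchedule,
)


class TestBuildTransitionMatrix:
    @pytest.mark.parametrize("policy", RESIDUAL_POLICIES)
    @pytest.mark.parametrize("strategy", [DTC, TAU])
    def test_rows_are_stochastic_under_every_policy(self, params, strategy, policy):
        tm = build_transition_matrix(params, strategy, policy)
        assert np.abs(tm.entries.sum(axis=1) - 1.0).max() <= 1e-12
        assert (tm.entries >= 0).all() and (tm.entries <= 1).all()

    @pytest.mark.parametrize("policy", RESIDUAL_POLICIES)
    def test_app_first_treatment_row_appears_verbatim(self, params, policy):
        row = build_transition_matrix(params, DTC, policy).row("T_W1_4")
        assert row[LOW] == pytest.approx(0.0514)
        assert row[HIGH] == pytest.approx(0.0111)
        assert row[T_W4_8] == pytest.approx(0.875)
        assert row[REMISSION] == pytest.approx(0.0625)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("strategy", [DTC, TAU])
    def test_healthy_is_a_unit_self_loop(self, params, strategy):
        row = build_transition_matrix(params, strategy).row("HEALTHY")
        assert row[HEALTHY] == 1.0 and row[:HEALTHY].sum() == 0.0

    @pytest.mark.parametrize("policy", RESIDUAL_POLICIES)
    def test_usual_care_end_row_deficit_goes_to_remission(self, params, policy):
        row = build_transition_matrix(params, TAU, policy).row("T_W8_12")
        assert row[REMISSION] == pytest.approx(0.664)
        assert row[HEALTHY] == pytest.approx(0.05)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_raw_entry_policy_recomposes_entry_probabilities(self, params):
        tm = build_transition_matrix(params, DTC, "raw_entry")
        assert tm.row("LOW")[T_W1_4] == pytest.approx(0.60)
        assert tm.row("LOW")[LOW] == pytest.approx(0.36)
        assert tm.row("HIGH")[T_W1_4] == pytest.approx(0.72)
        assert tm.row("HIGH")[HIGH] == pytest.approx(0.26)

    def test_renormalize_policy_keeps_entry_and_scales_the_rest(self, params):
        tm = build_transition_matrix(params, DTC, "renormalize_non_treatment")
        assert tm.row("LOW")[T_W1_4] == pytest.approx(0.75)
        assert tm.row("LOW")[LOW] == pytest.approx(0.20)
        assert tm.row("LOW")[HIGH] == pytest.approx(0.0125)
        assert tm.row("LOW")[REMISSION] == pytest.approx(0.0375)

    def test_resolutions_are_recorded(self, params):
        tm = build_transition_matrix(params, TAU)
        assert any("T_W8_12" in note for note in tm.resolutions)
        assert any("LOW" in note for note in tm.resolutions)

    def test_overfull_row_raises_inconsistency_error(self, params):
        with pytest.raises(ValueError, match="exceeds 1"):
            build_transition_matrix(params.replace(p_end_remission=0.95), DTC)

    def test_no_tunnel_entry_except_from_predecessor(self, params):
        for strategy in (DTC, TAU):
            m = build_transition_matrix(params, strategy).entries
            for tunnel, pred in ((T_W4_8, T_W1_4), (T_W8_12, T_W4_8)):
                feeders = [i for i in range(7) if m[i, tunnel] > 0]
                assert feeders == [pred]


class TestRunCohort:
    def test_identity_matrix_keeps_the_cohort_in_place(self):
        start = np.array([100.0, 0, 0, 0, 0, 200, 50])
        trace = run_cohort(np.eye(7), start, 5)
        assert np.allclose(trace.raw, start)

    def test_symmetric_two_state_split(self):
        # p(stay)=0.5 toward an absorbing sink: after one cycle, half each.
        m = np.eye(7)
        m[0, 0] = 0.5
        m[0, 6] = 0.5
        start = np.zeros(7)
        start[0] = 1000.0
        trace = run_cohort(m, start, 1)
        assert trace.raw[1, 0] == pytest.approx(500.0)
        assert trace.raw[1, 6] == pytest.approx(500.0)

    def test_mass_is_conserved_over_65_cycles(self, params):
        for strategy in (DTC, TAU):
            tm = build_transition_matrix(params, strategy)
            trace = run_cohort(tm, start_vector(params), 65)
            assert np.abs(trace.raw.sum(axis=1) - 10_000.0).max() <= 1e-9

    def test_corrected_is_the_half_cycle_average(self, params):
        tm = build_transition_matrix(params, DTC)
        trace = run_cohort(tm, start_vector(params), 10)
        assert np.allclose(trace.corrected, 0.5 * (trace.raw[:-1] + trace.raw[1:]))

    def test_dimension_mismatch_is_a_structural_error(self, params):
        tm = build_transition_matrix(params, DTC)
        with pytest.raises(ValueError):
            run_cohort(tm, np.ones(6), 5)


class TestDiscounting:
    @pytest.mark.parametrize(
        "cycle, rate, expected",
        [(0, 0.03, 1.0), (13, 0.03, 1 / 1.03), (26, 0.0, 1.0)],
    )
    def test_discount_factor_values(self, cycle, rate, expected):
        assert discount_factor(cycle, rate, 13) == pytest.approx(expected)

    def test_negative_cycle_is_a_domain_error(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03, 13)

    def test_factor_strictly_decreases_for_positive_rates(self):
        factors = [discount_factor(t, 0.03, 13) for t in range(40)]
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_annual_step_discounts_in_year_blocks(self):
        assert discount_factor(12, 0.03, 13, step="annual") == 1.0
        assert discount_factor(13, 0.03, 13, step="annual") == pytest.approx(1 / 1.03)


def _constant_trace(state: int, persons: float, n_cycles: int) -> CohortTrace:
    raw = np.zeros((n_cycles + 1, 7))
    raw[:, state] = persons
    return CohortTrace(raw=raw, corrected=0.5 * (raw[:-1] + raw[1:]), cohort_size=persons)


class TestAccrual:
    def test_closed_form_single_state_qalys(self):
        # Utility 0.8 for a full undiscounted year: 0.8 QALY per person.
        sched = ValueSchedule(
            strategy=DTC,
            state_costs=np.array([10.0, 0, 0, 0, 0, 0, 0]),
            utilities=np.array([0.8, 0, 0, 0, 0, 0, 0]),
            indirect_costs=np.zeros(7),
            cycle_length_years=1 / 13,
        )
        totals = accrue_values(_constant_trace(LOW, 1000.0, 13), sched,
                               annual_rate=0.0, utility_rate=0.0)
        assert totals.discounted_qalys == pytest.approx(0.8)
        assert totals.discounted_cost == pytest.approx(130.0)

    def test_zero_rate_equals_undiscounted(self, params):
        conv = Conventions(utility_discount_rate=0.0)
        totals = run_strategy(params.replace(discount_rate=0.0), DTC, conventions=conv)
        assert totals.discounted_cost == pytest.approx(totals.undiscounted_cost)
        assert totals.discounted_qalys == pytest.approx(totals.undiscounted_qalys)

    def test_per_state_breakdown_sums_to_totals(self, dtc_totals):
        assert dtc_totals.per_state_cost.sum() == pytest.approx(
            dtc_totals.discounted_cost, abs=1e-9)
        assert dtc_totals.per_state_qalys.sum() == pytest.approx(
            dtc_totals.discounted_qalys, abs=1e-9)

    def test_direct_and_indirect_components_sum_to_total(self, dtc_totals):
        assert dtc_totals.direct_cost + dtc_totals.indirect_cost == pytest.approx(
            dtc_totals.discounted_cost, abs=1e-9)

    def test_discounting_strictly_reduces_totals(self, params):
        disc = run_strategy(params, DTC,
                            conventions=Conventions(utility_discount_rate=None))
        assert disc.discounted_cost < disc.undiscounted_cost
        assert disc.discounted_qalys < disc.undiscounted_qalys

    def test_half_cycle_correction_brackets_begin_and_end_counting(self, params):
        res = {c: run_strategy(params, DTC, conventions=Conventions(correction=c))
               for c in ("life-table", "begin", "end")}
        lo_c = min(res["begin"].discounted_cost, res["end"].discounted_cost)
        hi_c = max(res["begin"].discounted_cost, res["end"].discounted_cost)
        assert lo_c <= res["life-table"].discounted_cost <= hi_c
        lo_q = min(res["begin"].discounted_qalys, res["end"].discounted_qalys)
        hi_q = max(res["begin"].discounted_qalys, res["end"].discounted_qalys)
        assert lo_q <= res["life-table"].discounted_qalys <= hi_q

    def test_healthy_count_is_raw_final_membership_rounded(self, params):
        tm = build_transition_matrix(params, DTC)
        trace = run_cohort(tm, start_vector(params), 39)
        totals = run_strategy(params, DTC)
        assert totals.healthy_count_at_horizon == int(np.floor(trace.raw[-1, HEALTHY] + 0.5))
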
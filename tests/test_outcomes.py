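"""Incremental economics: ICER quadrants, annualization, CE plane."""

import numpy as np
import pytest

from lbpcea import (
    DTC,
    TAU,
    annualize,
    build_transition_matrix,
    ce_plane_points,
    icer,
    incremental_outcomes,
    resource_utilization,
    run_cohort,
    start_vector,
)
from lbpcea.engine import StrategyTotals


def _totals(strategy: str, cost: float, qalys: float, horizon: int = 39) -> StrategyTotals:
    return StrategyTotals(
        strategy=strategy,
        discounted_cost=cost,
        discounted_qalys=qalys,
        undiscounted_cost=cost,
        undiscounted_qalys=qalys,
        per_state_cost=np.full(7, cost / 7),
        per_state_qalys=np.full(7, qalys / 7),
        indirect_cost=0.0,
        direct_cost=cost,
        healthy_count_at_horizon=0,
        horizon_cycles=horizon,
        cohort_size=10_000.0,
    )


class TestIcerQuadrants:
    @pytest.mark.parametrize(
        "dc, de, value, label, non_strict",
        [
            (121.59, 0.0221, 121.59 / 0.0221, "icer", False),       # NE
            (-288.58, 0.0319, None, "intervention_dominant", False),  # SE
            (100.0, -0.01, None, "comparator_dominant", False),     # NW
            (-1263.62, -0.0029, None, "comparator_dominant_sw", True),  # SW
            (100.0, 0.0, None, "undefined_ratio", False),
            (-100.0, 0.0, None, "undefined_ratio", False),
            (0.0, 0.0, None, "indeterminate", False),
            (0.0, 0.01, None, "intervention_dominant", True),
            (0.0, -0.01, None, "comparator_dominant", True),
        ],
    )
    def test_all_sign_combinations(self, dc, de, value, label, non_strict):
        got_value, got_label, got_flag = icer(dc, de)
        assert got_label == label
        assert got_flag == non_strict
        if value is None:
            assert got_value is None
        else:
            assert got_value == pytest.approx(value)

    def test_ne_quadrant_ratio_from_printed_rounded_increments(self):
        value, label, _ = icer(121.59, 0.0221)
        assert label == "icer"
        assert value == pytest.approx(121.59 / 0.0221, abs=1e-9)
        assert round(value, 2) == 5501.81


class TestIncrementalOutcomes:
    def test_equal_totals_are_indeterminate(self):
        r = incremental_outcomes(_totals(DTC, 100.0, 1.0), _totals(TAU, 100.0, 1.0))
        assert r.dominance_label == "indeterminate"
        assert r.delta_cost == 0.0 and r.delta_qalys == 0.0

    def test_antisymmetry(self, dtc_totals, tau_totals):
        fwd = incremental_outcomes(dtc_totals, tau_totals)
        rev = incremental_outcomes(tau_totals, dtc_totals)
        assert rev.delta_cost == pytest.approx(-fwd.delta_cost)
        assert rev.delta_qalys == pytest.approx(-fwd.delta_qalys)

    def test_mismatched_horizons_are_rejected(self):
        with pytest.raises(ValueError):
            incremental_outcomes(_totals(DTC, 1.0, 1.0, 39), _totals(TAU, 1.0, 1.0, 26))

    def test_icer_present_iff_label_is_icer(self, dtc_totals, tau_totals):
        r = incremental_outcomes(dtc_totals, tau_totals)
        assert (r.icer_value is not None) == (r.dominance_label == "icer")


class TestAnnualize:
    def test_division_recovers_per_year_values(self):
        cost, qalys = annualize(_totals(DTC, 6117.0, 2.091), 3)
        assert cost == pytest.approx(2039.0)
        assert qalys == pytest.approx(0.697)

    def test_one_year_is_identity(self):
        t = _totals(DTC, 1234.5, 1.5)
        assert annualize(t, 1) == (1234.5, 1.5)

    def test_annualized_times_horizon_recovers_totals(self, dtc_totals):
        cost, qalys = annualize(dtc_totals, 3)
        assert cost * 3 == pytest.approx(dtc_totals.discounted_cost)
        assert qalys * 3 == pytest.approx(dtc_totals.discounted_qalys)


class TestResourceUtilization:
    def test_empty_cohort_incurs_nothing(self, params):
        tm = build_transition_matrix(params, TAU)
        trace = run_cohort(tm, np.zeros(7), 13)
        out = resource_utilization(trace, params)
        assert out["gp_consultations_per_year"] == 0.0
        assert out["prescriptions_per_year"] == 0.0

    def test_fully_healthy_cohort_incurs_nothing(self, params):
        tm = build_transition_matrix(params, TAU)
        start = np.zeros(7)
        start[6] = 10_000.0
        out = resource_utilization(run_cohort(tm, start, 13), params)
        assert out["gp_consultations_per_year"] == 0.0

    def test_base_case_counts_carry_the_convention_label(self, params):
        tm = build_transition_matrix(params, TAU)
        out = resource_utilization(run_cohort(tm, start_vector(params), 39), params)
        assert "convention" in out
        assert out["gp_consultations_per_year"] > 0
        assert out["prescriptions_per_year"] > 0


class TestCePlane:
    def test_empty_input_yields_empty_table(self):
        points, lines = ce_plane_points([])
        assert points.empty
        assert list(lines["threshold_eur_per_qaly"]) == [10_000.0, 20_000.0]

    def test_base_case_point_lies_below_the_lower_threshold(self, dtc_totals, tau_totals):
        r = incremental_outcomes(dtc_totals, tau_totals)
        points, _ = ce_plane_points([r])
        row = points.iloc[0]
        assert row["delta_cost"] < 10_000.0 * row["delta_qalys"]
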
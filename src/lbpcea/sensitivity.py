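"""One-way deterministic sensitivity analysis and the scenario suite.

The DSA reruns the full base-case pipeline with one parameter at its lower
then upper bound, recomposing linked quantities (e.g. an app price changes
the first-treatment-cycle state cost; a remission-share change recomposes
all treatment-exit probabilities) and records the ICER or dominance at
each bound.  Bounds marked raw in the source are swept on the raw scale
and recomposed before matrix construction.

The scenario suite varies the time horizon (2/4/5 years) and the app
strategy's monthly attrition (best case equal to usual care; worse cases
14% and 30% after each treatment month).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .engine import Conventions, REPRODUCTION_PROFILE, run_strategy
from .outcomes import IncrementalResult, incremental_outcomes
from .parameters import (
    DTC,
    TAU,
    ModelParameters,
    physiotherapy_cycle_cost,
    treatment_entry_cost,
)

__all__ = [
    "DSABound",
    "DSATable",
    "ScenarioSpec",
    "SCENARIOS",
    "published_dsa_bounds",
    "one_way_dsa",
    "tornado_order",
    "run_scenario",
    "run_scenario_suite",
    "base_case",
]

Applier = Callable[[ModelParameters, float], ModelParameters]


def _set_state_cost(params: ModelParameters, strategy: str, state: str, value: float) -> ModelParameters:
    costs = {s: dict(d) for s, d in params.state_costs.items()}
    costs[strategy][state] = value
    return params.replace(state_costs=costs)


def _apply_app_cost(p: ModelParameters, v: float) -> ModelParameters:
    p2 = _set_state_cost(p, DTC, "T_W1_4", treatment_entry_cost(DTC, v, p))
    return p2.replace(app_cost=v)


def _apply_physio_sessions(p: ModelParameters, v: float) -> ModelParameters:
    cycle = physiotherapy_cycle_cost(int(round(v)), p.physio_session_price,
                                     p.prescription_charge, p.copay_rate)
    p2 = _set_state_cost(p, TAU, "T_W1_4", treatment_entry_cost(TAU, cycle, p))
    return p2.replace(physio_sessions=int(round(v)))


def _apply_daily_wage(p: ModelParameters, v: float) -> ModelParameters:
    base_wage = round(p.monthly_gross_wage / p.working_days, 2)
    costs = {s: dict(d) for s, d in p.state_costs.items()}
    for strat in costs:
        for state, days in p.absenteeism_days.items():
            if days:
                costs[strat][state] = round(costs[strat][state] + days * (v - base_wage), 2)
    return p.replace(state_costs=costs, monthly_gross_wage=v * p.working_days)


def _apply_untreated_cost(state: str) -> Applier:
    def apply(p: ModelParameters, v: float) -> ModelParameters:
        p2 = _set_state_cost(p, DTC, state, v)
        return _set_state_cost(p2, TAU, state, v)
    return apply


def _apply_utility(state: str) -> Applier:
    def apply(p: ModelParameters, v: float) -> ModelParameters:
        utils = {s: dict(d) for s, d in p.utilities.items()}
        for strat in utils:
            utils[strat][state] = v
        return p.replace(utilities=utils)
    return apply


def _apply_rem_stay(p: ModelParameters, v: float) -> ModelParameters:
    # Recompose the recurrence destinations with the 82.2/17.8 trajectory split.
    recur = 1.0 - v
    return p.replace(p_rem_stay=v,
                     p_rem_low=round(recur * p.low_trajectory_share, 4),
                     p_rem_high=round(recur * (1.0 - p.low_trajectory_share), 4))


def _apply_end_remission(p: ModelParameters, v: float) -> ModelParameters:
    # Keep the end-of-treatment row closed: the remission change is taken
    # proportionally out of the low/high return probabilities, leaving the
    # healthy probability (the strategy lever) untouched.
    returns = p.p_end_low + p.p_end_high
    scale = (returns - (v - p.p_end_remission)) / returns
    if scale < 0:
        raise ValueError("end-of-treatment remission bound exceeds the row budget")
    return p.replace(p_end_remission=v,
                     p_end_low=p.p_end_low * scale,
                     p_end_high=p.p_end_high * scale)


def _apply_end_healthy_dtc(p: ModelParameters, v: float) -> ModelParameters:
    # The healthy change is taken out of the remission entry so the app
    # strategy's row stays closed; the usual-care residual fill then leaves
    # that strategy's row unchanged.
    return p.replace(p_end_healthy={DTC: v, TAU: p.p_end_healthy[TAU]},
                     p_end_remission=p.p_end_remission - (v - p.p_end_healthy[DTC]))


_APPLIERS: dict[str, Applier] = {
    "dtc_app_cost": _apply_app_cost,
    "physio_sessions": _apply_physio_sessions,
    "daily_wage": _apply_daily_wage,
    "low_state_cost": _apply_untreated_cost("LOW"),
    "high_state_cost": _apply_untreated_cost("HIGH"),
    "discount_rate": lambda p, v: p.replace(discount_rate=v),
    "p_low_treat_raw": lambda p, v: p.replace(p_low_treat=v),
    "p_high_treat_raw": lambda p, v: p.replace(p_high_treat=v),
    "remission_share_raw": lambda p, v: p.replace(remission_share=v),
    "p_end_remission": _apply_end_remission,
    "p_end_healthy_dtc": _apply_end_healthy_dtc,
    "p_rem_stay_raw": _apply_rem_stay,
    "u_high": _apply_utility("HIGH"),
    "u_remission": _apply_utility("REMISSION"),
    "u_healthy": _apply_utility("HEALTHY"),
}


@dataclass(frozen=True)
class DSABound:
    """Low/high bound for one ledger parameter, with its recomposition rule."""

    parameter_id: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.parameter_id not in _APPLIERS:
            raise KeyError(f"unknown DSA parameter {self.parameter_id!r}")
        if self.low > self.high:
            raise ValueError(f"{self.parameter_id}: low bound exceeds high bound")

    def apply(self, params: ModelParameters, value: float) -> ModelParameters:
        return _APPLIERS[self.parameter_id](params, value)


def published_dsa_bounds() -> list[DSABound]:
    """The published one-way bounds (cost table and transition table)."""
    return [
        DSABound("dtc_app_cost", 99.96, 299.96),
        DSABound("physio_sessions", 4, 12),
        DSABound("daily_wage", 132.52, 161.96),
        DSABound("low_state_cost", 397.55, 530.06),
        DSABound("high_state_cost", 471.17, 706.75),
        DSABound("discount_rate", 0.00, 0.05),
        DSABound("p_low_treat_raw", 0.60, 0.90),
        DSABound("p_high_treat_raw", 0.70, 0.90),
        DSABound("remission_share_raw", 0.40, 0.60),
        DSABound("p_end_remission", 0.583, 0.644),
        DSABound("p_end_healthy_dtc", 0.095, 0.105),
        DSABound("p_rem_stay_raw", 0.30, 0.46),
        DSABound("u_high", 0.5795, 0.6405),
        DSABound("u_remission", 0.7657, 0.8463),
        DSABound("u_healthy", 0.7657, 0.8463),
    ]


def base_case(
    params: ModelParameters,
    n_cycles: int | None = None,
    conventions: Conventions = REPRODUCTION_PROFILE,
    scenario_id: str = "base",
) -> IncrementalResult:
    """Run both strategies and return the incremental outcome."""
    dtc = run_strategy(params, DTC, n_cycles, conventions)
    tau = run_strategy(params, TAU, n_cycles, conventions)
    return incremental_outcomes(dtc, tau, scenario_id)


def _icer_sentinel(r: IncrementalResult) -> float:
    """Signed scalar used to order dominance outcomes on the tornado axis.

    Plain ICERs map to themselves; intervention-dominant outcomes to
    -|ΔC/ΔE| (better than any positive ICER), comparator-dominant ones to
    +|ΔC/ΔE|; undefined ratios to NaN.
    """
    if r.icer_value is not None:
        return r.icer_value
    if abs(r.delta_qalys) <= 1e-12:
        return float("nan")
    ratio = abs(r.delta_cost / r.delta_qalys)
    return -ratio if r.dominance_label == "intervention_dominant" else ratio


@dataclass(frozen=True)
class DSATable:
    """Tornado-ordered one-way DSA results."""

    rows: pd.DataFrame
    base_result: IncrementalResult = field(repr=False)

    @property
    def base_icer(self) -> float:
        return _icer_sentinel(self.base_result)


def one_way_dsa(
    base: ModelParameters,
    bounds: list[DSABound] | None = None,
    conventions: Conventions = REPRODUCTION_PROFILE,
) -> DSATable:
    """Rerun the pipeline at each bound of each parameter, one at a time."""
    if bounds is None:
        bounds = published_dsa_bounds()
    base_result = base_case(base, conventions=conventions)
    records = []
    for b in bounds:
        res = {}
        for side, value in (("low", b.low), ("high", b.high)):
            r = base_case(b.apply(base, value), conventions=conventions,
                          scenario_id=f"dsa:{b.parameter_id}:{side}")
            res[side] = r
        lo, hi = _icer_sentinel(res["low"]), _icer_sentinel(res["high"])
        records.append({
            "parameter_id": b.parameter_id,
            "low_value": b.low,
            "high_value": b.high,
            "icer_at_low": lo,
            "icer_at_high": hi,
            "label_at_low": res["low"].dominance_label,
            "label_at_high": res["high"].dominance_label,
            "range": abs(hi - lo) if np.isfinite(lo) and np.isfinite(hi) else float("nan"),
        })
    table = pd.DataFrame.from_records(records)
    return tornado_order(DSATable(rows=table, base_result=base_result))


def tornado_order(table: DSATable) -> DSATable:
    """Stable sort by descending ICER range; ties broken lexicographically."""
    rows = table.rows.sort_values(
        ["range", "parameter_id"], ascending=[False, True], kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    return DSATable(rows=rows, base_result=table.base_result)


@dataclass(frozen=True)
class ScenarioSpec:
    """A published scenario: a horizon and/or app-strategy attrition override."""

    scenario_id: str
    horizon_cycles: int = 39
    dtc_attrition: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be positive")
        if self.dtc_attrition is not None:
            for a in self.dtc_attrition:
                if not 0.0 <= a <= 1.0:
                    raise ValueError(f"attrition must be in [0, 1], got {a}")


SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec("base", 39),
    "A1": ScenarioSpec("A1", 26),                       # 2-year horizon
    "A2": ScenarioSpec("A2", 52),                       # 4-year horizon
    "A3": ScenarioSpec("A3", 65),                       # 5-year horizon
    "B1": ScenarioSpec("B1", 39, (0.065, 0.043)),       # app attrition = usual care
    "B2": ScenarioSpec("B2", 39, (0.14, 0.14)),         # higher app attrition
    "B3": ScenarioSpec("B3", 39, (0.30, 0.30)),         # worst-case app attrition
}


def run_scenario(
    spec: ScenarioSpec,
    base: ModelParameters,
    conventions: Conventions = REPRODUCTION_PROFILE,
) -> IncrementalResult:
    """Run one scenario: attrition overrides apply to the app strategy only
    and are recomposed through the dropout split; usual care stays at base."""
    params = base
    if spec.dtc_attrition is not None:
        params = base.replace(attrition={DTC: spec.dtc_attrition,
                                         TAU: base.attrition[TAU]})
    return base_case(params, n_cycles=spec.horizon_cycles,
                     conventions=conventions, scenario_id=spec.scenario_id)


def run_scenario_suite(
    base: ModelParameters,
    conventions: Conventions = REPRODUCTION_PROFILE,
) -> list[IncrementalResult]:
    """Base case plus the six published scenarios, in publication order."""
    return [run_scenario(spec, base, conventions) for spec in SCENARIOS.values()]
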
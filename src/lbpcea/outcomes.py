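"""Incremental cost-effectiveness outcomes.

Computes incremental cost and QALYs between two strategies, the ICER with
quadrant-aware dominance classification, annualized per-person values,
cost-effectiveness-plane exports and a simple resource-utilization summary.

Dominance vocabulary: the intervention *dominates* when it is cheaper and
more effective (south-east quadrant); the comparator dominates strictly
when the intervention is costlier and less effective (north-west).  A
south-west outcome (cheaper but less effective) is not strict dominance;
following the source publication's convention it is labelled
comparator-dominant but flagged ``non_strict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import HIGH, LOW, T_W1_4, CohortTrace, StrategyTotals
from .parameters import ModelParameters

__all__ = [
    "DOMINANCE_LABELS",
    "IncrementalResult",
    "icer",
    "incremental_outcomes",
    "annualize",
    "resource_utilization",
    "ce_plane_points",
]

DOMINANCE_LABELS = (
    "icer",
    "intervention_dominant",
    "comparator_dominant",
    "comparator_dominant_sw",
    "indeterminate",
    "undefined_ratio",
)

_EPS = 1e-12


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental outcome of intervention vs comparator for one scenario."""

    scenario_id: str
    delta_cost: float
    delta_qalys: float
    icer_value: float | None
    dominance_label: str
    non_strict: bool = False
    intervention: StrategyTotals | None = field(default=None, repr=False, compare=False)
    comparator: StrategyTotals | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dominance_label not in DOMINANCE_LABELS:
            raise ValueError(f"unknown dominance label {self.dominance_label!r}")
        if (self.icer_value is not None) != (self.dominance_label == "icer"):
            raise ValueError("icer_value must be present exactly when the label is 'icer'")

    def tagged(self, scenario_id: str) -> "IncrementalResult":
        return replace(self, scenario_id=scenario_id)


def icer(delta_cost: float, delta_qalys: float) -> tuple[float | None, str, bool]:
    """Classify an incremental outcome: (icer value or None, label, non_strict).

    North-east (costlier, more effective) yields the ratio; south-east is
    intervention-dominant; north-west comparator-dominant; south-west is
    labelled comparator-dominant with the ``non_strict`` flag.  A zero QALY
    difference with a cost difference is an undefined ratio, signalled by
    label rather than by exception.
    """
    dc, de = delta_cost, delta_qalys
    if abs(de) <= _EPS:
        if abs(dc) <= _EPS:
            return None, "indeterminate", False
        return None, "undefined_ratio", False
    if de > 0:
        if dc > _EPS:
            return dc / de, "icer", False
        return None, "intervention_dominant", abs(dc) <= _EPS
    # de < 0
    if dc >= -_EPS:
        return None, "comparator_dominant", abs(dc) <= _EPS
    return None, "comparator_dominant_sw", True


def incremental_outcomes(
    intervention: StrategyTotals,
    comparator: StrategyTotals,
    scenario_id: str = "base",
) -> IncrementalResult:
    """Incremental cost, QALYs and ICER, computed on unrounded internals."""
    if intervention.horizon_cycles != comparator.horizon_cycles:
        raise ValueError("strategies must be run over the same horizon")
    dc = intervention.discounted_cost - comparator.discounted_cost
    de = intervention.discounted_qalys - comparator.discounted_qalys
    value, label, non_strict = icer(dc, de)
    return IncrementalResult(
        scenario_id=scenario_id,
        delta_cost=dc,
        delta_qalys=de,
        icer_value=value,
        dominance_label=label,
        non_strict=non_strict,
        intervention=intervention,
        comparator=comparator,
    )


def annualize(totals: StrategyTotals, horizon_years: float) -> tuple[float, float]:
    """Per-person-per-year (cost, QALYs) over the model horizon."""
    if horizon_years < 1:
        raise ValueError("horizon_years must be at least 1")
    return totals.discounted_cost / horizon_years, totals.discounted_qalys / horizon_years


def resource_utilization(
    trace: CohortTrace,
    params: ModelParameters,
    gp_contacts_per_cycle: float = 1.0,
    specialist_contacts_per_cycle: float = 1.0,
) -> dict[str, float]:
    """Primary-care contact and prescription counts per year.

    Convention (configurable, documented rather than asserted): every
    person-cycle spent in a consultation-incurring state (untreated low or
    high impact, or the first treatment cycle) incurs one GP and one
    specialist contact; prescriptions are counted as entries into the first
    treatment cycle.
    """
    years = trace.n_cycles / params.cycles_per_year
    person_cycles = trace.corrected[:, [LOW, HIGH, T_W1_4]].sum()
    entries = trace.raw[1:, T_W1_4].sum()
    return {
        "convention": "per person-cycle in LOW/HIGH/T_W1_4; prescriptions = T_W1_4 entries",
        "gp_consultations_per_year": gp_contacts_per_cycle * person_cycles / years,
        "specialist_consultations_per_year": specialist_contacts_per_cycle * person_cycles / years,
        "prescriptions_per_year": entries / years,
    }


def ce_plane_points(
    results: list[IncrementalResult],
    thresholds: tuple[float, ...] = (10_000.0, 20_000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cost-effectiveness-plane table and willingness-to-pay threshold lines.

    Returns one point per incremental result (ΔQALYs on the abscissa, Δcost
    on the ordinate) plus line specifications (slope = EUR/QALY) that any
    plotting layer can render.
    """
    points = pd.DataFrame(
        [
            {
                "scenario_id": r.scenario_id,
                "delta_qalys": r.delta_qalys,
                "delta_cost": r.delta_cost,
                "label": r.dominance_label,
            }
            for r in results
        ],
        columns=["scenario_id", "delta_qalys", "delta_cost", "label"],
    )
    if len(points):
        span = max(1e-3, 1.5 * float(np.abs(points["delta_qalys"]).max()))
    else:
        span = 1e-3
    lines = pd.DataFrame(
        [{"threshold_eur_per_qaly": w, "qalys_at_span": span, "cost_at_span": w * span}
         for w in thresholds]
    )
    return points, lines
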
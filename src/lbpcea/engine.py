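"""Discrete-time Markov cohort engine.

The model is a seven-state discrete-time Markov chain with 4-week cycles:
two untreated pain states (low / high impact), three treatment tunnel
states (weeks 1-4, 4-8, 8-12), temporary remission, and an absorbing
healthy state.  A cohort vector is propagated through a row-stochastic
transition matrix; state membership is life-table (half-cycle) corrected;
per-state costs and utilities are accrued with discounting to produce
per-person totals.

Residual row mass
-----------------
The printed low- and high-impact rows do not close: the literature-derived
entries plus the treatment-entry assumption sum to 0.95 (low) and 0.90
(high).  Three resolution policies are provided:

``raw_entry`` (default)
    Reads the treatment-entry assumptions as *raw* shares of the row mass
    left over after the literature entries (75% of 0.80 -> 0.60 for low,
    80% of 0.90 -> 0.72 for high); the unconverted remainder stays in the
    untreated state.  This is the reading consistent with the source's
    footnote that assumption values are raw numbers, and it reproduces the
    published incremental results most closely.
``renormalize_non_treatment``
    Keeps the printed entry probability fixed and scales the remaining
    printed destinations proportionally to fill the row.
``self_loop``
    Keeps all printed entries verbatim and adds the deficit to the
    diagonal.

In all policies the usual-care end-of-treatment row (which sums to 0.95)
is closed by assigning the 0.05 deficit to remission, consistent with the
text that only the healthy-transition probability differs between
strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import DTC, TAU, ModelParameters

__all__ = [
    "STATE_LABELS",
    "LOW", "HIGH", "T_W1_4", "T_W4_8", "T_W8_12", "REMISSION", "HEALTHY",
    "RESIDUAL_POLICIES",
    "StateSpace",
    "Conventions",
    "TransitionMatrix",
    "CohortTrace",
    "ValueSchedule",
    "StrategyTotals",
    "build_transition_matrix",
    "run_cohort",
    "discount_factor",
    "discount_factors",
    "value_schedule",
    "accrue_values",
    "run_strategy",
]

STATE_LABELS = ("LOW", "HIGH", "T_W1_4", "T_W4_8", "T_W8_12", "REMISSION", "HEALTHY")
LOW, HIGH, T_W1_4, T_W4_8, T_W8_12, REMISSION, HEALTHY = range(7)

RESIDUAL_POLICIES = ("raw_entry", "renormalize_non_treatment", "self_loop")

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class StateSpace:
    """Ordered seven-state space; healthy is the only absorbing state."""

    labels: tuple[str, ...] = STATE_LABELS
    absorbing: tuple[bool, ...] = (False, False, False, False, False, False, True)

    def __post_init__(self) -> None:
        if len(self.labels) != 7 or len(self.absorbing) != 7:
            raise ValueError("state space must have exactly 7 states")
        if tuple(i for i, a in enumerate(self.absorbing) if a) != (HEALTHY,):
            raise ValueError("HEALTHY must be the only absorbing state")

    def index(self, label: str) -> int:
        return self.labels.index(label)


LBP_STATES = StateSpace()


@dataclass(frozen=True)
class Conventions:
    """Model-run conventions the source leaves unstated.

    The defaults form the *reproduction profile*: the combination that best
    reproduces the published incremental results (see the methods note).
    ``utility_discount_rate=None`` means "use the cost rate".
    """

    residual_policy: str = "raw_entry"
    correction: str = "life-table"        # life-table | begin | end
    discount_step: str = "cycle"          # cycle (compound per cycle) | annual (step)
    utility_discount_rate: float | None = 0.0

    def __post_init__(self) -> None:
        if self.residual_policy not in RESIDUAL_POLICIES:
            raise ValueError(f"unknown residual policy {self.residual_policy!r}")
        if self.correction not in ("life-table", "begin", "end"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.discount_step not in ("cycle", "annual"):
            raise ValueError(f"unknown discount step {self.discount_step!r}")


REPRODUCTION_PROFILE = Conventions()
# Guideline profile: discount costs and utilities identically at the ledger rate.
GUIDELINE_PROFILE = Conventions(utility_discount_rate=None)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 7x7 transition matrix for one strategy."""

    strategy: str
    entries: np.ndarray
    residual_policy: str
    resolutions: tuple[str, ...] = ()
    states: StateSpace = field(default=LBP_STATES)

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (7, 7):
            raise ValueError("transition matrix must be 7x7")
        if (m < -_ROW_TOL).any() or (m > 1 + 1e-9).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = m.sum(axis=1)
        if (sums > 1 + 1e-9).any():
            raise ValueError(f"row mass exceeds 1: {sums}")
        if np.abs(sums - 1.0).max() > _ROW_TOL:
            raise ValueError(f"rows must sum to 1 within {_ROW_TOL}: {sums}")
        if m[HEALTHY, HEALTHY] != 1.0 or m[HEALTHY, :HEALTHY].any():
            raise ValueError("HEALTHY must be a unit self-loop")
        for tunnel, pred in ((T_W4_8, T_W1_4), (T_W8_12, T_W4_8)):
            feeders = [i for i in range(7) if i != pred and m[i, tunnel] > 0]
            if feeders:
                raise ValueError(f"tunnel state {STATE_LABELS[tunnel]} entered from {feeders}")
        object.__setattr__(self, "entries", m)

    def row(self, label: str) -> np.ndarray:
        return self.entries[self.states.index(label)]


def _close_untreated_row(row: np.ndarray, state: int, entry_raw: float,
                         policy: str, notes: list[str]) -> None:
    """Resolve the under-specified low/high-impact row in place."""
    label = STATE_LABELS[state]
    literature_mass = row.sum()  # entries already placed, excluding treatment
    if policy == "raw_entry":
        remainder = 1.0 - literature_mass
        row[T_W1_4] = entry_raw * remainder
        row[state] += (1.0 - entry_raw) * remainder
        notes.append(
            f"{label}: raw entry share {entry_raw} of remainder {remainder:.2f} -> "
            f"P({label}->T_W1_4) = {row[T_W1_4]:.4f}, residual {((1-entry_raw)*remainder):.4f} stays"
        )
    elif policy == "renormalize_non_treatment":
        row[T_W1_4] = entry_raw
        deficit = 1.0 - row.sum()
        scale = (literature_mass + deficit) / literature_mass
        for j in range(7):
            if j != T_W1_4 and row[j] > 0:
                row[j] *= scale
        notes.append(f"{label}: entry fixed at {entry_raw}, other destinations scaled by {scale:.4f}")
    elif policy == "self_loop":
        row[T_W1_4] = entry_raw
        deficit = 1.0 - row.sum()
        row[state] += deficit
        notes.append(f"{label}: deficit {deficit:.4f} added to self-loop")


def build_transition_matrix(
    params: ModelParameters,
    strategy: str,
    residual_policy: str = REPRODUCTION_PROFILE.residual_policy,
) -> TransitionMatrix:
    """Construct the per-strategy transition matrix from the ledger.

    Rows that are fully printed (the treatment tunnel rows, the remission
    row, the app strategy's end-of-treatment row) appear verbatim; rows with
    missing mass are resolved per ``residual_policy`` and each resolution is
    recorded on the result.
    """
    if strategy not in (DTC, TAU):
        raise ValueError(f"unknown strategy {strategy!r}")
    if residual_policy not in RESIDUAL_POLICIES:
        raise ValueError(f"unknown residual policy {residual_policy!r}")
    notes: list[str] = []
    m = np.zeros((7, 7))

    m[LOW, LOW] = params.p_low_low
    m[LOW, HIGH] = params.p_low_high
    m[LOW, REMISSION] = params.p_low_remission
    _close_untreated_row(m[LOW], LOW, params.p_low_treat, residual_policy, notes)

    m[HIGH, LOW] = params.p_high_low
    m[HIGH, HIGH] = params.p_high_high
    _close_untreated_row(m[HIGH], HIGH, params.p_high_treat, residual_policy, notes)

    for month, (row_idx, next_idx) in enumerate(((T_W1_4, T_W4_8), (T_W4_8, T_W8_12)), start=1):
        d = params.dropout_probs(strategy, month)
        m[row_idx, LOW] = d.to_low
        m[row_idx, HIGH] = d.to_high
        m[row_idx, REMISSION] = d.to_remission
        m[row_idx, next_idx] = d.continue_prob

    m[T_W8_12, LOW] = params.p_end_low
    m[T_W8_12, HIGH] = params.p_end_high
    m[T_W8_12, REMISSION] = params.p_end_remission
    m[T_W8_12, HEALTHY] = params.p_end_healthy[strategy]
    deficit = 1.0 - m[T_W8_12].sum()
    if deficit > 1e-9:
        m[T_W8_12, REMISSION] += deficit
        notes.append(f"T_W8_12: deficit {deficit:.4f} assigned to REMISSION "
                     f"(-> {m[T_W8_12, REMISSION]:.4f})")
    elif deficit < -1e-9:
        raise ValueError(f"T_W8_12 row mass exceeds 1 by {-deficit:.2e}")

    m[REMISSION, REMISSION] = params.p_rem_stay
    m[REMISSION, LOW] = params.p_rem_low
    m[REMISSION, HIGH] = params.p_rem_high

    m[HEALTHY, HEALTHY] = 1.0

    # Clean tiny float residue so rows close to machine precision.
    m /= m.sum(axis=1, keepdims=True)
    return TransitionMatrix(strategy=strategy, entries=m,
                            residual_policy=residual_policy, resolutions=tuple(notes))


@dataclass(frozen=True)
class CohortTrace:
    """Cohort state membership per cycle, raw and life-table corrected."""

    raw: np.ndarray        # (n_cycles+1, 7) persons, raw[0] = start
    corrected: np.ndarray  # (n_cycles, 7) half-cycle averages
    cohort_size: float

    @property
    def n_cycles(self) -> int:
        return self.corrected.shape[0]


def transition_entries(tm: "TransitionMatrix | np.ndarray") -> np.ndarray:
    """Accept a TransitionMatrix or a bare row-stochastic square array."""
    if isinstance(tm, TransitionMatrix):
        return tm.entries
    m = np.asarray(tm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("transition matrix must be square")
    if (m < 0).any() or np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("rows must be probability distributions")
    return m


def run_cohort(tm: "TransitionMatrix | np.ndarray", start: Sequence[float],
               n_cycles: int) -> CohortTrace:
    """Propagate a starting cohort through ``n_cycles`` transitions."""
    entries = transition_entries(tm)
    start = np.asarray(start, dtype=float)
    if start.shape != (entries.shape[0],):
        raise ValueError("start vector does not match the state space")
    if (start < 0).any():
        raise ValueError("start entries must be non-negative")
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    raw = np.empty((n_cycles + 1, entries.shape[0]))
    raw[0] = start
    for t in range(n_cycles):
        raw[t + 1] = raw[t] @ entries
    corrected = 0.5 * (raw[:-1] + raw[1:])
    return CohortTrace(raw=raw, corrected=corrected, cohort_size=float(start.sum()))


def discount_factor(cycle_index: int, annual_rate: float, cycles_per_year: int = 13,
                    step: str = "cycle") -> float:
    """Discount factor for one cycle index.

    ``cycle`` step compounds continuously per cycle, (1+r)^(-t/cycles_per_year);
    ``annual`` step discounts in whole-year blocks, (1+r)^(-floor(t/cpy)).
    Cycle 0 is undiscounted either way.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    if step == "cycle":
        return float((1.0 + annual_rate) ** (-cycle_index / cycles_per_year))
    if step == "annual":
        return float((1.0 + annual_rate) ** (-(cycle_index // cycles_per_year)))
    raise ValueError(f"unknown discount step {step!r}")


def discount_factors(n_cycles: int, annual_rate: float, cycles_per_year: int = 13,
                     step: str = "cycle", correction: str = "life-table") -> np.ndarray:
    """Vector of per-cycle discount factors aligned with the value rows.

    With life-table or begin counting, cycle t is valued at index t (the
    first accrual row is undiscounted); with end counting at index t+1.
    """
    offset = 1 if correction == "end" else 0
    idx = np.arange(offset, n_cycles + offset, dtype=float)
    if step == "cycle":
        return (1.0 + annual_rate) ** (-idx / cycles_per_year)
    return (1.0 + annual_rate) ** (-np.floor(idx / cycles_per_year))


@dataclass(frozen=True)
class ValueSchedule:
    """Per-state cycle costs (EUR) and utilities for one strategy."""

    strategy: str
    state_costs: np.ndarray        # (7,)
    utilities: np.ndarray          # (7,)
    indirect_costs: np.ndarray     # (7,) wage-linked component of state_costs
    cycle_length_years: float = 4.0 / 52.0

    def __post_init__(self) -> None:
        for name, v in (("state_costs", self.state_costs), ("utilities", self.utilities),
                        ("indirect_costs", self.indirect_costs)):
            arr = np.asarray(v, dtype=float)
            if arr.shape != (7,):
                raise ValueError(f"{name} must be a 7-vector")
            object.__setattr__(self, name, arr)
        if (self.utilities < 0).any() or (self.utilities > 1).any():
            raise ValueError("utilities must lie in [0, 1]")
        if self.state_costs[REMISSION] != 0 or self.state_costs[HEALTHY] != 0:
            raise ValueError("remission and healthy must be zero-cost states")


def value_schedule(params: ModelParameters, strategy: str) -> ValueSchedule:
    """Assemble the per-state value schedule for a strategy from the ledger."""
    return ValueSchedule(
        strategy=strategy,
        state_costs=np.array([params.state_costs[strategy][s] for s in STATE_LABELS]),
        utilities=np.array([params.utilities[strategy][s] for s in STATE_LABELS]),
        indirect_costs=np.array([params.indirect_state_cost(s) for s in STATE_LABELS]),
        cycle_length_years=1.0 / params.cycles_per_year,
    )


@dataclass(frozen=True)
class StrategyTotals:
    """Discounted per-person totals with per-state and component breakdowns."""

    strategy: str
    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    per_state_cost: np.ndarray
    per_state_qalys: np.ndarray
    indirect_cost: float
    direct_cost: float
    healthy_count_at_horizon: int
    horizon_cycles: int
    cohort_size: float


def accrue_values(
    trace: CohortTrace,
    schedule: ValueSchedule,
    annual_rate: float,
    utility_rate: float | None = None,
    cycles_per_year: int = 13,
    discount_step: str = "cycle",
    correction: str = "life-table",
) -> StrategyTotals:
    """Accrue discounted costs and QALYs over a cohort trace.

    Each cycle contributes membership x per-state value, where membership is
    the life-table-corrected count (or the raw start/end-of-cycle count for
    the ``begin``/``end`` conventions).  Costs discount at ``annual_rate``;
    utilities at ``utility_rate`` (defaulting to the cost rate).  Totals are
    per person (divided by the cohort size).
    """
    if utility_rate is None:
        utility_rate = annual_rate
    n = trace.n_cycles
    if correction == "life-table":
        occ = trace.corrected
    elif correction == "begin":
        occ = trace.raw[:-1]
    elif correction == "end":
        occ = trace.raw[1:]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    dfc = discount_factors(n, annual_rate, cycles_per_year, discount_step, correction)
    dfu = discount_factors(n, utility_rate, cycles_per_year, discount_step, correction)

    size = trace.cohort_size
    per_state_cost = (occ * dfc[:, None]).sum(axis=0) * schedule.state_costs / size
    per_state_qalys = ((occ * dfu[:, None]).sum(axis=0) * schedule.utilities
                       * schedule.cycle_length_years / size)
    undisc_occ = occ.sum(axis=0)
    undisc_cost = float(undisc_occ @ schedule.state_costs / size)
    undisc_qalys = float(undisc_occ @ schedule.utilities * schedule.cycle_length_years / size)
    indirect = float((occ * dfc[:, None]).sum(axis=0) @ schedule.indirect_costs / size)
    total_cost = float(per_state_cost.sum())
    healthy_final = int(np.floor(trace.raw[-1, HEALTHY] + 0.5))
    return StrategyTotals(
        strategy=schedule.strategy,
        discounted_cost=total_cost,
        discounted_qalys=float(per_state_qalys.sum()),
        undiscounted_cost=undisc_cost,
        undiscounted_qalys=undisc_qalys,
        per_state_cost=per_state_cost,
        per_state_qalys=per_state_qalys,
        indirect_cost=indirect,
        direct_cost=round(total_cost - indirect, 12),
        healthy_count_at_horizon=healthy_final,
        horizon_cycles=n,
        cohort_size=size,
    )


def start_vector(params: ModelParameters) -> np.ndarray:
    """Starting cohort as a 7-vector (LOW, HIGH, REMISSION populated)."""
    v = np.zeros(7)
    v[LOW], v[HIGH], v[REMISSION] = params.start_distribution
    return v


def run_strategy(
    params: ModelParameters,
    strategy: str,
    n_cycles: int | None = None,
    conventions: Conventions = REPRODUCTION_PROFILE,
) -> StrategyTotals:
    """Full pipeline for one strategy: matrix -> trace -> discounted totals."""
    if n_cycles is None:
        n_cycles = params.horizon_years * params.cycles_per_year
    tm = build_transition_matrix(params, strategy, conventions.residual_policy)
    trace = run_cohort(tm, start_vector(params), n_cycles)
    return accrue_values(
        trace,
        value_schedule(params, strategy),
        annual_rate=params.discount_rate,
        utility_rate=conventions.utility_discount_rate,
        cycles_per_year=params.cycles_per_year,
        discount_step=conventions.discount_step,
        correction=conventions.correction,
    )
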
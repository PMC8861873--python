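"""Model parameter ledger for the low-back-pain cost-utility model.

Every number here is a printed model input: transition probabilities and
quality-of-life utilities of the seven-state Markov chain, German unit costs
(2021 EUR) and the per-state cycle costs composed from them, the discount
rate, the time horizon and the starting cohort.  The closed-form
compositions that generate derived unit costs (physiotherapy cycle cost,
daily wage, treatment-entry state cost) and the dropout-splitting rule that
turns a monthly attrition rate into treatment-exit transition probabilities
live here too, so that sensitivity analyses can re-derive linked quantities
instead of editing them independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

__all__ = [
    "DTC",
    "TAU",
    "STRATEGIES",
    "DropoutProbs",
    "ModelParameters",
    "base_parameters",
    "dropout_split",
    "physiotherapy_cycle_cost",
    "daily_wage",
    "treatment_entry_cost",
    "round_cents",
]

DTC = "DTC"  # digital therapeutic care (app) strategy
TAU = "TAU"  # treatment as usual (face-to-face physiotherapy)
STRATEGIES = (DTC, TAU)


def round_cents(value: float) -> float:
    """Round a monetary amount to cents, half away from zero.

    Matches every printed derived cost in the ledger (e.g. 6 physiotherapy
    sessions -> 149.33, daily wage 3092/21 -> 147.24).
    """
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _round4(value: float) -> float:
    return float(Decimal(repr(float(value))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DropoutProbs:
    """Destination probabilities for one treatment-cycle transition.

    ``continue_prob`` is the probability of proceeding to the next tunnel
    state; dropouts split between temporary remission and the two untreated
    pain states.  The four fields sum to exactly 1 before display rounding.
    """

    continue_prob: float
    to_remission: float
    to_low: float
    to_high: float

    def rounded(self, ndigits: int = 4) -> "DropoutProbs":
        """Round the exit probabilities and keep the row closed.

        The continue probability is recomputed as the complement of the
        rounded exits, which is how the printed 4-decimal rows stay
        row-stochastic (e.g. 0.0514 + 0.0111 + 0.0625 + 0.875 = 1).
        """
        lo, hi, rm = _round4(self.to_low), _round4(self.to_high), _round4(self.to_remission)
        return DropoutProbs(continue_prob=1.0 - lo - hi - rm, to_remission=rm, to_low=lo, to_high=hi)


def dropout_split(
    attrition: float,
    remission_share: float = 0.5,
    low_trajectory_share: float = 0.822,
) -> DropoutProbs:
    """Split a monthly attrition rate into treatment-exit probabilities.

    A fraction ``attrition`` leaves the program; of those, ``remission_share``
    enter temporary remission and the rest return to their pain trajectory,
    ``low_trajectory_share`` of them to low-impact and the remainder to
    high-impact pain.

    Raises
    ------
    ValueError
        If any input lies outside [0, 1].
    """
    for name, v in (("attrition", attrition), ("remission_share", remission_share),
                    ("low_trajectory_share", low_trajectory_share)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    to_rem = attrition * remission_share
    nonrem = attrition * (1.0 - remission_share)
    return DropoutProbs(
        continue_prob=1.0 - attrition,
        to_remission=to_rem,
        to_low=nonrem * low_trajectory_share,
        to_high=nonrem * (1.0 - low_trajectory_share),
    )


def physiotherapy_cycle_cost(
    n_sessions: int,
    session_price: float = 21.11,
    prescription_charge: float = 10.0,
    copay_rate: float = 0.10,
) -> float:
    """Cost of one physiotherapy treatment cycle including patient copays.

    ``n_sessions`` sessions at ``session_price`` each, a proportional own
    share of ``copay_rate`` per session, plus a one-time prescription
    charge; rounded half-up to cents.  A prescription implies at least one
    session, so ``n_sessions == 0`` is rejected.
    """
    if n_sessions < 1:
        raise ValueError("a physiotherapy prescription implies at least one session")
    if session_price < 0 or prescription_charge < 0 or copay_rate < 0:
        raise ValueError("prices and copay rate must be non-negative")
    return round_cents(n_sessions * session_price * (1.0 + copay_rate) + prescription_charge)


def daily_wage(monthly_gross: float, working_days: int = 21) -> float:
    """Gross daily wage under the human-capital approach (cents, half-up)."""
    if working_days < 1:
        raise ValueError("working_days must be a positive count")
    if monthly_gross < 0:
        raise ValueError("monthly_gross must be non-negative")
    return round_cents(monthly_gross / working_days)


# Program components of the first treatment cycle: the 3-month app access
# price (DTC) and the 6-session physiotherapy cycle cost (TAU).  These are
# what the deterministic sensitivity analysis substitutes.
_BASE_PROGRAM_COMPONENT = {DTC: 239.96, TAU: 149.33}


def treatment_entry_cost(strategy: str, program_cost: float, params: "ModelParameters") -> float:
    """Recompose the first-treatment-cycle state cost for a new program price.

    The base state cost keeps its consultation, pharmacotherapy, diagnostic
    and wage components; only the program component (app access for DTC,
    the physiotherapy cycle for TAU) is replaced by ``program_cost``.
    """
    if program_cost < 0:
        raise ValueError("program_cost must be non-negative")
    base_state_cost = params.state_costs[strategy]["T_W1_4"]
    return round_cents(base_state_cost - _BASE_PROGRAM_COMPONENT[strategy] + program_cost)


@dataclass(frozen=True)
class ModelParameters:
    """The complete printed parameter ledger.

    Immutable; sensitivity and scenario analyses derive variants with
    :func:`dataclasses.replace` plus the composition operations above.
    Probabilities are stored at printed 4-decimal precision.
    """

    # --- untreated-state transition inputs -------------------------------
    # Literature-derived entries of the low/high-impact rows.
    p_low_low: float = 0.16
    p_low_high: float = 0.01
    p_low_remission: float = 0.03
    p_high_low: float = 0.02
    p_high_high: float = 0.08
    # Treatment-entry assumptions ("75%"/"80%"), stored on the raw scale:
    # the share of the row mass not fixed by the literature entries that
    # enters treatment (see engine residual policies).
    p_low_treat: float = 0.75
    p_high_treat: float = 0.80

    # --- treatment dynamics ----------------------------------------------
    # Monthly attrition after month one and month two, per strategy.
    attrition: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {DTC: (0.125, 0.125), TAU: (0.065, 0.043)}
    )
    remission_share: float = 0.5          # dropouts entering temporary remission
    low_trajectory_share: float = 0.822   # non-remission dropouts returning to low impact

    # End-of-treatment row (treatment weeks 8-12).
    p_end_low: float = 0.235
    p_end_high: float = 0.051
    p_end_remission: float = 0.614
    p_end_healthy: Mapping[str, float] = field(default_factory=lambda: {DTC: 0.10, TAU: 0.05})

    # Temporary-remission row: 61.4% recurrence split 82.2%/17.8%.
    p_rem_stay: float = 0.386
    p_rem_low: float = 0.505
    p_rem_high: float = 0.109

    # --- quality-of-life utilities (per state, per strategy) -------------
    utilities: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        DTC: {"LOW": 0.655, "HIGH": 0.610, "T_W1_4": 0.655, "T_W4_8": 0.699,
              "T_W8_12": 0.748, "REMISSION": 0.806, "HEALTHY": 0.806},
        TAU: {"LOW": 0.655, "HIGH": 0.610, "T_W1_4": 0.655, "T_W4_8": 0.717,
              "T_W8_12": 0.729, "REMISSION": 0.806, "HEALTHY": 0.806},
    })

    # --- unit costs (2021 EUR) -------------------------------------------
    app_cost: float = 239.96              # one-time 3-month app access
    gp_consultation: float = 20.47
    specialist_consultation: float = 21.36
    physio_session_price: float = 21.11
    physio_sessions: int = 6
    prescription_charge: float = 10.0
    copay_rate: float = 0.10
    pharmacotherapy: float = 16.81        # per cycle
    diagnostics: float = 29.24            # per cycle
    monthly_gross_wage: float = 3092.0
    working_days: int = 21

    # --- per-state cycle costs (EUR per person-cycle) --------------------
    state_costs: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        DTC: {"LOW": 441.72, "HIGH": 588.96, "T_W1_4": 475.08, "T_W4_8": 16.81,
              "T_W8_12": 16.81, "REMISSION": 0.0, "HEALTHY": 0.0},
        TAU: {"LOW": 441.72, "HIGH": 588.96, "T_W1_4": 377.85, "T_W4_8": 16.81,
              "T_W8_12": 16.81, "REMISSION": 0.0, "HEALTHY": 0.0},
    })
    # Absenteeism days per person-cycle (human-capital indirect component):
    # exact wage decomposition 3/4/1 days for low, high and the first
    # treatment cycle (3 x 147.24 = 441.72, 4 x 147.24 = 588.96).
    absenteeism_days: Mapping[str, float] = field(default_factory=lambda: {
        "LOW": 3.0, "HIGH": 4.0, "T_W1_4": 1.0, "T_W4_8": 0.0,
        "T_W8_12": 0.0, "REMISSION": 0.0, "HEALTHY": 0.0,
    })

    # --- run settings -----------------------------------------------------
    discount_rate: float = 0.03           # annual, applied to costs
    horizon_years: int = 3
    cycles_per_year: int = 13             # 52 weeks / 4-week cycles
    cohort_size: int = 10_000
    start_distribution: tuple[int, int, int] = (5320, 1120, 3560)  # LOW, HIGH, REMISSION

    def __post_init__(self) -> None:
        probs = [self.p_low_low, self.p_low_high, self.p_low_remission, self.p_low_treat,
                 self.p_high_low, self.p_high_high, self.p_high_treat,
                 self.p_end_low, self.p_end_high, self.p_end_remission,
                 self.p_rem_stay, self.p_rem_low, self.p_rem_high,
                 self.remission_share, self.low_trajectory_share, self.copay_rate]
        probs += [p for pair in self.attrition.values() for p in pair]
        probs += list(self.p_end_healthy.values())
        probs += [u for d in self.utilities.values() for u in d.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/utility out of [0, 1]: {p}")
        for d in self.state_costs.values():
            for c in d.values():
                if c < 0:
                    raise ValueError("state costs must be non-negative")
        if sum(self.start_distribution) != self.cohort_size:
            raise ValueError("start distribution must sum to the cohort size")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")

    # Convenience accessors -------------------------------------------------
    def utility(self, state: str, strategy: str) -> float:
        return self.utilities[strategy][state]

    def state_cost(self, state: str, strategy: str = TAU) -> float:
        return self.state_costs[strategy][state]

    def indirect_state_cost(self, state: str) -> float:
        """Wage-linked (absenteeism) component of the per-state cycle cost."""
        wage = daily_wage(self.monthly_gross_wage, self.working_days)
        return round_cents(self.absenteeism_days[state] * wage)

    def dropout_probs(self, strategy: str, treatment_month: int) -> DropoutProbs:
        """Printed-precision exit probabilities for treatment month 1 or 2."""
        a = self.attrition[strategy][treatment_month - 1]
        return dropout_split(a, self.remission_share, self.low_trajectory_share).rounded(4)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


# Provenance: ledger field -> printed source, kept with the parameters so a
# loaded configuration can be traced cell by cell.
PROVENANCE: dict[str, str] = {
    "p_low_low": "transition table, Low to Low",
    "p_low_high": "transition table, Low to High",
    "p_low_treat": "transition table, Low to treatment weeks 1-4 (assumption, raw share)",
    "p_low_remission": "transition table, Low to Remission",
    "p_high_low": "transition table, High to Low",
    "p_high_high": "transition table, High to High",
    "p_high_treat": "transition table, High to treatment weeks 1-4 (assumption, raw share)",
    "attrition": "trial attrition: app 12.5%/12.5%, usual care 6.5%/4.3%",
    "remission_share": "assumed 50% remission among program dropouts",
    "low_trajectory_share": "82.2% of non-remission dropouts return to low impact",
    "p_end_*": "end-of-treatment row 0.235/0.051/0.614; healthy 0.10 app vs 0.05 usual care",
    "p_rem_*": "remission row 0.386/0.505/0.109 (61.4% recurrence)",
    "utilities": "QoL utility table (VR-6D treatment states, SF-6D elsewhere)",
    "unit costs": "cost table: app 239.96, GP 20.47, specialist 21.36, physio session 21.11, "
                  "prescription 10.00 + 10% copay, pharmacotherapy 16.81, diagnostics 29.24, "
                  "monthly gross wage 3092 over 21 working days",
    "state_costs": "cost table, cost per cycle and per state",
    "discount_rate": "3% annual",
    "start_distribution": "hypothetical primary-care cohort of 10,000: 5320/1120/3560",
}

_BASE = ModelParameters()


def base_parameters() -> ModelParameters:
    """Return the printed base-case parameter ledger (immutable singleton)."""
    return _BASE
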
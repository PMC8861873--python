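"""Individual-level microsimulation and perturbed-parameter generation.

The cohort engine is deterministic: it propagates expected state
membership.  This module draws individual patient trajectories from the
same transition matrices, providing an independent Monte-Carlo oracle for
the cohort engine (the mean of simulated occupancies converges to the
cohort trace by the law of large numbers, with binomial standard errors),
plus a generator of randomly perturbed but structurally valid parameter
sets for property testing.

Initial states are assigned by deterministic largest-remainder
apportionment of the starting distribution, so the only randomness is in
the transitions.  Per-cycle values mirror the cohort engine's life-table
correction: each cycle is valued at the mean of the values of the states
occupied at its start and end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .engine import (
    Conventions,
    REPRODUCTION_PROFILE,
    TransitionMatrix,
    ValueSchedule,
    discount_factors,
    transition_entries,
)
from .parameters import ModelParameters
from .sensitivity import DSABound

__all__ = [
    "TrajectorySet",
    "simulate_individuals",
    "microsim_totals",
    "perturb_parameters",
    "apportion",
]


def matrix_fingerprint(tm: "TransitionMatrix | np.ndarray") -> str:
    h = hashlib.sha256()
    if isinstance(tm, TransitionMatrix):
        h.update(tm.strategy.encode())
    h.update(np.ascontiguousarray(transition_entries(tm)).tobytes())
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class TrajectorySet:
    """State index sequences for n individuals over n_cycles transitions."""

    sequences: np.ndarray   # (n, n_cycles+1) int8 state indices
    seed: int
    fingerprint: str        # hash of the generating matrix
    empty: bool = False

    @property
    def n(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.sequences.shape[1] - 1

    def occupancy(self) -> np.ndarray:
        """Fraction of individuals in each state at each time point,
        shape (n_cycles+1, 7)."""
        counts = np.stack([(self.sequences == s).sum(axis=0) for s in range(7)], axis=1)
        return counts / max(self.n, 1)


def apportion(start: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n individuals to the start vector."""
    start = np.asarray(start, dtype=float)
    if start.sum() <= 0:
        raise ValueError("start vector must have positive mass")
    quota = start / start.sum() * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_individuals(
    tm: "TransitionMatrix | np.ndarray",
    start: np.ndarray,
    n: int,
    n_cycles: int,
    seed: int,
) -> TrajectorySet:
    """Draw n individual trajectories from the transition matrix.

    Reproducible given (seed, matrix, start, n, n_cycles); n = 0 returns an
    empty, flagged set rather than raising.
    """
    entries = transition_entries(tm)
    n_states = entries.shape[0]
    fp = matrix_fingerprint(tm)
    if n == 0:
        return TrajectorySet(sequences=np.empty((0, n_cycles + 1), dtype=np.int8),
                             seed=seed, fingerprint=fp, empty=True)
    if n < 0:
        raise ValueError("n must be non-negative")
    counts = apportion(np.asarray(start, dtype=float), n)
    state = np.repeat(np.arange(n_states, dtype=np.int8), counts)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(entries, axis=1)
    cum[:, -1] = 1.0  # guard against float residue in the last column
    seq = np.empty((n, n_cycles + 1), dtype=np.int8)
    seq[:, 0] = state
    for t in range(n_cycles):
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int8)
        for s in range(n_states):
            mask = state == s
            if mask.any():
                nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        state = nxt
        seq[:, t + 1] = state
    return TrajectorySet(sequences=seq, seed=seed, fingerprint=fp)


def microsim_totals(
    ts: TrajectorySet,
    schedule: ValueSchedule,
    annual_rate: float,
    utility_rate: float | None = None,
    cycles_per_year: int = 13,
    conventions: Conventions = REPRODUCTION_PROFILE,
) -> dict[str, float]:
    """Mean per-person discounted cost and QALYs with Monte-Carlo SEs.

    Cycle t is valued at the mean of the start- and end-of-cycle state
    values (mirroring the cohort life-table correction) and discounted at
    the cycle's factor.
    """
    if utility_rate is None:
        utility_rate = annual_rate
    n, T = ts.n, ts.n_cycles
    if n == 0:
        raise ValueError("cannot summarise an empty trajectory set")
    dfc = discount_factors(T, annual_rate, cycles_per_year, conventions.discount_step)
    dfu = discount_factors(T, utility_rate, cycles_per_year, conventions.discount_step)
    c_states = schedule.state_costs[ts.sequences]           # (n, T+1)
    u_states = schedule.utilities[ts.sequences]
    c_cycle = 0.5 * (c_states[:, :-1] + c_states[:, 1:])    # (n, T)
    u_cycle = 0.5 * (u_states[:, :-1] + u_states[:, 1:])
    cost = c_cycle @ dfc
    qalys = (u_cycle @ dfu) * schedule.cycle_length_years
    return {
        "mean_cost": float(cost.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n)),
        "mean_qalys": float(qalys.mean()),
        "se_qalys": float(qalys.std(ddof=1) / np.sqrt(n)),
        "n": n,
    }


def perturb_parameters(
    base: ModelParameters,
    ranges: list[DSABound],
    n_sets: int,
    seed: int,
) -> list[ModelParameters]:
    """Draw structurally valid parameter sets uniformly within DSA ranges.

    Each draw is recomposed through the same linkage rules the DSA uses
    (treatment-entry costs, dropout splits, recurrence recomposition), so
    every returned set builds row-stochastic matrices by construction.
    """
    if n_sets < 0:
        raise ValueError("n_sets must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        p = base
        for b in ranges:
            value = float(rng.uniform(b.low, b.high))
            if b.parameter_id == "physio_sessions":
                value = int(rng.integers(int(b.low), int(b.high) + 1))
            p = b.apply(p, value)
        out.append(p)
    return out
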
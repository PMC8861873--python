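# lbpcea

Cost-utility analysis of a prescription digital therapeutic care (DTC) app
versus treatment as usual (TAU, face-to-face physiotherapy) for adults with
non-specific low back pain in the German statutory health insurance, as a
tested, reusable Python pipeline.  It is aimed at health-economic modellers
who want to rerun, audit or extend the published decision model rather than
re-type it from tables.

## The model

A discrete-time Markov cohort model with seven health states and 4-week
cycles:

```
LOW  — untreated low-impact pain        T_W1_4  — treatment weeks 1–4 ┐
HIGH — untreated high-impact pain       T_W4_8  — treatment weeks 4–8 ├ tunnel
REMISSION — temporary, episodic relief  T_W8_12 — treatment weeks 8–12 ┘
HEALTHY — lasting recovery (absorbing)
```

A cohort of 10,000 patients starts as 5320 / 1120 / 3560 in LOW / HIGH /
REMISSION and is propagated through a row-stochastic matrix **P** per
strategy: `x_{t+1} = x_t P`.  Treatment is a three-cycle tunnel with monthly
attrition *a* (12.5%/12.5% for the app, 6.5%/4.3% for usual care); dropouts
split as *a*/2 into remission and *a*/2 back onto their pain trajectory
(82.2% low-impact, 17.8% high-impact).  Completing treatment opens the only
route to HEALTHY (probability 0.10 with the app vs 0.05 under usual care).
State membership is life-table corrected, `(x_t + x_{t+1})/2`, and valued
with per-state cycle costs (2021 EUR, societal perspective including
absenteeism at the gross daily wage) and QALY utilities.  Outcomes:

- ΔC, ΔE — incremental discounted cost and QALYs per patient over 3 years,
- ICER = ΔC/ΔE with quadrant-aware dominance labels,
- one-way deterministic sensitivity analysis (tornado ordering),
- scenario suite: horizons of 2/4/5 years, best/worse-case app attrition,
- an individual-level microsimulation used as an independent Monte-Carlo
  oracle for the cohort engine.

## Worked example

```python
import lbpcea as L

params = L.base_parameters()                 # the printed parameter ledger
dtc = L.run_strategy(params, L.DTC)          # 39 cycles, life-table, 3% discounting
tau = L.run_strategy(params, L.TAU)
inc = L.incremental_outcomes(dtc, tau)
print(f"dCost {inc.delta_cost:8.2f} EUR")
print(f"dQALY {inc.delta_qalys:8.4f}")
print(f"ICER  {inc.icer_value:8.2f} EUR/QALY")
print(f"healthy at horizon: {dtc.healthy_count_at_horizon} of 10000")
```

prints

```
dCost   117.67 EUR
dQALY   0.0217
ICER   5416.62 EUR/QALY
healthy at horizon: 4252 of 10000
```

The app strategy costs ≈ €118 more per patient over three years but yields
≈ 0.022 additional QALYs, i.e. ≈ €5,400 per QALY gained — far below common
willingness-to-pay thresholds — and moves 4,252 of 10,000 patients into
lasting recovery (vs 2,622 under usual care).  The same pipeline is
available from the shell:

```bash
lbpcea run-base          # strategy totals, increments, cohort traces
lbpcea run-scenarios     # the published scenario table
lbpcea run-dsa           # one-way DSA / tornado table
lbpcea microsim --seed 7 # Monte-Carlo cross-check of the cohort engine
lbpcea export-ce-plane   # cost-effectiveness plane as CSV
```

Because the source publication leaves several conventions unstated
(how the under-specified transition rows are closed, how discounting
steps), the package exposes them as configuration
(`lbpcea.Conventions`); the default *reproduction profile* is the
combination that best matches the published results, and the methods note
(`docs/methods.md`) documents the evidence and the remaining deviations.

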
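# Methods

## Model

We model non-specific low back pain in a primary-care population as a
discrete-time Markov chain over seven states: untreated low-impact pain
(LOW), untreated high-impact pain (HIGH), three one-cycle treatment tunnel
states (T_W1_4, T_W4_8, T_W8_12 — weeks 1–4, 4–8, 8–12 of a 12-week
program), temporary remission (REMISSION) and an absorbing recovery state
(HEALTHY).  Cycles are 4 weeks; we treat 13 cycles as one year, so a cycle
contributes 1/13 of a year of utility.  There is no death state: the
condition carries no excess mortality and the cohort is middle-aged over a
3-year horizon.  Two strategies share the structure and differ only in
treatment parameters: a digital therapeutic care app (DTC) and face-to-face
physiotherapy (TAU).

Key dynamics, all taken from the printed ledger (`lbpcea.base_parameters()`):

- **Treatment attrition.** Each treatment month, a fraction *a* abandons the
  program (DTC 12.5%/12.5% after months one and two; TAU 6.5%/4.3%).
  Dropouts split: half to REMISSION, the rest back to their pain trajectory
  (82.2% LOW / 17.8% HIGH).  `dropout_split` composes these exactly and
  reproduces the printed 4-decimal rows (e.g. 0.0514/0.0111/0.0625/0.875)
  when the exits are rounded to 4 dp and the continue probability is taken
  as their complement.
- **Recovery.** Only treatment completers can reach HEALTHY: 0.10 per
  completion for DTC vs 0.05 for TAU (the app's assumed behaviour-change
  advantage).  Everyone else leaving the last treatment cycle returns to
  LOW/HIGH (0.235/0.051) or REMISSION.
- **Recurrence.** From REMISSION, 61.4% relapse each cycle, split
  0.505/0.109 to LOW/HIGH; 38.6% stay in remission.

Costs (2021 EUR, societal perspective) attach to states per cycle: LOW
441.72 and HIGH 588.96 (exactly 3 and 4 gross daily wages of 147.24 =
3092/21 — the absenteeism component), first treatment cycle 475.08 (DTC:
app 239.96 + GP 20.47 + specialist 21.36 + pharmacotherapy 16.81 +
diagnostics 29.24 + one day's wage) or 377.85 (TAU, a printed primitive
whose program component is the 6-session physiotherapy cycle 149.33 =
6 × 21.11 × 1.10 + 10), later treatment cycles 16.81, REMISSION and
HEALTHY zero.  Utilities: LOW 0.655, HIGH 0.610, tunnel states
0.655/0.699/0.748 (DTC) vs 0.655/0.717/0.729 (TAU), REMISSION and HEALTHY
0.806.  Derived monetary values round half-up to cents, which reproduces
every printed derived cost (149.33, 102.88, 288.65, 147.24, 132.52,
161.96, 335.08, 535.08, 331.40, 517.17) to the cent; internal arithmetic
is double precision and rounding happens only at output.

## Under-specified conventions and the reproduction profile

The published tables do not close the model by themselves.  Three gaps are
exposed as configuration (`Conventions`) rather than hard-coded; the
default *reproduction profile* is the combination that agrees best with
the published results, chosen once after a systematic grid comparison and
documented here.

**Residual row mass.**  The printed LOW row sums to 0.95 and HIGH to 0.90.
The treatment-entry values ("75%", "80%") are marked as assumptions, and
the source flags their sensitivity bounds as *raw numbers, before the
actual relative transition probability was calculated*.  We therefore read
them, by default (`raw_entry`), as raw shares of the row mass left after
the literature-derived entries: P(LOW→T) = 0.75 × (1 − 0.20) = 0.60 with
the unconverted 0.20 staying in LOW, and P(HIGH→T) = 0.80 × (1 − 0.10) =
0.72.  Two observations support this reading over taking 0.75/0.80
verbatim: the published DSA endpoint at the high app price implies a
discounted first-treatment-cycle occupancy of ≈ 5.5 person-cycles, which
the raw reading yields (5.6) and the verbatim reading does not (5.9); and
the base-case incremental cost lands within 3% under the raw reading
versus +20% verbatim.  The alternative closures
(`renormalize_non_treatment`: keep the entry fixed, scale the other
printed destinations; `self_loop`: add the deficit to the diagonal) remain
selectable, and every resolution is recorded on the built matrix.  The TAU
end-of-treatment row (sum 0.95) is closed by adding the 0.05 deficit to
REMISSION (→ 0.664) under all policies, consistent with the statement that
only the healthy-transition probability differs between strategies.

**Discounting.**  Costs discount at 3% per year, compounded per cycle:
(1.03)^(−t/13), cycle 0 undiscounted; an annual-step variant is available.
The published incremental QALYs (0.0221) and ICER (€5,486/QALY) are
numerically consistent only with *undiscounted* utility accrual (this
model: 0.0217 undiscounted vs 0.0204 at 3%), despite the stated intention
to discount both; the reproduction profile therefore discounts costs only.
A conventional profile discounting both at the ledger rate
(`GUIDELINE_PROFILE`) is provided and is what we would recommend for new
analyses.

**Half-cycle correction.**  Life-table by default: cycle t is valued at
(x_t + x_{t+1})/2 for costs and QALYs alike.  Start- and end-of-cycle
counting are available; life-table totals always lie between them
(property-tested).

## What reproduces and what does not

Under the reproduction profile the base case lands within a few percent of
the published values: ΔC 117.67 vs 121.59, ΔE 0.0217 vs 0.0221, ICER
5,417 vs 5,486 €/QALY, HEALTHY at horizon 4,252 vs 4,143, and the DSA
app-price endpoints (−: dominant; +: 20,917 vs 20,478 €/QALY) with the
same two tornado leaders (app price, physiotherapy volume) and the same
third driver (the treatment→healthy probability).

The *sensitivity* of the incremental cost to horizon and attrition does
not reproduce: our per-year incremental savings are uniformly ≈ 1.15–1.2×
the published ones under every convention combination in the grid (and
under continuous free variation of the two entry probabilities), giving
2-year ICER ≈ 30,990 vs 25,189, 4-year ΔC ≈ −146 vs −99, equal-attrition
ΔC ≈ −343 vs −289, and 14%-attrition ICER ≈ 11,364 vs 10,620.  We conclude
the original implementation differs in a way not recoverable from the
printed inputs (its supplementary model specification is not available).
The published worst-case attrition row (ΔC −1,263.62 with ΔE −0.0029,
labelled comparator-dominant) is additionally inconsistent with its own
prose and with any parameterization of the printed model — a negative ΔC
cannot make the comparator "dominant"; our run gives ΔC ≈ +1,391,
ΔE ≈ −0.006, which matches the label and the prose but not the printed
numbers.  The corresponding acceptance test is deliberately left failing
rather than loosened.

## Synthetic data: the microsimulation oracle

The source is a pure cohort model; `lbpcea.microsim` exists as an
independent check and fixture generator, not as a second analysis method.
`simulate_individuals` draws per-patient trajectories from the same
transition matrices under the study conditions (10,000-person starting
split scaled by largest-remainder apportionment, so initial states are
deterministic and the only randomness is transitional; explicit seeds; by
default n = 100,000 and 39 cycles).  Values mirror the cohort engine —
each cycle at the mean of its endpoint state values, discounted
identically — so the simulated mean cost/QALYs are unbiased estimates of
the cohort totals; tests require agreement within 4 Monte-Carlo standard
errors on totals and 4 binomial standard errors on per-state occupancy.
What this validates is the propagation/accrual arithmetic, not the model's
fidelity to real patients: the generator inherits every structural
assumption (Markov memorylessness, homogeneous cohort, no death state,
printed transition rates), so passing tests say nothing about, e.g.,
individual heterogeneity in attrition.  `perturb_parameters` draws
uniform values within the published sensitivity ranges and recomposes all
linked quantities, yielding structurally valid ledgers for property tests.

## Numerical choices

- Probabilities enter at printed 4-decimal precision; built rows are
  normalised to machine precision and validated to sum to 1 within 1e-12.
- Row deficits above 1e-9 trigger the residual policy; surpluses raise an
  inconsistency error.
- DSA sweeps that touch a closed row compensate within the row: a
  remission-probability change at the end of treatment is taken
  proportionally from the LOW/HIGH returns; a healthy-probability change
  is taken from remission.  Raw-scale bounds (treatment entry, remission
  share, remission persistence) are recomposed before matrix construction.
- Dominant DSA outcomes are ordered by the signed sentinel −|ΔC/ΔE|
  (intervention-dominant) / +|ΔC/ΔE| (comparator-dominant); ties in
  tornado ranges break lexicographically by parameter id.
- The healthy-at-horizon count reports raw (uncorrected) final-cycle
  membership rounded half-up, since the source reports integer patients.
- A zero ΔE with non-zero ΔC yields an "undefined ratio" label, not an
  exception.

## Limitations

Beyond the reproduction gaps above: no probabilistic sensitivity analysis
(the source refrained for lack of dispersion data), no death state or
background mortality, no inpatient/rehabilitation/injection pathways, no
individual covariates, and the consultation-count convention behind the
published per-year utilization figures is unknown, so
`resource_utilization` reports counts under an explicit, configurable
convention without claiming equivalence.
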
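absenteeism_days:
  HEALTHY: 0.0
  HIGH: 4.0
  LOW: 3.0
  REMISSION: 0.0
  T_W1_4: 1.0
  T_W4_8: 0.0
  T_W8_12: 0.0
run:
  cohort_size: 10000
  cycles_per_year: 13
  discount_rate: 0.03
  horizon_years: 3
  start_distribution:
  - 5320
  - 1120
  - 3560
schema_version: 1
state_costs:
  DTC:
    HEALTHY: 0.0
    HIGH: 588.96
    LOW: 441.72
    REMISSION: 0.0
    T_W1_4: 475.08
    T_W4_8: 16.81
    T_W8_12: 16.81
  TAU:
    HEALTHY: 0.0
    HIGH: 588.96
    LOW: 441.72
    REMISSION: 0.0
    T_W1_4: 377.85
    T_W4_8: 16.81
    T_W8_12: 16.81
transitions:
  attrition:
    DTC:
    - 0.125
    - 0.125
    TAU:
    - 0.065
    - 0.043
  low_trajectory_share: 0.822
  p_end_healthy:
    DTC: 0.1
    TAU: 0.05
  p_end_high: 0.051
  p_end_low: 0.235
  p_end_remission: 0.614
  p_high_high: 0.08
  p_high_low: 0.02
  p_high_treat: 0.8
  p_low_high: 0.01
  p_low_low: 0.16
  p_low_remission: 0.03
  p_low_treat: 0.75
  p_rem_high: 0.109
  p_rem_low: 0.505
  p_rem_stay: 0.386
  remission_share: 0.5
unit_costs:
  app_cost: 239.96
  copay_rate: 0.1
  diagnostics: 29.24
  gp_consultation: 20.47
  monthly_gross_wage: 3092.0
  pharmacotherapy: 16.81
  physio_session_price: 21.11
  physio_sessions: 6
  prescription_charge: 10.0
  specialist_consultation: 21.36
  working_days: 21
utilities:
  DTC:
    HEALTHY: 0.806
    HIGH: 0.61
    LOW: 0.655
    REMISSION: 0.806
    T_W1_4: 0.655
    T_W4_8: 0.699
    T_W8_12: 0.748
  TAU:
    HEALTHY: 0.806
    HIGH: 0.61
    LOW: 0.655
    REMISSION: 0.806
    T_W1_4: 0.655
    T_W4_8: 0.717
    T_W8_12: 0.729
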
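# Bundled synthetic-cohort configuration: the cohort structure the grouping
# method assumes (elderly-dominated age mix, ~63/37 insurance split,
# tertiary-skewed hospitals, right-skewed LOS, log-normal baseline cost with
# additive planted CC and control effects, overall mean near 1,560).  Same
# values as drgmix.synthetic.default_sim_params.
n: 10000
seed: 0
sex_probs: {male: 0.495, female: 0.505}
insurance_probs: {urban_employee: 0.6266, urban_rural_resident: 0.3734}
hospital_probs: {primary: 0.1963, secondary: 0.3272, tertiary: 0.4765}
charge_probs:
  tertiary_a: 0.2739
  tertiary_b: 0.2024
  secondary_a: 0.2616
  secondary_b: 0.0500
  tertiary_b_up: 0.0285
  tertiary_b_down: 0.1836
age_bin_probs: {le45: 0.019, 45to65: 0.2532, 65to75: 0.3249, 75to85: 0.3126, ge85: 0.0903}
los_log_mean: 2.35
los_log_sd: 0.55
max_los: 60
baseline_log_mean: 5.47
baseline_log_sd: 0.55
noise_sd: 250.0
multiplicative: false
control_effects:
  hospital_level: {secondary: 220.0, tertiary: 480.0}
  charge_level:
    tertiary_a: 150.0
    tertiary_b: 60.0
    secondary_a: 40.0
    tertiary_b_up: 25.0
    secondary_b: 15.0
  age_bin: {45to65: 30.0, 65to75: 50.0, 75to85: 80.0, ge85: 120.0}
  los_bin: {9to12: 250.0, gt12: 620.0}
  insurance: {urban_rural_resident: -100.0}
  sex: {female: -20.0}
cc_catalog:
  - {code: G97, slot: 1, prevalence: 0.03, effect: 1200.0}
  - {code: J95, slot: 1, prevalence: 0.10, effect: 450.0}
  - {code: Z98, slot: 1, prevalence: 0.20, effect: 60.0}
  - {code: T06, slot: 2, prevalence: 0.02, effect: 1300.0}
  - {code: B44, slot: 2, prevalence: 0.08, effect: 420.0}
  - {code: L88, slot: 2, prevalence: 0.15, effect: 50.0}
  - {code: B37, slot: 3, prevalence: 0.04, effect: 1100.0}
  - {code: Q12, slot: 3, prevalence: 0.07, effect: 480.0}
  - {code: G92, slot: 3, prevalence: 0.18, effect: 70.0}
  - {code: F43, slot: 4, prevalence: 0.03, effect: 1250.0}
  - {code: I12, slot: 4, prevalence: 0.12, effect: 400.0}
  - {code: C25, slot: 4, prevalence: 0.12, effect: 55.0}
  - {code: A40, slot: 5, prevalence: 0.02, effect: 1400.0}
  - {code: B49, slot: 5, prevalence: 0.06, effect: 500.0}
  - {code: D73, slot: 5, prevalence: 0.15, effect: 45.0}
  - {code: D46, slot: 6, prevalence: 0.03, effect: 1150.0}
  - {code: S73, slot: 6, prevalence: 0.09, effect: 430.0}
  - {code: R57, slot: 6, prevalence: 0.16, effect: 65.0}
  - {code: B95, slot: 7, prevalence: 0.05, effect: 1300.0}
  - {code: A41, slot: 7, prevalence: 0.08, effect: 460.0}
  - {code: I10, slot: 7, prevalence: 0.25, effect: 40.0}
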
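# atezopk default run configuration.
#
# Reproduces the study conditions: a 1000-subject virtual oncology
# population, four IV dosing regimens of atezolizumab (standard 1200 mg
# q3w and three extended-interval arms ending in 840 mg q6w), 7 cycles
# each, summarized against the 6 µg/mL minimum effective concentration.

seed: 20260928
output_dir: output
mec: 6.0               # µg/mL minimum effective concentration

grid:
  resolution: 0.1      # days between observation-grid points within a cycle

population:
  n_subjects: 1000
  age_min: 20.0        # years, uniform
  age_max: 80.0
  p_male: 0.5
  weight_intercept_f: 65.0   # kg at the 40-year reference age
  weight_intercept_m: 85.0
  weight_age_slope: 0.75     # kg/year
  weight_sd_f: 3.5           # kg, Gaussian noise SD
  weight_sd_m: 10.0
  albumin_log_median: 42.0   # g/L (natural-scale median of the log-normal)
  albumin_log_sd: 0.10       # ln-scale SD, calibrated to the observed min-max range
  tumor_log_location: 4.2    # ln(mm); median e^4.2 = 66.7 mm
  tumor_log_sd: 0.70         # ln-scale SD, calibrated to the observed min-max range
  p_ada: 0.40                # probability of anti-drug antibodies

model:
  # Externally sourced: structural values, covariate effects and IIV
  # variances transcribed from the published atezolizumab population-PK
  # model (FDA CDER clinical pharmacology review for atezolizumab in
  # NSCLC; Stroh et al., metastatic urothelial carcinoma popPK).  They
  # are configuration, not estimates produced by this package.
  structural:
    cl: 0.200    # L/day
    v1: 3.28     # L
    q: 0.546     # L/day
    v2: 3.63     # L
  infusion_duration_days: 0.0416666667   # 1-hour IV infusion
  covariates:
    - {parameter: cl, covariate: weight,     kind: power,        reference: 77.0, value: 0.808}
    - {parameter: cl, covariate: albumin,    kind: power,        reference: 40.0, value: -1.12}
    - {parameter: cl, covariate: tumor_size, kind: power,        reference: 63.0, value: 0.125}
    - {parameter: cl, covariate: ada,        kind: proportional, value: 0.16}
    - {parameter: cl, covariate: female,     kind: proportional, value: -0.139}
    - {parameter: v1, covariate: weight,     kind: power,        reference: 77.0, value: 0.559}
    - {parameter: v1, covariate: female,     kind: proportional, value: -0.129}
  iiv:
    omega_sq:
      cl: 0.083    # ln-scale variance (~29% CV)
      v1: 0.0324   # ln-scale variance (~18% CV)

# Built-in regimen names, or inline definitions as
#   {name: ..., blocks: [[amount_mg, interval_days, n_doses], ...]}
regimens:
  - "1200 mg q3w"
  - "840 mg q2w x2, 840 mg q6w x5"
  - "1200 mg q3w x2, 840 mg q6w x5"
  - "1680 mg q4w x2, 840 mg q6w x5"
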
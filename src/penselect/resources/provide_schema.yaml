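# Synthetic PROVIDE-like cohort schema (N=512 Bangladeshi birth-cohort
# children): 33 biomarkers / clinical risk factors with their native-unit
# means and SDs, the eight-variable correlated block, and the generating
# effects (standardized scale) used to synthesize the outcome.
#
# The eight anthropometric / socioeconomic covariates in the correlated
# block come first, in the AR(1) ordering used throughout; the remaining
# 25 covariates are mutually independent.
outcome:
  name: haz_1y          # height-for-age z-score at one year
  mean: -1.47
  sd: 1.02
snr: 2.6                # Var(x'beta) / Var(eps) of the generating model
rho: 0.5                # AR(1) correlation within the block
covariates:
  - {name: expenditure,        mean: 11736.56, sd: 7555.13,  block: true,  effect: 0.0}
  - {name: income,             mean: 13021.23, sd: 9708.96,  block: true,  effect: 0.0}
  - {name: mother_weight,      mean: 49.36,    sd: 9.33,     block: true,  effect: 0.45}
  - {name: mother_height,      mean: 150.38,   sd: 5.61,     block: true,  effect: 0.0}
  - {name: WAZ_wk18,           mean: -0.82,    sd: 1.06,     block: true,  effect: 0.0}
  - {name: WHZ_wk18,           mean: -0.10,    sd: 1.01,     block: true,  effect: 0.0}
  - {name: HAZ_birth,          mean: -0.90,    sd: 0.89,     block: true,  effect: 0.0}
  - {name: HAZ_wk18,           mean: -1.02,    sd: 0.93,     block: true,  effect: 0.67}
  - {name: MPO_wk12,           mean: 10952.92, sd: 11489.08, block: false, effect: -0.045}
  - {name: calprotectin_wk12,  mean: 781.68,   sd: 725.30,   block: false, effect: 0.0}
  - {name: neopterin_wk12,     mean: 2601.90,  sd: 2041.17,  block: false, effect: 0.0}
  - {name: ALA_wk12,           mean: 0.85,     sd: 0.71,     block: false, effect: 0.0}
  - {name: mannitol_wk12,      mean: 0.02,     sd: 0.02,     block: false, effect: -0.055}
  - {name: mannitol_wk24,      mean: 0.02,     sd: 0.02,     block: false, effect: 0.0}
  - {name: reg1b_wk6,          mean: 56.13,    sd: 91.12,    block: false, effect: 0.0}
  - {name: reg1b_wk12,         mean: 80.87,    sd: 117.88,   block: false, effect: 0.0}
  - {name: diarrhea_days_wk18, mean: 6.22,     sd: 10.75,    block: false, effect: 0.0}
  - {name: ferritin_wk6,       mean: 229.42,   sd: 153.31,   block: false, effect: -0.07}
  - {name: ferritin_wk18,      mean: 45.45,    sd: 56.39,    block: false, effect: 0.0}
  - {name: CRP_wk6,            mean: 1.11,     sd: 3.83,     block: false, effect: 0.0}
  - {name: CRP_wk18,           mean: 2.89,     sd: 7.53,     block: false, effect: 0.0}
  - {name: sCD14_wk6,          mean: 1686.90,  sd: 630.27,   block: false, effect: 0.0}
  - {name: sCD14_wk18,         mean: 1967.24,  sd: 697.34,   block: false, effect: -0.035}
  - {name: LPS_wk6,            mean: 29.21,    sd: 42.25,    block: false, effect: 0.0}
  - {name: LPS_wk18,           mean: 11.27,    sd: 39.98,    block: false, effect: 0.0}
  - {name: log_activin_wk6,    mean: 6.41,     sd: 1.12,     block: false, effect: 0.0}
  - {name: vitamin_D_wk6,      mean: 35.58,    sd: 18.20,    block: false, effect: 0.0}
  - {name: vitamin_D_wk18,     mean: 61.38,    sd: 24.17,    block: false, effect: 0.0}
  - {name: zinc_wk6,           mean: 725.64,   sd: 107.58,   block: false, effect: 0.0}
  - {name: zinc_wk18,          mean: 771.86,   sd: 146.50,   block: false, effect: 0.0}
  - {name: RBP_wk6,            mean: 24317.52, sd: 11461.94, block: false, effect: 0.0}
  - {name: RBP_wk18,           mean: 29780.83, sd: 15167.70, block: false, effect: 0.0}
  - {name: breast_feeding_wk18, mean: 95.99,   sd: 41.71,    block: false, effect: -0.085}
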
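# Default parameter set for the COPD burden model.
#
# Disease, cost and utility blocks hold the published Canadian inputs
# (2011 CAD, EQ-5D utilities, GOLD stages with III/IV merged).  The
# demography block holds the synthetic stand-in for Statistics Canada
# projections: age/sex structure and smoking mix are plausible 2011
# Canadian values; entry and net-migration rates are placeholders that
# the calibration replaces (see copdsim.demography.default_demography).

horizon:
  start: 2011
  end: 2035
dt: 0.25

economics:
  discount_rate: 0.03
  base_year: 2011
  wtp_per_qaly: 50000.0

anchors:
  pop40plus_2011: 17.0e6
  pop40plus_2035: 24.0e6
  pop70plus_2035: 8.0e6
  copd_total_2011: 3.45e6

demography:
  # fraction of the 40+ population in each band in 2011 (40-49, 50-59, 60-69, 70+)
  age_shares: [0.303, 0.291, 0.212, 0.194]
  # male fraction within each band
  men_share: [0.50, 0.50, 0.48, 0.42]
  # smoking mix (current, previous, never) per sex and band; free calibration
  # parameters -- a current<->never shift is solved against copd_total_2011
  smoking_mix:
    men:
      - [0.24, 0.28, 0.48]
      - [0.22, 0.32, 0.46]
      - [0.17, 0.38, 0.45]
      - [0.11, 0.40, 0.49]
    women:
      - [0.18, 0.24, 0.58]
      - [0.16, 0.28, 0.56]
      - [0.13, 0.34, 0.53]
      - [0.07, 0.36, 0.57]
  # band-to-band transfer rates, 1/years (10-year bands; 70+ absorbs)
  aging_rates: [0.1, 0.1, 0.1, 0.0]
  smoking_cessation_rate: 0.02      # current -> previous, per year
  smoking_initiation_rate: 0.002    # never -> current in the 40-49 band, per year
  entry_rate_per_sex: [250000.0, 250000.0]   # persons/yr entering 40-49; calibrated
  net_migration_rate: 0.004                  # per-capita/yr, all subgroups; calibrated
  initiation_multiplier: 1.0   # intervention I lever; scales initiation and the
                               # initiation-attributable current-smoker entry share

# deaths per 10,000 person-years, by sex / smoking / age band
background_mortality_per_10k:
  men:
    current:  [27.0, 69.0, 186.0, 830.7]
    previous: [18.9, 48.3, 130.2, 581.5]
    never:    [16.2, 41.4, 111.6, 498.4]
  women:
    current:  [16.8, 43.0, 108.9, 694.8]
    previous: [11.8, 30.1, 76.2, 486.4]
    never:    [10.1, 25.8, 65.3, 416.9]

# % symptomatic, by sex / smoking, for people without and with COPD
symptom_prevalence_pct:
  men:
    current:  {no_copd: 36.7, copd: 95.1}
    previous: {no_copd: 19.0, copd: 49.2}
    never:    {no_copd: 14.5, copd: 37.6}
  women:
    current:  {no_copd: 40.0, copd: 100.0}
    previous: {no_copd: 24.7, copd: 64.1}
    never:    {no_copd: 21.8, copd: 56.5}

spirometry:
  uptake: 0.37
  sensitivity: 0.92
  specificity: 0.84

# % (none, mild, moderate, severe) per sex / smoking / age band
stage_distribution_pct:
  men:
    current:
      - [79.3, 17.0, 3.4, 0.4]
      - [74.4, 17.0, 7.7, 0.8]
      - [67.0, 17.0, 14.5, 1.6]
      - [48.0, 17.0, 31.6, 3.4]
    previous:
      - [81.4, 15.2, 3.0, 0.3]
      - [77.1, 15.2, 6.9, 0.7]
      - [70.4, 15.2, 13.0, 1.4]
      - [53.4, 15.2, 28.3, 3.0]
    never:
      - [89.6, 8.5, 1.7, 0.2]
      - [87.2, 8.5, 3.9, 0.4]
      - [83.5, 8.5, 7.2, 0.8]
      - [74.0, 8.5, 15.8, 1.7]
  women:
    current:
      - [72.3, 24.4, 2.5, 0.8]
      - [72.3, 24.4, 2.5, 0.8]
      - [47.9, 24.4, 20.9, 6.8]
      - [22.5, 24.4, 40.0, 13.1]
    previous:
      - [90.7, 8.2, 0.8, 0.3]
      - [90.7, 8.2, 0.8, 0.3]
      - [82.5, 8.2, 7.0, 2.3]
      - [73.9, 8.2, 13.5, 4.4]
    never:
      - [91.9, 7.1, 0.7, 0.2]
      - [91.9, 7.1, 0.7, 0.2]
      - [84.9, 7.1, 6.1, 2.0]
      - [77.5, 7.1, 11.6, 3.8]

# mean years to the next stage: [mild->moderate, moderate->severe]
progression_times_years:
  men:
    current:  [22.0, 16.0]
    previous: [30.0, 21.0]
    never:    [30.0, 21.0]
  women:
    current:  [22.0, 17.0]
    previous: [32.0, 21.0]
    never:    [32.0, 21.0]

exacerbations:
  rate_per_patient_year: [0.79, 1.22, 1.47]   # mild, moderate, severe
  minor_fraction: [0.94, 0.93, 0.90]
  major_fraction: [0.06, 0.07, 0.10]
  death_prob_per_major: 0.046

utilities:
  reference_by_age: [0.874, 0.864, 0.828, 0.79]   # EQ-5D, general population
  chronic_by_stage: [0.81, 0.72, 0.67]
  minor_exac_by_stage: [0.72, 0.658, 0.475]
  major_exac_by_stage: [0.519, 0.447, 0.408]
  minor_episode_duration_days: 14.0
  major_episode_duration_days: 30.0

costs_cad_2011:
  direct_maintenance: [144.0, 430.0, 628.0]       # per patient-year, by stage
  direct_minor_episode: 161.0
  direct_major_episode: 6501.0
  indirect_maintenance: [36.0, 215.0, 524.0]
  indirect_minor_episode: [40.0, 80.0, 134.0]
  indirect_major_episode: [1625.0, 3250.0, 5417.0]
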
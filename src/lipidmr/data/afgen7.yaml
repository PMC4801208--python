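# Default seven-cohort consortium configuration.
#
# n, fraction_male, follow-up horizon, the covariate-availability (NA) pattern
# and the target AF case count are the calibrated quantities; covariate means/
# SDs are plausible per-cohort baselines and death/dropout rates are free
# censoring parameters. Expected case counts sum to 5434 of 64901 (8.4%).
scenario:
  theta_lipid: 0.0        # log-HR of AF per 1 SD of the exposure lipid (0 = null)
  theta_direct: 0.0       # log-HR per 1 SD of gene score via a non-lipid path
  instrument_r2: 0.05     # lipid variance explained by the gene score
  exposure_fraction: LDL
  confounder_effects: {}
  seed: 0

cohorts:
  - name: AGES
    n: 2953
    mean_age: 76
    sd_age: 5
    fraction_male: 0.454
    followup_years: 10.0
    death_rate: 0.05
    dropout_rate: 0.005
    cases: 422
    missing_covariates: [lvh, prior_stroke, prior_chd]
    covariates:
      height: [167, 9]
      smoking: 0.13
      bmi: [27, 4]
      sbp: [143, 20]
      dbp: [74, 10]
      antihypertensive: 0.64
      diabetes: 0.11
      prior_hf: 0.03
      lipid_meds: 0.23
      education: 0.75
  - name: ARIC
    n: 8849
    mean_age: 54
    sd_age: 6
    fraction_male: 0.465
    followup_years: 22.0
    death_rate: 0.012
    dropout_rate: 0.004
    cases: 1207
    missing_covariates: []
    covariates:
      height: [169, 10]
      smoking: 0.24
      bmi: [27, 5]
      sbp: [118, 17]
      dbp: [72, 10]
      antihypertensive: 0.25
      diabetes: 0.08
      lvh: 0.01
      prior_stroke: 0.02
      prior_hf: 0.03
      prior_chd: 0.05
      lipid_meds: 0.03
      education: 0.75
  - name: FHS
    n: 4126
    mean_age: 64
    sd_age: 13
    fraction_male: 0.435
    followup_years: 11.0
    death_rate: 0.02
    dropout_rate: 0.005
    cases: 565
    missing_covariates: [education]
    covariates:
      height: [166, 10]
      smoking: 0.15
      bmi: [28, 5]
      sbp: [130, 20]
      dbp: [74, 10]
      antihypertensive: 0.35
      diabetes: 0.08
      lvh: 0.01
      prior_stroke: 0.02
      prior_hf: 0.01
      prior_chd: 0.07
      lipid_meds: 0.15
  - name: MDCS
    n: 28218
    mean_age: 58
    sd_age: 8
    fraction_male: 0.395
    followup_years: 17.0
    death_rate: 0.012
    dropout_rate: 0.004
    cases: 2087
    missing_covariates: [lvh, lipid_hdl, lipid_ldl, lipid_tc, lipid_tg]
    unavailable_fractions: [TC]
    reduced_panel: true
    covariates:
      height: [169, 9]
      smoking: 0.29
      bmi: [26, 4]
      sbp: [141, 20]
      dbp: [86, 10]
      antihypertensive: 0.17
      diabetes: 0.029
      prior_stroke: 0.01
      prior_hf: 0.002
      prior_chd: 0.02
      lipid_meds: 0.03
      education: 0.75
  - name: RS-I
    n: 4560
    mean_age: 68
    sd_age: 8
    fraction_male: 0.408
    followup_years: 21.0
    death_rate: 0.03
    dropout_rate: 0.005
    cases: 571
    missing_covariates: []
    covariates:
      height: [167, 9]
      smoking: 0.24
      bmi: [26, 4]
      sbp: [139, 22]
      dbp: [74, 11]
      antihypertensive: 0.42
      diabetes: 0.10
      lvh: 0.04
      prior_stroke: 0.02
      prior_hf: 0.02
      prior_chd: 0.13
      lipid_meds: 0.02
      education: 0.75
  - name: RS-II
    n: 1689
    mean_age: 65
    sd_age: 8
    fraction_male: 0.458
    followup_years: 8.0
    death_rate: 0.02
    dropout_rate: 0.005
    cases: 78
    missing_covariates: []
    covariates:
      height: [169, 9]
      smoking: 0.22
      bmi: [27, 4]
      sbp: [143, 21]
      dbp: [79, 11]
      antihypertensive: 0.27
      diabetes: 0.11
      lvh: 0.02
      prior_stroke: 0.03
      prior_hf: 0.02
      prior_chd: 0.05
      lipid_meds: 0.12
      education: 0.75
  - name: WGHS
    n: 14506
    mean_age: 54
    sd_age: 7
    fraction_male: 0.0
    followup_years: 18.0
    death_rate: 0.004
    dropout_rate: 0.003
    cases: 504
    missing_covariates: [lvh, prior_stroke, prior_chd, prior_hf]
    covariates:
      height: [164, 6]
      smoking: 0.11
      bmi: [26, 5]
      sbp: [124, 14]
      dbp: [77, 9]
      antihypertensive: 0.13
      diabetes: 0.02
      lipid_meds: 0.04
      education: 0.75
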
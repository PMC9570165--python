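age_range_years:
- 20.0
- 65.0
albumin_ratio: 1.0
cyp_abundance_cv:
  CYP1A2: 0.4
  CYP2C19: 0.4
  CYP2C9: 0.4
  CYP2D6: 0.4
  CYP3A4: 0.4
cyp_abundance_mean:
  CYP1A2: 52.0
  CYP2C19: 14.0
  CYP2C9: 73.0
  CYP2D6: 8.0
  CYP3A4: 137.0
female:
  haematocrit_cv: 0.05
  haematocrit_mean_pct: 38.0
  height_mean_cm: 163.0
  height_sd_cm: 6.0
  height_weight:
    a: 2.178160450787455
    residual_gsd: 1.1
    x0: 0.012
  target_bmi_mean: 23.5
hepatic_blood_flow_l_per_h: 90.0
liver_mass_g: 1650.0
male:
  haematocrit_cv: 0.05
  haematocrit_mean_pct: 43.0
  height_mean_cm: 176.0
  height_sd_cm: 7.0
  height_weight:
    a: 2.213210750399277
    residual_gsd: 1.1
    x0: 0.012
  target_bmi_mean: 24.4
mppgl_mg_per_g: 40.0
name: healthy
proportion_female: 0.5
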
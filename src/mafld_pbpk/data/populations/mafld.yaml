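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
  CYP1A2: 19.24
  CYP2C19: 4.298
  CYP2C9: 52.559999999999995
  CYP2D6: 5.72
  CYP3A4: 85.351
female:
  haematocrit_cv: 0.05
  haematocrit_mean_pct: 42.6
  height_mean_cm: 163.0
  height_sd_cm: 6.0
  height_weight:
    a: 2.328046731828256
    residual_gsd: 1.1
    x0: 0.012
  target_bmi_mean: 27.3
hepatic_blood_flow_l_per_h: 90.0
liver_mass_g: 1650.0
male:
  haematocrit_cv: 0.05
  haematocrit_mean_pct: 48.2
  height_mean_cm: 176.0
  height_sd_cm: 7.0
  height_weight:
    a: 2.4097746639087747
    residual_gsd: 1.1
    x0: 0.012
  target_bmi_mean: 29.7
mppgl_mg_per_g: 40.0
name: mafld
proportion_female: 0.5
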
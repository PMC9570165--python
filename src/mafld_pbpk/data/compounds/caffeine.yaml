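bp_ratio: 1.04
bp_reference_hct_pct: null
cl_renal_l_per_h: 0.08
clint_other_ul_min_mg: 0.185
clint_per_pmol:
  CYP1A2: 0.067596
dose_mg: 150.0
fa_fg: 1.0
fu: 0.65
ka_per_h: 4.0
mm: null
name: caffeine
vss_l_per_kg: 0.5
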
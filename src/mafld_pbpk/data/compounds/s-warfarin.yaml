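bp_ratio: 0.55
bp_reference_hct_pct: null
cl_renal_l_per_h: 0.0
clint_other_ul_min_mg: 0.252
clint_per_pmol:
  CYP2C9: 0.034904
dose_mg: 10.0
fa_fg: 1.0
fu: 0.01
ka_per_h: 1.0
mm: null
name: s-warfarin
vss_l_per_kg: 0.14
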
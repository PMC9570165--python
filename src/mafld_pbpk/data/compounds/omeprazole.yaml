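bp_ratio: 0.6
bp_reference_hct_pct: null
cl_renal_l_per_h: 0.0
clint_other_ul_min_mg: 17.55
clint_per_pmol:
  CYP2C19: 8.389286
dose_mg: 20.0
fa_fg: 0.9
fu: 0.05
ka_per_h: 2.0
mm: null
name: omeprazole
vss_l_per_kg: 0.3
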
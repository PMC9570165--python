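bp_ratio: 1.0
bp_reference_hct_pct: null
cl_renal_l_per_h: 0.5
clint_other_ul_min_mg: 12.0
clint_per_pmol:
  CYP2D6: 8.5
dose_mg: 30.0
fa_fg: 0.95
fu: 0.35
ka_per_h: 1.5
mm: null
name: dextromethorphan
vss_l_per_kg: 5.0
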
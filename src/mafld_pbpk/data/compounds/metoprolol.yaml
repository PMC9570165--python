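bp_ratio: 1.1
bp_reference_hct_pct: null
cl_renal_l_per_h: 6.0
clint_other_ul_min_mg: 12.54
clint_per_pmol:
  CYP2D6: 5.5575
dose_mg: 100.0
fa_fg: 0.95
fu: 0.88
ka_per_h: 2.0
mm: null
name: metoprolol
vss_l_per_kg: 4.0
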
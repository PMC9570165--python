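bp_ratio: 0.66
bp_reference_hct_pct: null
cl_renal_l_per_h: 0.0
clint_other_ul_min_mg: 12.9
clint_per_pmol:
  CYP3A4: 1.475182
dose_mg: 5.0
fa_fg: 0.55
fu: 0.03
ka_per_h: 6.0
mm: null
name: midazolam
vss_l_per_kg: 1.0
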
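bp_ratio: 0.85
bp_reference_hct_pct: null
cl_renal_l_per_h: 0.0
clint_other_ul_min_mg: 28.5
clint_per_pmol:
  CYP1A2: 2.557692
  CYP3A4: 0.208029
dose_mg: 12.5
fa_fg: 0.9
fu: 0.05
ka_per_h: 1.5
mm: null
name: clozapine
vss_l_per_kg: 5.4
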
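bp_ratio: 0.8
bp_reference_hct_pct: null
cl_renal_l_per_h: 0.0
clint_other_ul_min_mg: 158.1
clint_per_pmol:
  CYP2C9: 2.080822
dose_mg: 4.0
fa_fg: 0.99
fu: 0.002
ka_per_h: 1.2
mm: null
name: rosiglitazone
vss_l_per_kg: 0.25
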
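enzyme,observed_ratio,simulated_ratio,printed_mfe
CYP1A2,1.93,2.12,1.1
CYP2C9,1.04,1.0,1.04
CYP2C19,2.38,2.52,1.06
CYP2D6,1.46,1.32,1.11
CYP3A4,2.03,1.55,1.31
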
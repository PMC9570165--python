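enzyme,substrate,parameter,observed_ratio,simulated_ratio,printed_mfe,source_ref
CYP1A2,caffeine,AUC,2.9,2.12,1.37,B9
CYP1A2,caffeine,Cmax,2.5,1.14,2.19,B9
CYP1A2,clozapine,AUC,1.2,1.81,1.5,B12
CYP1A2,clozapine,Cmax,0.69,1.15,1.66,B12
CYP2C9,rosiglitazone,AUC,2.41,1.16,2.08,B10
CYP2C9,rosiglitazone,Cmax,0.86,0.982,1.14,B10
CYP2C19,omeprazole,AUC,11.1,2.52,4.4,B9
CYP2C19,omeprazole,Cmax,6.5,1.54,4.23,B9
CYP2D6,dextromethorphan,AUC,2.69,1.32,2.03,B9
CYP2D6,dextromethorphan,Cmax,3.31,1.2,2.77,B9
CYP2D6,metoprolol,AUC,2.28,1.45,1.57,B11
CYP2D6,metoprolol,Cmax,1.41,1.22,1.16,B11
CYP3A4,midazolam,AUC,1.55,1.55,1.0,B9
CYP3A4,midazolam,Cmax,1.22,1.11,1.1,B9
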
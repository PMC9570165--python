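enzyme,endpoint,probe_reaction,ratio,source_ref,model_system
CYP1A2,activity,7-methoxyresorufin O-demethylation,0.46,B25,human_microsomes
CYP1A2,activity,Phenacetin O-deethylation,0.58,B26,human_microsomes
CYP2C9,activity,Diclofenac 4'-hydroxylation,0.82,B25,human_microsomes
CYP2C9,activity,Testosterone 16b-hydroxylation,0.64,B25,human_microsomes
CYP2C9,activity,Testosterone 16b-hydroxylation,0.4,B27,human_microsomes
CYP2C9,activity,Diclofenac 4'-hydroxylation,1.53,B26,human_microsomes
CYP2C9,activity,Tolbutamide 4-hydroxylation,1.42,B26,human_microsomes
CYP2C19,activity,Androstenedione,0.46,B25,human_microsomes
CYP2C19,activity,Testosterone 16b-hydroxylation,0.4,B27,human_microsomes
CYP2C19,activity,Androstenedione,0.62,B27,human_microsomes
CYP2C19,activity,Mephenytoin 4'-hydroxylation,0.21,B26,human_microsomes
CYP2D6,activity,Dextromethorphan O-demethylation,0.68,B26,human_microsomes
CYP3A4,activity,Midazolam 1'-hydroxylation,0.45,B28,human_microsomes
CYP3A4,activity,Testosterone 6b-hydroxylation,0.55,B25,human_microsomes
CYP3A4,activity,Testosterone 6b-hydroxylation,0.57,B25,human_microsomes
CYP3A4,activity,Testosterone 2b-hydroxylation,0.41,B25,human_microsomes
CYP3A4,activity,Testosterone 15b-hydroxylation,0.55,B27,human_microsomes
CYP3A4,activity,Testosterone 6b-hydroxylation,0.44,B27,human_microsomes
CYP3A4,activity,Testosterone 2b-hydroxylation,0.43,B27,human_microsomes
CYP3A4,activity,Testosterone 6b-hydroxylation,0.46,B29,human_microsomes
CYP3A4,activity,Midazolam 1'-hydroxylation,0.41,B28,human_microsomes
CYP3A4,activity,Midazolam 1'-hydroxylation,0.61,B30,human_microsomes
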
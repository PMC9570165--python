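compound,enzyme,regimen,metric,healthy,mafld,printed_ratio,suspect
caffeine,CYP1A2,single,cmax,3399.0,3885.0,1.14,0
caffeine,CYP1A2,single,auc,23712.0,50331.0,2.12,0
caffeine,CYP1A2,multiple,cmax,3597.0,5568.0,1.55,0
caffeine,CYP1A2,multiple,auc,25130.0,72715.0,2.89,0
clozapine,CYP1A2,single,cmax,54.4,62.6,1.15,0
clozapine,CYP1A2,single,auc,436.0,788.0,1.81,0
clozapine,CYP1A2,multiple,cmax,58.4,81.3,1.39,0
clozapine,CYP1A2,multiple,auc,469.0,1026.0,2.19,0
s-warfarin,CYP2C9,single,cmax,924.0,866.0,0.94,0
s-warfarin,CYP2C9,single,auc,15458.0,15500.0,1.0,0
s-warfarin,CYP2C9,multiple,cmax,1877.0,1983.0,1.06,0
s-warfarin,CYP2C9,multiple,auc,31630.0,35778.0,1.13,0
rosiglitazone,CYP2C9,single,cmax,245.0,241.0,0.98,0
rosiglitazone,CYP2C9,single,auc,1152.0,1331.0,1.16,0
rosiglitazone,CYP2C9,multiple,cmax,248.0,247.0,0.99,0
rosiglitazone,CYP2C9,multiple,auc,1166.0,1364.0,1.17,0
omeprazole,CYP2C19,single,cmax,153.0,236.0,1.54,0
omeprazole,CYP2C19,single,auc,467.0,1174.0,2.52,0
omeprazole,CYP2C19,multiple,cmax,191.0,323.0,1.7,0
omeprazole,CYP2C19,multiple,auc,666.0,2112.0,3.17,0
dextromethorphan,CYP2D6,single,cmax,4.25,5.08,1.2,0
dextromethorphan,CYP2D6,single,auc,49.9,66.0,1.32,0
dextromethorphan,CYP2D6,multiple,cmax,7.56,10.1,1.33,0
dextromethorphan,CYP2D6,multiple,auc,63.6,89.8,1.41,0
metoprolol,CYP2D6,single,cmax,1412.0,172.0,1.22,1
metoprolol,CYP2D6,single,auc,841.0,1223.0,1.45,0
metoprolol,CYP2D6,multiple,cmax,145.0,180.0,1.24,0
metoprolol,CYP2D6,multiple,auc,863.0,1276.0,1.48,0
midazolam,CYP3A4,single,cmax,18.7,20.7,1.11,0
midazolam,CYP3A4,single,auc,54.7,84.8,1.55,0
midazolam,CYP3A4,multiple,cmax,19.9,23.4,1.18,0
midazolam,CYP3A4,multiple,auc,56.1,89.7,1.6,0
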
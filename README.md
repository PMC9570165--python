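# mafld-pbpk

Virtual-population pharmacokinetic simulation of drug exposure in
metabolic-associated fatty liver disease (MAFLD).

MAFLD perturbs the hepatic cytochrome P450 (CYP) enzymes that clear most
small-molecule drugs, but human exposure data in this population are scarce.
This package provides an open, testable pipeline for the physiologically
based pharmacokinetic (PBPK) workflow used to extrapolate preclinical CYP
observations to clinical drug exposure:

1. **Meta-pooling** — study-level MAFLD/control ratios of CYP abundance or
   activity are pooled into one proportional difference per enzyme
   (arithmetic by default, geometric available).
2. **Population building** — a healthy virtual population (demographics,
   height–weight model `weight = exp(a + x0·height)`, haematocrit, per-CYP
   liver abundance with log-normal variability) is rescaled into a disease
   population: CYP1A2 abundance ×0.37, CYP2C9 ×0.72, haematocrit set to
   48.2%/42.6% (M/F), BMI recalibrated to 29.7/27.3 kg/m².
3. **PK engine** — per-subject hepatic clearance by in vitro–in vivo
   extrapolation (CLint scaled by enzyme abundance, MPPGL and liver mass)
   through the well-stirred liver model
   `CL_H = Q_H·fu_b·CLint / (Q_H + fu_b·CLint)`, feeding a one-compartment
   oral model with hepatic first-pass; AUC/Cmax over the observation window.
4. **Virtual trials** — 20 trials × 10 subjects per population; geometric
   mean (95% interval) AUC and Cmax; populations compared by geometric-mean
   ratio with a bioequivalence-style flag at >20% difference.
5. **Validation** — simulated disease/healthy ratios against in vitro
   activity and animal-model comparators by absolute mean fold error,
   `MFE = max(sim/obs, obs/sim)`; MFE ≤ 2 is robust concordance.

Eight CYP probe substrates ship as documented fixture profiles: caffeine and
clozapine (CYP1A2), s-warfarin and rosiglitazone (CYP2C9), omeprazole
(CYP2C19), dextromethorphan and metoprolol (CYP2D6), midazolam (CYP3A4).

## Worked example

Pool the packaged in vitro activity study table and compare midazolam
exposure between populations (5 trials × 5 subjects for speed):

```sh
mafld-pbpk make-fixtures --out fx
mafld-pbpk pool --in fx/cyp_activity_studies.csv --method arithmetic
mafld-pbpk compare --test fx/populations/mafld.yaml --ref fx/populations/healthy.yaml \
    --compound fx/compounds/midazolam.yaml --regimen single --seed 1 \
    --n-trials 5 --n-subjects 5
```

prints

```
enzyme,endpoint,n_studies,pooled_ratio,ratio_min,ratio_max,method
CYP1A2,activity,2,0.52,0.46,0.58,arithmetic
CYP2C19,activity,4,0.4225,0.21,0.62,arithmetic
CYP2C9,activity,5,0.962,0.4,1.53,arithmetic
CYP2D6,activity,1,0.68,0.68,0.68,arithmetic
CYP3A4,activity,10,0.488,0.41,0.61,arithmetic

midazolam auc ratio 1.54 flagged=True
midazolam cmax ratio 1.01 flagged=False
```

Read: in vitro CYP2C19 activity is on average 58% lower in MAFLD models
(pooled ratio 0.42 of 4 studies, range 0.21–0.62). Under the disease
population's 38% lower CYP3A4 abundance, simulated midazolam AUC is 1.54-fold
higher than in healthy controls — a meaningful (>20%) exposure increase —
while Cmax is essentially unchanged (ratio 1.01): clearance changes move AUC
more than the absorption-dominated peak.

The same steps are available as library calls (`pool_table`,
`build_mafld_spec`, `run_virtual_trial`, `compare_populations`,
`build_validation_tables`); see the module docstrings.

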
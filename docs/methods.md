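# Methods

## Scope and model structure

The package estimates how fatty-liver-disease-associated changes in hepatic
CYP enzyme abundance translate into changes in oral drug exposure, using a
virtual-population PBPK workflow. The disposition model is deliberately
minimal: a one-compartment model with first-order absorption and hepatic
first-pass, not a full multi-organ PBPK model. The endpoints of interest are
*ratios* of AUC and Cmax between a disease and a healthy population that
share every parameter except the disease scalars; such ratios are driven by
clearance scaling and are largely insensitive to peripheral
compartmentalization. A second compartment could be added behind
`simulate_regimen` without touching the trial or validation layers.

Per subject and compound the chain is:

1. **IVIVE.** Whole-liver intrinsic clearance
   `CLint (L/h) = [Σ_i abundance_i (pmol/mg) · clint_i (µL/min/pmol) +
   clint_other (µL/min/mg)] · MPPGL (mg/g) · liver mass (g) · 60·10⁻⁶`.
2. **Well-stirred liver.** `CL_H = Q_H·fu_b·CLint / (Q_H + fu_b·CLint)` with
   `fu_b = fu / B:P`; extraction `E_H = CL_H/Q_H`; oral bioavailability
   `F = fa·Fg·(1 − E_H)`.
3. **Disposition.** Blood concentrations from the Bateman solution
   `C(t) = F·D·ka / (V(ka−ke)) · (e^{−ke t} − e^{−ka t})`, `ke = (CL_H +
   CL_renal)/V`, superposed across doses; the `ka → ke` limit uses the
   confluent form `F·D·ka·t·e^{−ka t}/V`. Plasma concentration = blood
   concentration / B:P, reported in ng/mL.

AUC and Cmax are taken by trapezoid/maximum on a 0.05 h grid over the 24 h
window after the last dose; at that resolution the trapezoid AUC of a linear
single-dose run is within 0.5% of the closed form `F·D/CL` (tested).

An optional Michaelis–Menten mode replaces the linear hepatic CLint by
`Vmax/(Km + Cu_b)` and integrates the two-state system (gut, central) with
LSODA at rtol 10⁻⁸. First-pass extraction is evaluated at the *systemic*
unbound concentration rather than the portal one — an approximation that is
exact in the linear limit (verified by a convergence test at dose ≪ Km within
1%) but understates first-pass saturation at high portal concentrations. The
mode is off by default and no shipped fixture enables it.

## Pooling of study ratios

Study-level MAFLD/control ratios are pooled unweighted per enzyme and
endpoint. Both the arithmetic mean and the geometric mean `exp(mean(ln r))`
are implemented. The default is **arithmetic** because the published pooled
column this package reproduces (0.52 / 0.96 / 0.42 / 0.68 / 0.49) equals the
arithmetic mean of the study rows, although it is labelled a geometric mean
in its source; the geometric means would be 0.52 / 0.85 / 0.39 / 0.68 / 0.48.
A warning is emitted whenever the two disagree by more than 1%, so users
choosing either method see the discrepancy. Sensitivity analysis is exposed
as stratified re-pooling by model system (microsomes / hepatocytes / biopsy /
animal); no weighting scheme is applied anywhere.

The observed comparator for validation is the reciprocal of the pooled
activity ratio (control/MAFLD orientation, so reduced activity reads as an
exposure-like increase). By default the pooled value is rounded to 2 decimals
before inverting, matching the precision at which pooled values are reported;
`round_first=False` inverts the exact value.

## Populations and sampling

The healthy baseline is literature-typical for adult volunteers, not a claim
about any proprietary population library:

| parameter | male | female | source of the default |
|---|---|---|---|
| height (cm) | N(176, 7), ±3 SD | N(163, 6), ±3 SD | typical adult anthropometry |
| BMI target (kg/m²) | 24.4 | 23.5 | typical healthy volunteers |
| haematocrit (%) | 43.0, CV 5% | 38.0, CV 5% | typical reference range |
| CYP abundance (pmol/mg) | 1A2 52, 2C9 73, 2C19 14, 2D6 8, 3A4 137 | same | literature-typical liver microsome means |
| abundance CV | 40% (log-normal) | same | typical inter-individual variability |
| MPPGL / liver / Q_H | 40 mg/g, 1650 g, 90 L/h | same | standard IVIVE scaling factors |

The height–weight model `weight = exp(a + x0·height)` uses a fixed slope
`x0 = 0.012` per cm; the intercept is solved so the model hits the per-sex
BMI target exactly at the mean height (`calibrate_height_weight`). Weight
carries a multiplicative log-normal residual with geometric SD 1.1. Covariates
with mean m and CV are drawn log-normally with the arithmetic mean preserved
(`σ² = ln(1+CV²)`, `µ = ln m − σ²/2`). Within a trial at proportion-female
0.5 the sexes alternate deterministically (exact 5/5 in a 10-subject trial),
reducing between-population variance; single draws use a Bernoulli sex.

The disease population multiplies CYP abundance means by per-enzyme scalars,
sets haematocrit to 48.2%/42.6% (M/F; equivalently a 1.12-fold increase on
the healthy means, which is how the values are documented), and recalibrates
the height–weight intercepts to BMI 29.7/27.3. Plasma protein is carried as
an `albumin_ratio` field defaulting to 1.0 (no reliable disease value was
available to set it). Haematocrit can feed exposure through the blood:plasma
ratio: when a compound declares `bp_reference_hct_pct`, each subject's B:P is
rescaled as `B:P = 1 + (B:P_ref − 1)·(hct/hct_ref)` — the red-cell-associated
excess scales with haematocrit. The shipped fixtures leave this off (the
reference platform's internal handling is unknown, and the adjustment is a
documented approximation), so by default haematocrit is carried on the
subject without affecting exposure.

**Abundance scalars.** CYP1A2 0.37 and CYP2C9 0.72 are the pooled
abundance-meta-analysis values (abundance reduced by 63% and 28%). The
source's scalars for CYP2C19, 2D6 and 3A4 are not publicly printed, so the
defaults are **calibrated**, not observed: each is solved from the
low-extraction single-enzyme identity `AUC ratio = 1/(fm·s + 1 − fm)` using
the fixture fm of the enzyme's dominant probe and that probe's published
single-dose AUC ratio (omeprazole 2.52 → s₂C19 = 0.307; dextromethorphan
1.32 → s₂D6 = 0.715; midazolam 1.55 → s₃A4 = 0.623). They are labelled
CALIBRATED in the shipped YAML and should be replaced if abundance data
become available.

## Compound fixtures

The eight probe-substrate profiles carry literature-typical oral PK
parameters (dose, ka, fa·Fg, fu, B:P, Vss, fm, total microsomal CLint,
renal clearance). They are *approximations*: the reference compound models
are proprietary, and no quantitative test or acceptance value in this package
depends on fixture PK parameters — validation arithmetic runs on the packaged
printed tables only. Per-enzyme CLint is partitioned as
`clint_i = fm_i · CLint_total / abundance_i(healthy)`, so in the healthy
population each enzyme carries its nominal fraction of clearance by
construction (tested).

## Virtual trials and comparison

Default design: 20 trials × 10 subjects (n = 200) per population,
proportion-female 0.5, ages uniform 20–65 y; single dose, or 10 doses q24h
(q12h for midazolam and dextromethorphan), each observed 24 h after the last
dose. Trials are seeded via `numpy` `SeedSequence.spawn`, so results are
exactly reproducible and trial-parallelizable. Summaries are geometric means
with 95% intervals; the default interval is the 2.5th–97.5th percentile of
the subject-level values, because published intervals of this kind at n=200
span several-fold and cannot be standard errors of the mean; a t-based CI of
the geometric mean is available (`interval="ci"`).

Populations are compared by the ratio of geometric means. The
non-equivalence flag uses a symmetric >20% rule (ratio > 1.2 or < 0.8);
the lower bound is untestable against the source tables (no printed ratio
falls below 0.8) and is the package's own reading of "increase or decrease".
Ratios are conventionally reported to 2 decimals.

## Validation statistics

`MFE = max(sim/obs, obs/sim) ≥ 1`; MFE ≤ 2 (inclusive) is classified robust,
otherwise poor. The in vitro arm matches each enzyme's pooled activity
reciprocal against the enzyme's primary probe AUC ratio (caffeine,
s-warfarin, omeprazole, dextromethorphan, midazolam); the animal arm matches
per (substrate, parameter), and per-enzyme averages are arithmetic means of
substrate-level MFEs. Comparators without a simulated counterpart are listed
as missing rather than raised. MFEs are computed on unrounded inputs and
reported to 2 decimals; tests against the published columns allow ±0.015 on
the animal table, whose printed MFEs are inconsistent with strict 2-decimal
rounding in three cells (e.g. 1.81/1.20 = 1.508 printed as 1.50).

## What the synthetic data do and do not show

The synthetic study generator draws ratios log-normally around a known truth
(`ratio = r·exp(N(0, σ))`) and exists to verify parameter recovery of the
pooling estimator (n = 500 studies at σ = 0.3 recovers r within 5%,
geometric method). It emulates between-study heterogeneity only — no
within-study sampling error, no publication bias, no systematic differences
between model systems — so a passing recovery test validates the estimator's
arithmetic, not the epidemiology of real study collections.

Likewise, the virtual-trial pipeline demonstrates that the *engine*
propagates abundance scalars into exposure ratios consistent with the
analytic low-extraction oracle (within 2% where extraction < 0.1), not that
the fixture compounds reproduce any specific clinical exposure. Known
limitation: with a literature-typical fm(CYP2C9) ≈ 0.9, the engine predicts a
~1.3-fold s-warfarin AUC increase under the 0.72 CYP2C9 scalar, whereas the
reference simulations report no change — a discrepancy attributed to
enzyme–transporter interplay that a pure CYP-scaling model cannot capture.
Transporters, non-CYP clearance pathways, disease staging and CYP2C19/2D6
polymorphism phenotypes are all out of scope.

## Numerical choices

- Profile grid 0.05 h; trapezoid AUC; Cmax/Tmax from the grid (Tmax accurate
  to one step).
- MM integration: LSODA, rtol 10⁻⁸, atol 10⁻¹², integrated piecewise between
  dose times.
- Height truncation at ±3 SD by rejection; degenerate CV = 0 inputs return
  the mean deterministically.
- Pooled ratios are clipped into the observed [min, max] to absorb
  floating-point roundoff of `exp(mean(log))` on constant inputs.
- Acceptance and test problem sizes: the end-to-end pipeline checks run a
  reduced 5-trials × 5-subjects design over four probes, chosen as the
  smallest design that still exercises sex balancing, multi-trial seeding and
  both flagged and unflagged outcomes.
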
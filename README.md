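# milknmr

Quantitative ¹H-NMR lipid profiling of bovine milk: simulation of
lipid-fraction spectra, fatty-acid quantification from signal integrals,
and PLS-DA chemometrics for discriminating organic from conventional milk.

## The problem

The fatty-acid profile of milk fat shifts with the feeding regime:
forage-based (organic) herds give milk that is richer in conjugated
linoleic acid (CLA), linoleic and α-linolenic acid and total unsaturated
fatty acids (UFA), and poorer in caproleic acid, than concentrate-fed
(conventional) herds. A single quantitative ¹H spectrum of the extracted
lipid fraction carries enough information both to quantify these minor
species and to classify a sample's origin. This package implements that
workflow end to end and, because raw milk spectra of this kind are not
publicly deposited, ships a forward simulator so that every stage is
testable against known ground truth.

## The model

**Quantification.** With `I_x` the integral at `x` ppm and
`I_TL = I0.88 + I0.95` the total methyl integral (three protons per acyl
chain, so `I_TL/3` counts chains), composition in mol % of chains is

    α-linolenic = 100 · 3 I2.81 / (4 I_TL)        (4 bis-allylic H)
    linoleic    = 100 · 3 I2.77 / (2 I_TL)        (2 bis-allylic H)
    CLA c,t     = 100 · 3 I6.28 / I_TL            (H11, 1 H)
    CLA t,t     = 100 · 3 I5.99 / (2 I_TL)        (H10 + H11)
    caproleic   = 100 · 3 I5.80 / I_TL  =  100 · 3 I4.99 / I_TL
    UFA         = 100 · (D + 2 I4.99) / (2 C)
    SFA         = 100 − UFA
    MUFA        = UFA − linoleic − α-linolenic − CLA

where `D` (allylic CH₂, 2.02 ppm) collects 4 H per non-terminal
unsaturated chain but only 2 H from caproleic acid — the one milk MUFA
with a terminal double bond — whose extra vinyl proton appears in `I4.99`;
`C` (α-carbonyl CH₂, 2.33 ppm) collects 2 H from every chain. The
pure-caproleic limit (`D = 2n, I4.99 = n, C = 2n → 100 %`) fixes the
correction.

**Simulation.** Each resonance is a Lorentzian of area
`mole fraction × protons × lipid scale × (1−E)/(1−E cos θ)`, with
`E = exp(−TR/T1)` the Ernst steady-state factor (TR = 9.3 s, θ = 30°
relax even the slowest milk protons, T1 = 3.2 s, to ~99.2 %). Cohorts add
per-species lognormal composition jitter, per-sample lipid scale factors
(1.5 % vs 3 % fat subgroups) and Gaussian noise.

**Chemometrics.** Spectra are bucketed into 631 bins of 0.01 ppm
(0.03–6.34 ppm), optionally normalized by `3/I_TL` per sample ("NorCont",
removing total-lipid differences), Pareto-scaled, and analysed by PCA and
a NIPALS PLS-DA implemented here. Validation uses segmented
cross-validation (Q²), a two-sided Fisher exact test on the pooled
out-of-fold confusion matrix, 100-iteration label-permutation testing,
Hotelling-T² outlier flagging and per-bucket VIP scores.

## Worked example

```bash
milknmr run --outdir runs/demo --seed 1
```

simulates the processed-sample design (14 organic, semi-skimmed, vs 16
conventional samples of which half carry twice the lipid), quantifies every
sample, fits and validates the PLS-DA, and writes `runs/demo/report.md`:

```
| quantity        | conventional  | organic       | t-test p |
| alpha_linolenic | 0.81 +/- 0.07 | 1.01 +/- 0.15 | 2.31e-04 |
| linoleic        | 2.23 +/- 0.22 | 2.88 +/- 0.22 | 9.90e-09 |
| cla_ct          | 0.54 +/- 0.05 | 1.03 +/- 0.09 | 1.71e-13 |
| caproleic       | 2.53 +/- 0.17 | 1.87 +/- 0.25 | 1.99e-08 |
| ufa             | 24.33 +/- 1.64| 27.63 +/- 1.55| 4.77e-06 |

- PLS-DA R2Y (cum., 3 components): 0.96
- Q2 (7-segment CV): 0.90
- correct predictions: 100.0%
- Fisher exact p: 6.88e-09
- permutation (100 iterations): Q2 intercept -0.49, valid
```

Organic samples show higher CLA, PUFA and total UFA and lower caproleic
acid; the cohorts separate completely (p = 1/C(30,14) ≈ 6.9 × 10⁻⁹), and
the permutation test confirms the model is not overfitted. The same
stages are available programmatically (`simulate_cohort`,
`extract_integral_set`, `quantify`, `PLSDA(...).fit()`) and as the
`simulate`, `quantify`, `bucket`, `pca`, `fit-plsda`, `permute` and
`report` subcommands.

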
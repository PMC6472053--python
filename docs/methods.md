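# Methods

This note records the models, conventions and numerical choices behind
`milknmr`, and what the synthetic-data tests do and do not demonstrate
about real milk spectra.

## Forward model of the lipid-fraction spectrum

A sample is a mixture of eight acyl-chain species — butyric acid, a lumped
saturated pool (6:0–18:0), an oleic-type MUFA pool, linoleic,
α-linolenic, two conjugated-18:2 groups (the three co-resonating
cis/trans isomers lumped, and the trans/trans isomer) and caproleic acid —
given as mole fractions of chains. Each proton group of each species
(shipped in `data/assignments.yaml`) contributes a Lorentzian at its
assigned shift with area

    mole_fraction × protons_per_chain × lipid_scale × f_ss(T1),

where `f_ss = (1−E)/(1−E·cosθ)`, `E = exp(−TR/T1)`, is the steady-state
fraction of equilibrium magnetization sampled by repeated pulses of flip
angle θ and recycle time TR. At the quantitative defaults (TR = 9.3 s,
θ = 30°) the slowest-relaxing milk protons (caproleic terminal vinyl,
T1 = 3.2 s) reach ≈ 99.2 %, so differential saturation is negligible —
which is exactly why the quantification equations can ignore T1. Groups
without a measured T1 use a 2.0 s fallback; this affects simulation
realism only, not the equations.

Glycerol-backbone protons (4.15/4.28/5.27 ppm; 3.73 ppm for the minor DAG
fraction) are booked per glycerol unit, one unit per three chains
(pure-TAG assumption). The chemical-shift reference
(hexamethylcyclotrisiloxane, 0.172 ppm) has a fixed area independent of
`lipid_scale`, as a constant added amount.

**Chain-count convention.** Caproleic acid (9-decenoic) chemically lacks a
terminal methyl — its C10 is the vinyl =CH₂. The quantification model,
however, counts chains by `I_TL/3` and therefore assumes every chain
contributes three methyl-region protons. The simulator follows the model:
it books a 3 H methyl-region entry per caproleic chain. This is a
deliberate idealization; on real spectra, percentages are biased by the
(small) caproleic fraction missing from `I_TL`.

**Lineshape.** Pure Lorentzians, default FWHM 0.5 Hz at 500 MHz
(exponential broadening of 0.3 Hz plus a well-shimmed residual width; the
fine structure of a 7.2 Hz triplet is resolvable at this width, as in the
experimental spectra). Multiplets use first-order splitting only — each
listed coupling is to an equivalent CH₂ pair and splits the line 1:2:1 —
which is sufficient because quantification integrates windows, not
shapes. The axis spans −2 to 12 ppm (14 ppm spectral width) with 2¹⁶
points, the acquisition's digitization; at this sampling the trapezoidal
window integrals are converged (doubling the point count changes no
reported percentage by more than 10⁻³ pp).

The linewidth matters quantitatively: Lorentzian tails are heavy, and the
bis-allylic windows are only 0.06 ppm wide with peaks 0.04 ppm apart. At
1.5 Hz each bis-allylic window loses ≈ 3.6 % of its peak to tail
truncation and the large aliphatic/α-carbonyl signals leak measurably
into the allylic window, biasing UFA by ≈ 0.2 pp; at 0.5 Hz a 128-corner
sweep of the realistic profile box bounds every recovery error at
0.052 pp, within the 0.1 pp budget the round-trip oracle enforces.

**Integration windows** (`data/windows.yaml`) are package conventions
centred on each integral's shift and chosen to isolate it from the
neighbours; the α-carbonyl window C extends to 2.40 ppm so that the D
(1.93–2.09) and C (2.25–2.40) windows truncate their Lorentzians by
matching fractions, keeping the UFA ratio `(D + 2 I4.99)/(2C)` unbiased.
The I0.95 window (0.92–1.01) deliberately covers both the butyric CH₃
(0.95) and the α-linolenic CH₃ (0.98), per the definition of `I_0.95`.
All bounds are overridable from the run config; overlapping windows are
rejected before any computation.

## Equations

The composition equations are ratios of window integrals to the
chain-count denominator `I_TL/3`; their printed sources are partially
corrupted typographically, so the implemented forms are fixed by proton
stoichiometry: α-linolenic has four bis-allylic protons (two CH₂ between
three double bonds), hence the factor `3/(4 I_TL)`; the UFA closed form
`(D + 2 I4.99)/(2C)` follows from 4 allylic H per non-terminal
unsaturated chain, 2 allylic H + 1 vinyl H (I4.99) for caproleic, and 2
α-carbonyl H per chain, and is validated by the pure-oleic and
pure-caproleic 100 % limits. Noise can push a window integral slightly
negative; integrals are floored at zero with a logged warning. If
`D < 2 I4.99` (possible only under extreme noise), UFA is clipped to the
caproleic-only floor, again with a warning. The ω-6:ω-3 ratio uses
linoleic over α-linolenic only — no other ω-3/ω-6 species is quantified.

## Cohort generator

Class presets are the package's composition conventions for organic and
conventional milk, chosen once to satisfy the qualitative and
quantitative constraints of the study system: total UFA 28.0 vs
24.0 mol %; organic higher in CLA c,t (1.0 vs 0.55), linoleic (2.9 vs
2.16) and α-linolenic (1.0 vs 0.8); conventional higher in caproleic
(2.4 vs 1.8); ω-6:ω-3 2.9 vs 2.7; butyric 9 mol % in both. Per-sample
composition jitter is lognormal per species (default 8 % relative,
mean-preserving) followed by renormalization, which keeps fractions
positive; lipid scale factors model the fat subgroups (the demo design
gives half the conventional samples twice the lipid) with 5 % lognormal
scale jitter. One cohort seed drives deterministic per-sample substreams,
so cohorts are exactly reproducible.

What the generator does *not* emulate: phase and baseline errors, solvent
and water artefacts, shim-dependent lineshape distortions, ¹³C
satellites, the full multiplet structure of overlapping TAG resonances,
chain-length heterogeneity within the lumped pools, and biological
covariance between species (jitter is independent per species). Passing
tests therefore demonstrate the correctness of the analysis chain given
the model's assumptions, not instrument-grade robustness.

## Processing

Spectra are stored on a descending ppm axis. Referencing translates the
axis so the reference maximum (searched within ±0.05 ppm of 0.172 ppm,
and required to stand out from the local median by five robust sigma)
sits exactly at 0.172 ppm. Integration is trapezoidal on the native axis
with linear interpolation at the window edges, making areas exactly
additive over adjacent windows; bucketing (631 half-open bins
`[0.03+0.01k, 0.03+0.01(k+1))`) is computed from the cumulative integral
and hence partitions the full-range area to machine precision. Baseline
is assumed corrected upstream; no per-window baseline is subtracted by
default.

## Chemometrics

* **Reference-region masking.** Bucket matrices zero the 0.12–0.22 ppm
  buckets by default. The reference is not a lipid signal; after NorCont
  its fixed amount anti-scales with lipid content and becomes a spurious
  high-variance pseudo-variable. Zeroed columns keep the 631-column
  layout and drop out under Pareto scaling (constant columns map to 0).
* **NorCont** multiplies each sample row by `3/I_TL`, with `I_TL` the sum
  of the methyl-window buckets, so buckets become per-proton % contents
  and total-lipid differences cancel exactly (up to the masked reference
  tails).
* **Pareto scaling** centres columns and divides by the square root of
  the sample standard deviation — gentler than unit variance, so
  abundant signals are damped without magnifying noise buckets.
* **PCA** is the SVD of the centred matrix.
* **PLS-DA** is NIPALS on one-hot, centred Y with X- and Y-deflation per
  component; convergence tolerance 1e-12 on the score vector, max 500
  iterations, error on non-convergence. Weights are unit-norm, scores
  orthogonal; `R²Y = Σ_a ‖t_a‖²‖q_a‖² / ‖Y_c‖²`. Prediction uses
  `B = W(PᵀW)⁻¹Qᵀ` and argmax over predicted one-hot columns. The
  library default is 2 components (score plots use two latent
  variables); the pipeline default is 3, because the processed-sample
  design carries a within-class fat-content subgroup that consumes one
  latent variable before the class structure.
* **Cross-validation** uses deterministic stratified segments (round
  robin within class; default 7 segments), or whole replicate groups
  when given, so replicates never straddle folds. A segment that would
  hold an entire class is an error. `Q² = 1 − PRESS/TSS`; out-of-fold
  predictions are pooled into a confusion matrix for the % correct and
  the Fisher exact p (a zero-margin confusion matrix yields p = 1).
  Scaling is refit on each training fold.
* **Permutation testing** (default 100 iterations) refits model + CV
  under permuted labels and regresses R²Y and Q² on the absolute
  correlation between permuted and true labels, the original model
  included at correlation 1; the validity flag requires all permuted
  values below the original and a negative Q² intercept.
* **Fisher exact test** enumerates the hypergeometric support and sums
  probabilities ≤ that of the observed table (two-sided convention);
  verified exhaustively against an independent implementation for all
  margins ≤ 20.
* **Hotelling T²** uses the sample covariance of the scores and the
  in-model limit `A(n−1)/(n−A)·F₁₋α(A, n−A)` (α = 0.05). All-identical
  scores flag nothing; a genuinely singular covariance is an error.
  Outlier exclusion in the pipeline is one-shot: flag, drop, refit once.
* **Marker t-tests** are Welch by default (pooled optional); raw
  p-values are reported, with no multiple-testing correction by default
  (a Benjamini–Hochberg step would be a caller-side addition).

## Test oracles and problem sizes

The round-trip oracle simulates noise-free spectra over a 200-point Latin
hypercube of milk-realistic profiles — butyric 5–12, caproleic 0.5–4,
linoleic 1–5, α-linolenic 0.3–2, CLA c,t 0.2–2, CLA t,t 0.05–0.3, oleic
12–30 mol %, saturated pool the remainder — and requires every quantified
percentage to match its seeded value within 0.1 pp. Cohort-level checks
use 20 samples per class (noise on) for the UFA means and the 14 + 16
processed-sample design for classification; permutation checks use 25–30
iterations in tests and 100 in the pipeline default. These sizes keep the
full suite to a couple of minutes on one CPU while leaving the acceptance
properties comfortably over-determined.

## Known limitations

Percentages are mole % of acyl chains, not weight %; no absolute (mM)
quantification is attempted. The three cis/trans CLA isomers are lumped,
as are the saturated and MUFA pools. JCAMP-DX I/O is not provided;
spectra are two-column CSV. The PLS-DA is strictly two-class, without
OPLS or batch correction. Real-spectrum deviations listed under the
cohort generator apply to every downstream claim.
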
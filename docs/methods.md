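# Methods

This note records the models implemented in `steatopipe`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter when comparing results.

## Signal model and the α estimator

The simulator (`signal_sim`) treats an ROI as two proton pools, water and
fat, in a spoiled gradient-echo steady state. Each pool contributes a
weight

w = ρ · sinθ · (1 − E₁) / (1 − cosθ·E₁),  E₁ = e^(−TR/T1),

and the magnitude signal at echo time TE is |W ± F| · e^(−TE/T2*), with the
minus sign at the opposed-phase echoes (TE₁, TE₃) and plus at the in-phase
echo (TE₂). Gaussian noise, if requested, is added independently per echo.
Simulation is restricted to fat fractions ≤ 0.5: magnitude-only dual-echo
data cannot distinguish water-dominant from fat-dominant voxels, and the
pipeline adopts the water-dominant branch throughout (population MRS
surveys place essentially all livers below 50 % triglyceride content).

The estimator (`alpha`) computes T2* = (TE₃−TE₁)/ln(OP₁/OP₂) from the two
opposed-phase echoes and corrects OP₁ forward to the in-phase echo time
before forming α = (IP − OP₁·e^(−ΔTE/T2*)) / (2·IP). Without T1 weighting
(θ = 90°, TR ≫ T1) this inverts the signal model exactly: α equals the fat
proton fraction to machine precision, independent of the simulated T2*
(verified over f ∈ [0, 0.45], T2* ∈ [5, 40] ms). With the protocol's
deliberate T1 weighting (θ = 70°, TR = 88 ms), fat's shorter T1 gives it a
larger per-proton weight; α then follows the calibration model below with
k equal to the weight ratio, which is the sensitivity-enhancement mechanism
the method exploits.

Numerical conventions: OP₁ ≤ OP₂ (noise-inverted decay) falls back to no
correction (decay factor 1) and flags the slice rather than failing the
subject; zero intensities are hard errors; raw α outside [0, 1] is clamped
(negative values arise from noise at very low fat). Slices are averaged at
the α level, after per-slice T2* correction. These choices are logged so
silent fallbacks are auditable.

## Calibration

α = k·f/(k·f + 1 − f) is a strictly monotone bijection of [0, 1] for every
k > 0, with dα/df(0) = k. `fit_k` minimises the sum of squared α residuals
by bounded scalar minimisation on k ∈ (0, 100], tolerance 1e−9 —
deterministic, no random initialisation. All-zero fat fractions are
rejected as unidentifiable; constant nonzero fractions fit but warn that
the data give no leverage over the model's shape. The HIS-MORPH ~ HIS-VIS
link is ordinary least squares with intercept (a through-origin variant is
available); grade cutoffs on the morphometric scale are the line evaluated
at the visual boundaries.

## Morphometry

The pipeline mirrors standard particle analysis on thresholded histology:
green-channel threshold at ≥ 220 (the comparison is inclusive; the
published description does not state strictness), 8-connected component
labelling, per-particle hole filling (vacuoles are voids and should be
solid), size filter 100–10000 px and circularity filter 0.5–1 with both
bounds inclusive. The tissue denominator is the inverted threshold image
with all interior holes filled, so vacuole and vessel voids count as
tissue; fat is deliberately not subtracted from it.

Perimeter is estimated with the weighted chain-code estimator
(`skimage.measure.perimeter`, ImageJ-comparable), not a raw pixel-edge
count: digital circles of diameter 12–120 px measure circularity 0.91–1.03
(clipped to 1) under the weighted estimator, whereas raw edge counting
pushes small circles below the 0.5 acceptance bound and would wrongly
reject legitimate vacuoles. A consequence worth knowing: a digital square
of side s has weighted perimeter 4(s−1), so its circularity (~0.93–0.97 for
small s) exceeds the naive-estimator value π/4. Particles touching the
image border are included by default (configurable), pixel size defaults to
0.5 µm/px (back-inferred from the 100 px ↔ 5.6 µm equivalence), and
labelling order is row-major and deterministic.

## Synthetic data

**Histology phantoms** composite a textured tissue ellipse (trichrome-like
colour, green well below threshold) on a white slide, with three kinds of
bright voids: circular vacuoles (diameters drawn from a configurable range,
default 8–45 µm), oversized elongated vessels (area 12000–22000 px,
elongation 3.5–5), and thin tears (very low circularity). Structures never
overlap each other or the tissue border (2 px separation), so the
ground-truth fraction is exactly fat pixels / tissue pixels. Vacuole
placement is rejection-resampled until the achieved fraction is within
±10 % relative of target; an unreachable target raises rather than
silently under-filling. Phantoms do not emulate staining variability,
partial-volume blur at vacuole edges, overlapping or clustered vacuoles,
micro-vs-macrovesicular morphology, or scanner artefacts — so passing
recovery tests demonstrates correctness of the segmentation chain, not
robustness to real-slide appearance. On these clean phantoms the pipeline
recovers the ground truth exactly; real sections will not behave this well.

**Cohorts** follow the generative chain visual percent → morphometric
fraction → α. HIS-VIS is a two-component mixture — a low-fat bulk
(lognormal, median 2.5 %) and a fatty-liver subgroup (27 % of patients,
lognormal median 45 %) — quantized the way pathologists report (integers
below ~12 %, steps of five above, a cluster at zero) and clipped to
0–98 %. HIS-MORPH follows the regression line implied by the published
grade cutoffs (slope 0.00103 per %, intercept 0.0088) with multiplicative
lognormal scatter (log-sd 0.10); α comes from the calibration model with
k = 3 applied to a dispersed effective fraction (log-sd 0.10) plus
per-slice Gaussian noise (sd 0.01), clamped to [0, 1]. Controls draw α from
a lognormal with median 0.024, all below 0.2. These levels were chosen so
the simulated cohort sits in the diagnostic regime the method targets —
ROC areas above 0.9 at every grade boundary and k recoverable within 10 % —
while keeping the stated distribution landmarks (patient HIS-VIS median
within 2–10 % across seeds, control α range). Known limitation: the
implied inter-method scatter (Bland–Altman log-sd ≈ 0.2) is milder than
real biopsy-vs-MRI comparisons (≈ 0.5), and the morphometric median
(~0.015) sits below the clinical value (~0.029) because the regression
line and the marginal median cannot both be matched by a linear link with
symmetric noise; the regression line was prioritised because the cutoff
derivation consumes it. All randomness flows from one seed; per-stage
child seeds are derived by hashing.

## Diagnostics

AUC uses the Mann–Whitney pairwise formulation via midranks (ties count
½), identical to trapezoidal integration of the empirical ROC. The
operating cutoff scans midpoints between sorted unique scores plus
sentinels, maximises sensitivity + specificity, and breaks ties toward the
lowest cutoff (favouring sensitivity); positive calls are score > cutoff.
Sensitivity/specificity intervals are exact Clopper–Pearson; the AUC
p-value is the asymptotic Mann–Whitney two-sided test (reported for
completeness, not a validated surface). Bland–Altman agreement is computed
on natural logarithms (the difference variance grows with fat level on the
raw scale); limits are mean ± 1.96 sd, their confidence intervals use
SE = sd·√(3/n) with the t(n−1) quantile, and exponentiating the limits
gives multiplicative ratio bounds. The control reference range is a
prediction interval on the log scale, mean ± t·sd·√(1 + 1/n),
exponentiated; natural logs are used throughout for consistency.
Dichotomisation conventions: the first (any-steatosis) reference cutoff
uses ≥, higher ones use >; degenerate strata (one class absent in a small
sample) are skipped with a warning rather than failing the report.

## Problem sizes

Default phantoms are 512×512 px (~138 k tissue pixels) and cohorts are 59
patients + 10 controls, matching the study design the pipeline emulates;
property suites iterate over tens of seeds and the calibration-recovery
check over 200 seeds. The whole test suite and the acceptance script each
complete in seconds on one CPU.
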
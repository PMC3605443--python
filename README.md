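# steatopipe

Quantifying liver fat (hepatic steatosis) normally requires a biopsy: a
pathologist visually estimates the percentage of hepatocytes containing fat
vacuoles (HIS-VIS, graded at the clinically relevant 5 / 33 / 66 %
boundaries), optionally backed by computer-assisted morphometry of the
stained section (HIS-MORPH, the areal fraction occupied by fat vacuoles).
`steatopipe` implements a rapid, non-invasive alternative — a fat-sensitive
parameter **α** computed from a single breath-hold triple-echo gradient-echo
MRI acquisition — together with the morphometric reference method and the
statistics needed to evaluate one against the other. A synthetic-data layer
(histology phantoms with exact ground truth, a two-compartment ROI signal
simulator, whole-cohort generation) makes every stage runnable and testable
offline.

It is aimed at researchers in quantitative MRI and digital pathology who
want a tested, reproducible implementation of this measurement chain or a
ground-truthed sandbox for benchmarking related fat-quantification methods.

## The measurement chain

**MRI α.** The acquisition yields three echoes — opposed-phase at TE₁,
in-phase at TE₂, opposed-phase at TE₃ (2.38 / 4.76 / 7.14 ms at 1.5 T,
TR 88 ms, flip 70°). Per slice, with ROI-mean intensities OP₁, IP, OP₂:

    T2* = (TE₃ − TE₁) / ln(OP₁ / OP₂)
    α   = (IP − OP₁ · e^(−(TE₂−TE₁)/T2*)) / (2 · IP)        ∈ [0, 1]

i.e. the opposed-phase signal is decay-corrected to the in-phase echo time
before forming the Dixon fraction; α is averaged over three axial slices.
The deliberately high flip angle T1-weights the signal so that fat protons
outweigh water protons, amplifying sensitivity at low fat.

**Calibration.** α relates to the tissue fat volume fraction *f* through

    α = k·f / (k·f + (1 − f))

where the constant *k* lumps the proton-density and T1-weighting
differences (k = dα/df at f = 0, so k > 1 boosts low-fat contrast). `fit_k`
estimates k by least squares; `invert_alpha` maps α back to an equivalent
areal fat fraction.

**Morphometry.** HIS-MORPH is measured by thresholding the green channel at
220/255 (bright voids: vacuoles, vessels, tears, slide background), keeping
connected components with area 100–10000 px and circularity
(4πA/P²) 0.5–1 as fat vacuoles, and dividing their summed area by the
hole-filled tissue outline. At ~0.5 µm/px the size bounds correspond to
vacuole diameters of 5.6–56 µm.

**Diagnostics.** ROC areas of α against the dichotomised histology
references, operating cutoffs by maximum sensitivity + specificity with
exact Clopper–Pearson intervals, log-scale Bland–Altman limits of agreement
(back-transformed to ratio bounds), and a 95 % prediction interval of
control-subject α as a healthy reference range.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_calibrate.py --seed 1
python analysis/04_diagnostics.py --seed 1
```

which prints (abridged):

```
calibration constant k = 2.922 (r^2 = 0.986, n = 59)
morphometric grade cutoffs: 5.0% -> 0.0141, 33.0% -> 0.0441, 66.0% -> 0.0795

reference cutoff_label  alpha_cutoff      auc  sensitivity_pct  specificity_pct
  HIS-VIS         >=5%      0.045408 0.958042        90.909091       100.000000
  HIS-VIS         >33%      0.123141 1.000000      100.000000       100.000000
  HIS-VIS         >66%      0.171738 0.991758      100.000000        98.076923
controls' 95% prediction interval for alpha: 0.0079 to 0.0534 (n=10)
```

The simulated 59-patient cohort was generated with k = 3 and the
regression line tying the 5 / 33 / 66 % visual grades to morphometric
fractions 0.014 / 0.043 / 0.077; the fitted values recover both (k̂ = 2.92,
cutoffs 0.0141 / 0.0441 / 0.0795), and α separates the grade boundaries
with ROC areas above 0.95. `analysis/02_phantom_morphometry.py` validates
the morphometric pipeline against phantom ground truth (exact recovery on
clean phantoms, with vessels and tears correctly rejected), and
`analysis/05_signal_roundtrip.py` shows the α estimator inverting the
signal model to machine precision without T1 weighting.

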
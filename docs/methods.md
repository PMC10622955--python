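# Methods

`brainage` re-implements a deep-learning brain-age analysis as a fully
testable pipeline. Because the clinical cohort it models (70 female SLE
patients and 24 age-matched healthy controls with 3T MPRAGE imaging,
neuropsychological testing and plasma NfL) is not publicly deposited, the
package ships a synthetic-phantom generator whose defaults encode the study
conditions, so that every downstream stage — CNN age regression, bias
correction, z-scoring, occlusion attention, cohort statistics — can be
validated against a known ground truth.

## The phantom model

A phantom is a pair of co-registered 3D grids: a noisy intensity volume and
a noise-free integer label map (0 background, 1 sulcal CSF, 2 gray matter,
3 white matter, 4 ventricular CSF, 5 WMH). Geometry is four nested
concentric ellipsoids sharing the aspect ratio of the intracranial
ellipsoid (semiaxes 13 x 14.5 x 13 voxels on the default 32^3 grid). This
is deliberately not anatomy: the signal a brain-age model feeds on is
"atrophy-like morphology varies with age", and ellipsoids make every tissue
volume analytically computable.

Aging is linear in three structures:

- ventricular volume grows by `ventricle_growth` (8 voxels/y) from
  `ventricle_base_volume` (150 voxels at age 18);
- the GM ribbon thins by `gm_thinning` (20 voxels/y) from
  `gm_ribbon_base`, the lost volume accruing one-for-one to the sulcal CSF
  shell (so GM + sulcal CSF is conserved and the WM outer boundary is
  fixed while ventricles eat into WM from inside — reproducing the pattern
  of a clearly lower GM and higher CSF fraction but a near-unchanged WM
  fraction between patients and controls);
- WMH lesions are small hyperintense spheres carved into WM, with a
  Poisson-distributed count of expectation
  `wmh_rate x multiplier x max(0, age - 30)`; patients carry a rate
  multiplier (default 2).

Base volumes were calibrated once, numerically, so that the *voxelized*
label counts of a control cohort at the control mean age (37 y) land on the
healthy-control volumetry of the study population: CSF (sulcal +
ventricular) ~10.8 % of ICV, GM ~52.3 %, WM ~36.9 %, WMH ~0.05 mL; with
the injected patient offset the patient means land near the published
patient values (CSF ~11.9 %, WMH ~0.18 mL). Analytic ellipsoid volumes
differ from voxel counts by a near-constant surface term (about +156
voxels on the thin sulcal shell at 32^3), which the calibration absorbs.
No quantitative atrophy rates are reported for the cohort itself, so the
slopes are free parameters fixed only by this calibration; they are not
estimates of human atrophy rates.

Per-subject biological variability is a single zero-mean Gaussian jitter
(SD 2 y) on the *structural age* shared by all structures. This keeps
label volumes monotone in effective age for a fixed seed, leaves cohort
means untouched, and gives the control brain-age-gap distribution a
realistic spread (so z-scores are finite and the patient z elevation is of
the same order as the published +0.6, rather than arbitrarily large).

Patients are built at `chronological age + delta`, where delta (the
disease-related aging offset) is drawn from N(4, 2) years truncated at
zero — the quantity the pipeline must recover. The published cohort-level
analog is patients' brains "looking 3.6 years older". Negative offsets can
be allowed by flag. Covariates: log10 plasma NfL is linear in age
(0.010/y) and offset (0.035/y) with Gaussian noise (SD 0.12), intercept
0.33 — giving control age-adjusted means near 0.70 and patient means near
0.84; the five cognitive domain scores start at the normative mean 100
(SD 15) and fall linearly with the offset (reaction time fastest,
2.4 points per offset-year), placing patient means near the published
90–96 range. Cohorts are all-female by design; the generator makes no sex
distinction.

All randomness flows from one root seed through named substreams (ages,
structure, noise, covariates, WMH), so partial reruns are reproducible and
label geometry, intensity noise and covariates can be varied independently.

What the phantoms do *not* emulate: anatomy (no hemispheres, gyri,
subcortical nuclei), MRI physics (no bias field, partial-volume mixing,
k-space artifacts), registration error, scanner/site effects, or any
pathology beyond atrophy surrogates and WMH spheres. Consequently, a
passing suite shows the *method* is implemented correctly and recovers
injected effects under realistic sample sizes and noise — not that the
published effect would replicate on real MRI.

## Preprocessing and volumetry

Phantoms are generated pre-registered on the template grid, so the minimal
preprocessing is min–max intensity normalization over the brain mask
(labels > 0; the phantoms come "pre-stripped") with out-of-mask voxels set
to zero; a general affine resampler (trilinear for intensities, nearest
for labels, pull-back convention) is provided for completeness. Volumetry
reports GM/WM/CSF as % of ICV and WMH in mL; CSF pools sulcal and
ventricular compartments (the study reports a single CSF number), and WMH
voxels count as WM tissue in the WM fraction while also being reported
separately in mL — the reporting convention is stated here because the
source tables do not state theirs (at WMH loads of ~0.01 % of ICV the two
conventions are numerically indistinguishable).

## The age regressor

The model is a small 3D CNN: four convolution blocks (8, 16, 32, 64
filters, 3^3 kernels, ReLU), global average pooling, a fixed feature gain,
and a linear scalar head in years. Two choices are deliberate
implementation decisions rather than reproductions, since the source
architecture is external and not specified:

- downsampling is by stride-2 convolution rather than stride-1 convolution
  followed by pooling: at 32^3 on one CPU the pooled variant costs ~8x the
  FLOPs for no representational benefit at this task; per-block average
  pooling remains available through `ArchitectureSpec`;
- the *feature gain* (default 8) is a fixed multiplier between the pooled
  features and the head. With unit-scale inputs, pooled ReLU features are
  O(0.1); at the protocol's learning rate (0.001) a mean-absolute-error
  SGD signal through such small features cannot move the head far enough
  within the iteration budget, while much larger features make the
  quadratic part of the optimization unstable. The gain puts the head's
  input on the O(1) scale where both conditions hold. It is mathematically
  equivalent to a per-layer learning-rate multiplier on the head.

Training follows the published protocol: MAE cost, SGD with learning rate
0.001, momentum 0.1, inverse-time decay 5e-5 per optimizer step
(`lr_t = lr / (1 + decay * t)`, the classic SGD decay convention), batch
size 8, 150 iterations, on-the-fly augmentation by random rigid jitter
(rotation up to 10 degrees about a random axis, translation up to 2 voxels
per axis; the source does not state magnitudes). "150 iterations" is read
as 150 epochs; a config knob (`iteration_unit`) switches to raw optimizer
steps. Whether the original SGD used Nesterov momentum is unstated; plain
momentum is implemented. The head bias is initialized to the training-age
mean so early optimization works on the residual signal. Everything is
float32, CPU-only, and deterministic for a fixed seed and thread count.
The convolution engine (im2col + BLAS, hand-derived backward pass) is
verified against a scipy correlation oracle and adjoint identities;
augmentation resampling has a fused numba kernel with a pure-numpy
reference path.

5-fold cross-validation deterministically shuffles subjects from the seed;
every subject is out-of-fold exactly once.

## BrainAGE scoring

Raw gap = predicted − chronological age (positive = older-looking). The
age bias is removed by OLS of the *gap* on chronological age; the
residual is the corrected gap, converted to a z-score against the control
group (sample SD, n−1). Two ambiguities in the source are resolved as
follows and kept configurable:

- the printed regression equation nominally regresses *predicted age* on
  age, yet the reported slope (alpha = 0.13) is plausible only for the gap;
  gap-on-age is the default (`regressand="gap"`), and the literal
  predicted-on-age variant is provided behind the same interface (the two
  are algebraically identical corrections, differing by 1 in the slope);
- which population the bias was fitted on is unstated; the default is the
  study's healthy controls, configurable to the training set.

Residualize-then-z-score is the order of operations. Residualization is
idempotent, corrected gaps are exactly uncorrelated with age on the
fitting set, and z-scoring is affine-invariant — all asserted in tests.

## Occlusion attention

A sliding mask (default 8^3 voxels, non-overlapping stride; "sliding" is
stated without a stride in the source) replaces the input region with the
fill value 0 — the background value after min–max normalization — and the
placement's weight is the absolute change in predicted age. Each voxel
accumulates the weights of the placements covering it, divided by its
coverage count when overlapping strides are used; population maps average
overlap-normalized subject maps. These overlap/normalization conventions
are documented choices, not inferred from the source. Localization is
quantified as a ranked-region test — mean attention inside the
age-signal tissues (ventricles + GM ribbon) over the background-shell
mean — never as anatomical claims.

## Statistical plan

Patient-control contrasts use pooled-SD Cohen's d and Student t (Welch
available); the pooled-SD formula is used for the skewed WMH row too,
because it is the formula that reproduces all five printed effect sizes.
WMH is tested with Mann-Whitney U (exact for tie-free samples up to n=20,
tie-corrected normal approximation otherwise). Three-group comparisons
use ANOVA or Kruskal-Wallis with Bonferroni pairwise follow-up. Log NfL
uses base-10 (the printed patient mean of 0.84 for concentrations around
7 pg/mL identifies the base) and is compared age-adjusted via ANCOVA
(common-slope model; adjusted means at the grand-mean age). The 2x2
chi-square uses no continuity correction — the variant that reproduces the
printed DMARD p of 0.01 — with the Woolf CI for the odds ratio.

The high/low BrainAGE cutoff is re-derived per run: ROC of the patient
z-scores against low reaction-time performance (standardized score < 80),
threshold at the maximal Youden index over midpoints between consecutive
unique scores, ties broken toward higher specificity (the largest tied
threshold). The published cohort-specific cutoff (z = 0.9) is kept as a
documented constant, not hard-coded into the pipeline. If a simulated
cohort happens to contain a single outcome class the pipeline falls back
to a median split and logs it.

Risk-factor modelling screens covariates univariately (t for continuous,
chi-square for binary; enter at p < 0.2), drops the later-listed member of
any candidate pair with |Pearson r| > 0.6 (column order is the declared
priority — the source names the excluded variables but not the rule), and
fits a maximum-likelihood logistic regression (Newton/IRLS) with Wald CIs.
Non-convergence (e.g. separation) raises; no penalized fallback is
substituted silently. The candidate set in the pipeline is age, log NfL,
WMH and the cognitive domains *except* reaction time, which defines the
outcome cutoff.

No multiplicity adjustment is applied across table rows — matching the
source analysis — only the pairwise post-hoc comparisons are adjusted.
This is a faithful reproduction choice, not a statistical recommendation.

## Validation design and problem sizes

The repeated-seed experiments run the full protocol at the study design:
200 training phantoms at 32^3 (the full-scale 182 x 218 x 182 grid is kept
as a documented constant; the phantom geometry scales), 24 controls, 70
patients, ten pre-registered root seeds. One trained model per seed is
shared by the offset-recovery, model-sanity, attention and
null-calibration checks, and each seed also scores a matched
zero-offset cohort for the null arm. Expected behaviour, asserted in
`tests/test_acceptance.py`: corrected-gap difference within [2, 6] years
of the injected ~4 y offset with one-sided p < 0.05 (>= 9/10 seeds);
held-out MAE below half the age SD, above-0.7 correlation with effective
age, constant-predictor baseline beaten; attention ratio >= 2 (>= 8/10);
null differences non-significant (>= 8/10). p-value calibration under
simulated nulls is checked by Kolmogorov-Smirnov for the
continuous-statistic tests and by the alpha = 0.05 exceedance rate for the
discrete-statistic tests (Mann-Whitney, chi-square), where a KS test
against U(0,1) would be wrong by construction.

## Numerical conventions and degenerate inputs

Sample SD uses n−1 everywhere. Voxel indices are 0-based; world
coordinates come from the NIfTI affine; resampling uses the pull-back
convention (output voxel -> input coordinate). Min–max normalization of a
constant image, empty masks/brain masks, singular affines, constant ages
in the bias fit, zero-variance correlation inputs, single-class ROC
outcomes, zero contingency marginals and non-finite training losses all
raise typed errors rather than returning silently wrong numbers.

## Known limitations

- Phantom realism as above; effect sizes on phantoms are set by the
  injected offset and jitter, not fitted to the clinical tables beyond the
  control volumetry means.
- The CNN is a stand-in for the unpublished source architecture; its
  cross-validated MAE (~2-3 y on phantoms) is not comparable to the
  published 4.4 y on real multi-site MRI.
- Attention maps are evaluated against phantom tissue regions; no claim
  about human anatomical attention regions is made or checkable here.
- The screened-logistic step reproduces a common clinical modelling recipe
  whose statistical properties (post-selection inference) are themselves
  debatable; it is reproduced, not endorsed.
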
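# Methods

`adwave` implements a multi-slice texture pipeline for separating
Alzheimer's disease (AD) patients from healthy controls (HC) using 2-D
brain-slice images: per-slice dual-tree complex wavelet features, PCA
score-matrix reduction, a small feed-forward network trained by scaled
conjugate gradients, and repeated stratified 10-fold cross-validation.
This note records the model, the numerical choices, and what the
synthetic benchmark does and does not establish.

## The dual-tree complex wavelet transform

The plain decimated DWT is shift-variant (decimation aliases each
subband) and cannot separate +45 from -45 structure (its HH band mixes
both diagonals).  The dual-tree construction runs two real wavelet
filter banks ("trees" A and B) in parallel over rows and columns.  When
tree B's filters delay tree A's by half a sample at every scale, the
pair of real wavelets forms an approximate Hilbert pair, and the complex
combinations

    z1 = ((u_aa - u_bb) + i (u_ab + u_ba)) / s
    z2 = ((u_aa + u_bb) + i (u_ba - u_ab)) / s

of the four (row-tree, column-tree) subbands are approximately analytic:
each has a one-sided 2-D spectrum, which yields six orientation-selective
subbands per level (labelled +15, +45, +75, -15, -45, -75 degrees, where
the angle is the direction of intensity variation from the column axis)
whose **magnitudes** vary little under translations of the input.

### Filters

* **Level 1** - the published 10-tap Daubechies least-asymmetric
  (symlet) filter, deployed in its time-reversed (synthesis)
  orientation; tree B uses the same taps delayed by one sample, which
  realises the half-sample offset exactly at the first scale.  The
  delayed filter is stored padded to even length so its alternating-sign
  reverse remains a valid conjugate-quadrature partner.
* **Levels >= 2** - a 14-tap orthonormal Q-shift filter designed for
  this package; tree B is its time reverse, so the trees sit a
  quarter-sample before/after the filter midpoint.  The design
  parameterises the filter on the paraunitary lattice (orthonormality is
  then exact by construction, and constraining the lattice angle sum to
  pi/4 places an exact zero at Nyquist, making the DC gain exactly
  sqrt(2)).  The free angles minimise (i) the energy of the iterated
  dual-tree complex wavelets at levels 2-5 on the wrong side of the
  spectrum (non-analyticity), (ii) the spread of subsampled subband
  energy across sampling phases (the quantity that controls
  shift-variance of subband magnitudes; for a diagonally shifted
  impulse the level energy factors as q(2p + q) with p, q the
  periodised scaling/wavelet energies), and (iii) residual stop-band
  energy.  `scripts/design_qshift.py` reproduces the taps.

With these filters the measured behaviour (the properties the tests
assert) is: wrong-side spectral energy 0.1-0.4% at levels 2-5; level-3
subband energy of a centred impulse changes by about 0.8% under a
one-pixel diagonal shift (the plain DWT changes by 80-460% depending on
the probe); oriented gratings at the six nominal angles concentrate
74-99% of level-appropriate magnitude energy in the matching subband.

### Boundary rule, inversion and normalisation

Analysis uses circular (periodic) convolution with even-phase
decimation, `y[n] = sum_m f[m] x[(2n - m) mod N]`.  Periodic filtering
makes each single-tree stage an exactly invertible linear map; the
inverse solves the 2x2 polyphase system per frequency pair, which stays
exact even when a deep level's extent is shorter than the filter (the
wrapped filter bank is no longer orthonormal there, but it is still
invertible).  Round-trip error is at machine precision (~1e-15) for all
tested sizes and depths.  Reflect extension was considered and rejected:
with orthonormal, non-symmetric filters it breaks perfect
reconstruction at the boundaries.

Odd extents are edge-replicated to even before a level and cropped again
on inversion; the pre-pad shapes ride along in the pyramid.

Subbands are scaled by `1/(2*sqrt(2))` and the packed low-pass by `1/2`,
which makes total coefficient energy equal image energy exactly whenever
no wrap-around occurs - a convenient tight-frame convention for
energy-based diagnostics.

## Features

Per subject: the 32 contiguous centre slices (lower-median start on
ties) of the stack, each intensity-scaled to [0, 1] (integer images are
divided by their dtype maximum) and bilinearly resized to 256x256, then
decomposed to level 5.  The six level-5 complex subbands are 8x8 each;
flattening real parts then imaginary parts per subband gives
6 x 8 x 8 x 2 = 768 features per slice and 32 x 768 = 24,576 per
subject.  The real+imaginary definition is forced by the dimension
arithmetic (768 = 6 x 64 x 2); a magnitude-only variant (384 per slice)
is available behind `FeatureConfig(magnitude_only=True)` for
experimentation.  Only the deepest level is kept: coarse-scale
coefficients summarise morphology at the ventricular scale while
discarding fine-scale noise.

Demographic variables (age, gender, education, socioeconomic status,
MMSE) are carried through the cohort table but **not** appended to the
feature matrix by default - the 24,576-column arithmetic excludes them;
`with_demographics=True` appends them z-scored after the wavelet block.

## PCA reduction

Standard PCA on mean-centred columns via SVD of the data matrix (the
features x features covariance is never formed; with n subjects the rank
is at most n-1, so a 126-subject matrix yields a 126x125 score matrix).
No per-feature variance scaling: the wavelet features share one physical
scale.  Component signs follow a deterministic convention (largest-
magnitude entry positive).  The retained count k is the smallest whose
cumulative explained-variance fraction reaches the threshold (default
0.90); `pcs_override` forces a fixed k instead.  During cross-validation
the PCA is fit on the nine training folds only and applied to the held
-out fold (`pca_mode='per-fold'`, the default) - fitting on all subjects
first leaks information; `'global'` mode is provided to mimic protocols
that reduce before splitting.

## Classifier and training

A two-layer network N_I-N_H-1 (default hidden size 10): sigmoid hidden
units, linear output, biases in both layers (a `use_bias=False` switch
reproduces the bias-free textbook equations).  Targets are HC = 0,
AD = 1; the decision threshold is 0.5 and an output exactly at threshold
classifies as AD.  Weights initialise from a seeded symmetric uniform
distribution scaled by 1/sqrt(fan-in).

The fitness is a class-cost-weighted mean squared error,

    F(w) = sum_l c_{class(l)} (O_l - T_l)^2 / sum_l c_{class(l)},

with costs defaulting to inverse class frequency during CV (the cohort
is unbalanced, 28 AD vs 98 HC; without re-weighting the network can sit
at the majority-class solution).  With unit costs this is the plain MSE.

Training uses Moller's scaled conjugate gradient: conjugate directions,
a Hessian-vector product estimated by finite-differencing the gradient
along the search direction (sigma = 1e-5), and Levenberg-style scaling
lambda (initial 1e-6) grown when the quadratic model is poor
(comparison parameter < 0.25) and shrunk when it is good (> 0.75), with
a restart along the gradient every n-parameters accepted steps.  There
is no line search and no learning rate.  The loss trace over accepted
steps is non-increasing by construction; training stops at the
iteration cap, the MSE goal, a vanishing gradient, or trust-region
collapse.  The analytic backprop gradient is verified against central
finite differences to 1e-6 relative in the tests.

## Evaluation protocol

Stratified k-fold assignment (seeded shuffle; fold sizes and per-class
counts differ by at most one; if a class has fewer members than k the
assignment downgrades, with a warning, to per-class round-robin
dealing).  The 10-fold CV is repeated (default 50 runs; the heavy test
suite uses 10) with fresh folds per run.  Within a run the validation
predictions of the ten folds are **pooled** into one confusion matrix
before computing accuracy, sensitivity, specificity and precision -
with only 2-3 AD cases per fold, per-fold ratios are too granular.
Aggregates are mean and sample SD (ddof = 1) across runs; the SD across
all individual folds is also reported (`sd_folds`) since both
conventions exist in the literature.  Undefined ratios (zero
denominator) are reported as NaN with a warning, never silently zero.
A master seed spawns per-run seeds through `numpy.random.SeedSequence`,
so any single run is reproducible in isolation.

## Synthetic cohort

No imaging data ships with the package; a seeded generator emulates the
study's structure: 28 AD + 98 HC subjects, 32 axial slices of 176x208
8-bit PNG each, plus a demographics table whose distributions echo an
elderly cross-sectional cohort (AD: MMSE 21.67 +/- 3.75, CDR 1; HC:
MMSE 28.95 +/- 1.20, CDR 0).

Each subject is a smooth ellipsoidal "brain" whose cross-section waxes
and wanes through the stack, with a bright cortical rim and a dark
central ventricular region, individualised by random scale, axis ratio,
rotation and centre jitter, plus per-pixel Gaussian noise (SD 0.04 on
the unit intensity scale - visible speckle without drowning the
anatomy).  The AD signature is deliberately **morphological, not
photometric**: the ventricular region dilates (+30% linear per unit
effect size) and the rim thins (-35% at effect size 2), with per-subject
severity drawn around the nominal effect size; mean brightness is left
untouched so that a classifier must exploit texture/shape, which is
what the wavelet features encode.  At `effect_size = 0` the AD branch
multiplies out and the classes are exchangeable by construction.  The
default `effect_size = 1` produces a clearly visible but noisy
difference; 2.0 is strongly separable (the pipeline reaches >= 95%
cross-validated accuracy on 126 subjects), and the tests verify chance-
level accuracy at 0.

What passing on this benchmark shows: the transform delivers its stated
invariances, the feature/reduction/classifier chain is wired correctly,
information flows end to end, and the evaluation harness is unbiased
(null cohorts score at chance).  What it does not show: performance on
real MRI.  Real scans differ in registration error, bias fields,
scanner noise statistics, anatomical variability and disease
heterogeneity, none of which the phantom models; accuracy figures on
synthetic cohorts are not comparable to clinical results.

## Problem sizes in the shipped tests

The end-to-end tests use the full 126-subject, 32-slice geometry with
10 CV repeats (the package default outside tests remains 50), and the
exchangeability check uses 40 scaled-down Monte-Carlo replicates; both
choices keep the whole suite near five minutes on one CPU while leaving
every assertion at the study's stated dimensions.

## Known limitations

* Coefficient-level agreement with other DTCWT implementations is not
  expected: boundary rule (periodic vs reflect), filter sets and
  normalisation all differ.  The transform is validated against its
  mathematical properties and pywavelets (for the shared plain-DWT
  step) instead.
* Circular filtering assumes content near opposite borders may
  interact; for brain slices on a dark background this is immaterial.
* At depths where a level's extent falls below the filter length the
  transform wraps; inversion stays exact, but energy normalisation and
  shift-invariance degrade (256x256 at five levels does not wrap).
* The SCG classifier is a full-batch method; cohorts far larger than
  the study scale would want mini-batching or another optimiser.
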
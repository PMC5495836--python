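# Methods

`oiconnect` implements a resting-state functional-connectivity analysis for
multispectral intrinsic optical signal (OIS) imaging of the rodent cortex,
together with a ground-truth synthetic-data generator that emulates the kind
of acquisition the analysis targets: a two-group study (sham-injected
controls versus an inflammatory white-matter-injury model) in which
interhemispheric coupling is degraded in proportion to lesion severity.
This note records the models, the parameter choices, and the reasoning
behind the design decisions that were genuinely open.

## Spectral model

Reflectance movies are acquired at three wavelengths (525, 590, 630 nm) at a
5 Hz full-frame rate.  Differential optical density is defined per pixel and
wavelength as dOD = log10(I0 / I); the reference intensity I0 defaults to
the stack's stored reference when present and to the per-pixel temporal mean
otherwise (the two differ by a per-pixel constant, which the differential
analysis ignores).  The modified Beer-Lambert model

    dOD(lambda, t) = sum_i eps_i(lambda) * dC_i(t) * D(lambda),

with base-10 molar extinction coefficients eps_i and differential pathlength
factors D(lambda), is inverted per pixel and frame by the Moore-Penrose
pseudoinverse of the 3 x 2 system, i.e. ordinary least squares over
wavelengths.  Chromophore changes dC are reported in uM relative to
baseline; absolute concentrations are out of scope.  The extinction and
pathlength tables ship as editable configuration (representative values of
the right order of magnitude, not calibrated constants): D(lambda) defaults
to 0.15 / 0.25 / 0.45 cm for 525 / 590 / 630 nm, longer where absorption is
weak.  Wavelength-dependent sensor response and LED spectra are folded into
per-wavelength scalar correction weights multiplying the rows of the system
(identity by default); full spectral integration is a configuration hook.
Base-10 logarithms are used on both the forward and inverse side --
consistency between the two is the binding requirement and is enforced by a
round-trip test (noiseless forward rendering followed by unmixing recovers
the input to < 1e-8).

## Preprocessing

The per-subject chain is: unmixing -> nuisance regression -> spatial
smoothing -> temporal band-pass -> seed analysis.  Each stage can be
disabled in the run configuration.

* **Nuisance regression.**  An ordinary GLM per pixel with standardized
  regressors: heart rate, respiration signal, ECG, respiration rate
  (linearly interpolated to frame timestamps), and the mean signal of all
  cortex pixels of the chromophore being regressed, computed before
  smoothing.  Collinear columns are dropped with a warning; the residual
  C'(t) is carried forward and is exactly orthogonal to the design.
  Regressors are used raw (not band-passed); the subsequent band-pass of the
  residual movie removes out-of-band leftovers either way.
* **Smoothing.**  11 x 11 Gaussian kernel, sigma 3 px, applied per frame as
  normalized convolution over the cortex mask so that border pixels average
  only cortical neighbours.
* **Band-pass.**  Fourth-order Butterworth, 0.009-0.08 Hz, applied
  forward-backward (zero phase).  The two passes square the magnitude
  response, i.e. an eighth-order effective roll-off; this is the standard
  reading of a zero-phase fourth-order design and is documented rather than
  compensated.  Edges are handled by odd-reflection padding of three times
  the filter's impulse-response decay length (the time for |h| to fall
  below 10% of its peak, 283 samples at the default band and rate; the 1%
  decay time would exceed a 7-minute record and over-pad it).  Records
  shorter than three decay lengths raise an error.
* **Registration.**  Projective (homography) registration from >= 4 control
  point pairs via the normalized DLT, with the RMS reprojection error
  reported.  By default the transform is applied to the atlas geometry and
  derived maps rather than resampling every frame (equivalent for seed
  statistics and much cheaper); full-movie warping with bilinear
  interpolation and validity tracking is available.

Movies can be held either as full frames or in a packed cortex-pixels-only
layout ((T, n_pixels) plus the pixel coordinates).  Packing is the first
analysis step in spirit -- only cortical pixels enter any statistic -- and
the two layouts are checked equivalent in the test suite; the packed form
cuts the memory traffic of the per-pixel stages several-fold and is what the
pipeline uses internally.

## Connectivity statistics

Seed time courses are unweighted means over each seed's 17 member pixels
(the 17 in-mask pixels nearest the seed centre; ties broken by angle, then
row-major order).  Seed-to-seed connectivity is Pearson correlation with the
Fisher transform z = atanh(r) applied for group statistics; r is clamped to
+/-(1 - 1e-7) so self-correlations stay finite.  Seed-to-pixel maps are
per-pixel correlations with a seed trace, Fisher-transformed and normalized
to zero mean / unit SD over the valid cortex pixels.  Group maps are
per-pixel two-tailed one-sample t tests of the normalized maps against zero
(pixels with fewer than 3 valid subjects or zero variance are marked
invalid, not infinite).  Significance control: Benjamini-Hochberg FDR at
q = 0.05 over the in-mask p values (the cortex mask delimits the test
family), then removal of connected components strictly smaller than 5% of
the height-surviving pixel count (8-connectivity by default, 4 available).
The spatial extent of a network is the surviving-pixel count divided by the
cortex-mask pixel count; a group/contrast summary is the distribution of the
eight per-seed extents, with the mean as the headline number.

Group comparisons of extent (and of any scalar connectivity measure) use the
two-sample Mann-Whitney rank-sum test -- exact enumeration for tie-free
combined samples of up to 12, otherwise the normal approximation with tie
and continuity corrections -- plus Hedges' g with the small-sample
correction J = 1 - 3/(4N - 9).  Fisher's exact mid-P (half weight on the
observed table) is provided for 2 x 2 confound checks; the two-sided value
doubles the smaller one-sided mid-P, capped at 1.

## Machine learning

Feature vectors concatenate the upper triangles of the HbO2 and HbR
seed-to-seed Fisher-Z matrices in a canonical order (region M, C, S, R, then
hemisphere L, R): 28 pairs per contrast, 56 features for the default atlas.

* **Classification.**  Soft-margin SVM with RBF kernel
  exp(-||u - v||^2 / (2 sigma^2)).  C and sigma are selected by grid search
  (log2-spaced, C in 2^[-5..15], sigma in 2^[-3..9], step 2) on inner
  stratified validation folds of each training split only; features are
  z-scored with training-split statistics.  Evaluation is repeated
  stratified 10-fold cross-validation (10 repeats); the report carries the
  aggregate confusion matrix with Se/Sp/PPV/NPV/Acc and the per-repeat
  accuracies, since both aggregate and per-run readings are in use.
* **Regression.**  A two-layer feed-forward network (20 tanh hidden units,
  linear output) maps the 56 features to fractional lesion volume, trained
  by Levenberg-Marquardt steps on the Bayesian-regularized objective
  F = beta E_D + alpha E_W with MacKay evidence updates of (alpha, beta)
  from the Gauss-Newton Hessian approximation.  Stopping: MSE <= 1e-5 on
  scaled targets or 1000 epochs.  The effective-parameter count gamma is
  capped at 0.9 x the sample count: with ~10^3 weights and ~10 subjects the
  raw update can reach gamma = N, driving the noise-precision estimate beta
  to zero and collapsing the network to the prior (a constant); the cap
  keeps the data term alive and is the one numerically load-bearing guard
  in the trainer.  Inputs and targets are z-scored internally; weight
  initialization is deterministic under the RNG seed.  Held-out evaluation
  rotates test folds (leave-one-out up to 13 subjects) and pools the
  predictions before computing r and RMSEP.

## Histology

Ventricular volume from serial coronal sections: threshold, binarize, fill
holes, count pixels, convert via the scanning resolution (228 px/mm
default), multiply by section depth, and sum.  Thresholds come from a
three-class multi-Otsu split computed over the whole stack's gray levels
(background / tissue / bright ventricle) so that ventricle-free sections
yield empty masks instead of splitting tissue noise.  Two depth conventions
are provided: "thickness" (area x 50 um section thickness -- the literal
counting rule of the emulated protocol) and "spacing" (area x 300 um
section spacing -- the Cavalieri estimator that recovers the true volume of
a solid).  Fractional volume (ventricle / brain) cancels the convention
when applied consistently, which is why the fraction is the quantity used
downstream.

## Synthetic data generator

The generator provides every input the pipeline consumes, with known ground
truth.  What it emulates, and what it deliberately does not:

* **Geometry.**  An elliptical cortical window (about a third of the frame)
  on a 128 x 128 grid standing in for the (14.7 mm)^2 field of view at
  desk scale (the native 1024 x 1024 resolution is a configuration option).
  Eight seeds (motor, cingulate, somatosensory, retrosplenial x L/R) are
  placed at atlas-like positions; spatial parameters below are fixed in
  physical units and scaled to the grid.
* **Network signals.**  Each seed anchors a network patch with a Gaussian
  spatial profile (sigma = 4.5 px at 128 x 128, ~0.5 mm).  Latent network
  signals are zero-mean Gaussian processes strictly band-limited to
  0.009-0.08 Hz, synthesised by drawing the in-band Fourier coefficients
  directly (distributionally identical to zeroing the out-of-band
  coefficients of white noise) and mixed to a target correlation matrix
  through its symmetric PSD square root.  Default coupling: 0.7 homotopic,
  0.3 within-hemisphere, 0.15 other interhemispheric pairs (provably PSD).
  Every cortex pixel carries the profile-weighted sum of latents plus
  independent in-band noise (SD 0.5 of the unit latent), so cortex between
  patches expresses mostly noise, as in real maps.  Seed-trace correlations
  converge (in expectation across subjects) to the coupling matrix up to a
  noise-dilution factor 1/(1 + 0.5^2/17), about 1.5%.
* **Between-subject variability.**  Two jitters, chosen once for realism:
  the subject-level correlation matrix is the target plus symmetric noise
  of SD 0.12 (PSD-projected, unit diagonal restored), and patch centres are
  displaced by isotropic Gaussian jitter of SD 2 px (~0.23 mm), emulating
  biological variability and registration error.  Without them every pixel
  is a consistent network member across subjects and group t-maps saturate,
  which no real cohort shows.
* **Injury model.**  Injured subjects have all interhemispheric couplings
  multiplied by (1 - kappa * lesion_fraction), clipped to [0, 1], with
  kappa = 1 and lesion fractions drawn uniformly from [0.6, 1.0] by
  default.  Uniform attenuation is a convex combination of the original
  matrix with its block-diagonal part, so it can never destroy positive
  semidefiniteness; the PSD guard in the generator is defensive.
* **Chromophores and optics.**  HbO2 amplitude is 1 uM (the literature
  gives no resting-state amplitude scale; this is a free parameter).  HbR
  is -0.5 x the HbO2 network signal plus its own in-band noise, so both
  contrasts carry the same networks with opposite polarity.  The forward
  camera model applies the same corrected Beer-Lambert system as the
  inverse, 12-bit-scale reference intensity (3000 counts) and additive
  Gaussian read noise (SD 2 counts); negative intensities are redrawn, or
  clamped with a warning.  Shot (Poisson) noise, photon transport, and
  vascular compartments are not modelled.
* **Physiology.**  Quasi-periodic respiration (~1 Hz with slowly wandering
  rate), slowly drifting heart rate around 330 bpm, an ECG proxy at its
  aliased frequency (the cardiac cycle is above the 2.5 Hz frame Nyquist),
  and a respiration-rate trace.  Cohort movies are contaminated with a
  global slow drift (0.3 uM) plus a respiration leak (0.1 uM) so the GLM
  stage has real work to do; awake-motion artifacts are not simulated.
* **Histology phantom.**  An ellipsoidal brain (semi-axes 4.5 / 3.5 / 3 mm)
  with a concentric brighter ellipsoid whose analytic volume is exactly the
  requested lesion fraction, sectioned every 300 um.
* **Reproducibility.**  Per-subject RNG streams are derived by hashing
  (cohort seed, subject index) through `numpy.random.SeedSequence`;
  cohorts are bit-reproducible and subjects independent.

Because the generator shares no code with the analysis path beyond the
forward Beer-Lambert system (intentionally, so forward/inverse consistency
is a checked identity rather than an assumption), passing tests demonstrate
that the pipeline recovers the structure this generator encodes: localized
band-limited coupled networks, multiplicative interhemispheric attenuation,
and a monotone feature-to-lesion mapping.  They do not demonstrate
robustness to features the generator omits: vascular anatomy, spatially
correlated physiological noise, motion, optical vignetting, or
misregistration beyond the modelled jitter.

## Problem sizes in the validation suite

The group-contrast experiment runs at the emulated acquisition scale -- 13
subjects (8 control, 5 injured), 128 x 128 frames, 2100 frames at 5 Hz --
for 20 seeded replicates, with the optics round-trip (an exact identity on
noiseless data, validated separately) and the nuisance stage (no
contamination is simulated in that experiment) skipped.  Coupling-
convergence checks average 20-50 replicates at the same frame count.
Machine-learning recovery uses 20-subject feature-level cohorts in which
lesion size drives the interhemispheric features linearly with 10% feature
noise.  The acceptance script runs one full cohort, all stages enabled,
at the same scale.

## Known limitations

* The pseudoinverse unmixing ignores scattering changes and wavelength
  cross-talk beyond the scalar correction weights.
* Global-signal regression can induce anticorrelations; the package applies
  it because the emulated protocol does, and exposes the regressor list so
  it can be dropped.
* Spatial-extent magnitudes depend strongly on the between-subject
  variability of the cohort; on synthetic cohorts the control-group extents
  are higher than in typical real data, and only the direction and
  significance of the group difference, not the absolute extents, should be
  compared across generators.
* The exact-enumeration threshold of the rank-sum test (combined n <= 12)
  matches the emulated study's group sizes; larger samples use the
  tie-corrected normal approximation.
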
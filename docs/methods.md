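# Methods

## The measurement model

iBSA treats the body surface as the iso-surface of a binary body mask
extracted from a calibrated CT volume. The pipeline is deterministic and has
three stages:

1. **Segmentation.** A voxel is body iff HU ≥ `hu_threshold` (default
   −400 HU: midway between soft tissue at ~40 HU and air at −1000 HU, with
   hundreds of HU of margin against noise on either side). The raw mask is
   then closed with a spacing-aware Euclidean ball
   (`closing_radius_mm = 3`, about one voxel at typical 3 mm slice spacing —
   bridges skin-surface noise without fusing limbs across real gaps), the
   largest 26-connected component is kept (removing the scanner couch and
   clothing), and all background not reachable from the volume border is
   filled — in 3-D and again per axial slice, so lungs and bowel gas that
   communicate with outside air through open airways still become interior.
   The result is the *outer skin surface* definition of the body.
   Connectivity is the standard dual pair: 26-neighbour foreground,
   6-neighbour background. The closing is implemented with two exact
   Euclidean distance transforms (`sampling=spacing`), which is equivalent
   to structuring-element morphology but exact for anisotropic voxels and
   fast at sub-millimetre spacings; the mask is padded before the transform
   pair because the EDT is biased at the array border. A segmentation whose
   largest component is below `min_component_volume_ml` (default 500 ml —
   no plausible human body is smaller) raises "no body found"; bench-top
   phantom work lowers this floor explicitly.

2. **Meshing.** The binary mask is converted to a float field, smoothed with
   a Gaussian that is isotropic in physical space (default sigma = 1 voxel
   on the finest axis, rescaled per axis by the spacing), padded by one
   background layer so the surface closes, and triangulated by marching
   cubes at iso-level 0.5 with the physical spacing applied. Marching cubes
   on a *raw* binary mask overestimates the area of smooth bodies by a
   roughly scale-free staircase (metrication) bias; the pre-smoothing
   removes it, and `smoothing_sigma_vox=0` reproduces the raw behaviour for
   study. No decimation or Taubin smoothing is applied — both silently
   change area. Degenerate zero-area faces are dropped.

3. **Area.** iBSA is the sum over triangles of ½‖(v1−v0)×(v2−v0)‖, reported
   in cm² and m². A per-vertex accumulation is not a well-defined estimator;
   face summation is the standard discrete surface integral. The z-extent is
   (n_slices − 1)·z_spacing (slice centres, matching the marching-cubes
   support), and the optional per-length normalisation `area_cm2/(z/10)`
   makes partial (thoracic/abdominal) scans comparable longitudinally.

Because the smoothing scale is specified in voxels, it tracks the grid:
refining the grid while holding sigma at 1 voxel does not drive the error
to zero (the residual staircase term is scale-free), but the error stays
within a few tenths of a percent across 2/1/0.5 mm; holding the *physical*
sigma fixed instead makes the error essentially resolution-independent at
about −0.3% for a 50 mm sphere. Measured accuracy at defaults, 1 mm
isotropic: sphere +0.13%, cube +0.52%, cylinder −0.35%, ellipsoid +0.12%,
composite body −0.36%.

## Anthropometric formulas

Public interface is always (metres, kilograms); each formula's native units
are internal: Du Bois as printed takes metres (0.20247·100^0.725 recovers
the classical 0.007184 cm coefficient), Mosteller/Haycock/Gehan-George take
centimetres, Boyd grams. Values are verified against independent 30-digit
evaluations and never rounded in computation. The error-propagation relation
is the exact logarithmic derivative of Du Bois, so a 2% weight loss at 50 kg
gives −0.85% BSA — formula-based BSA is deliberately insensitive to
morphological change, which is the clinical argument for measuring instead.

## Agreement statistics

Proportional Bland-Altman differences use the pair mean as denominator (the
standard choice for ratio-scale data; switchable to absolute differences).
SD uses n−1 (the motivating use case has n = 11–26). Limits of agreement are
bias ± 1.96·SD by construction. Bootstrap CIs are percentile intervals over
whole-pair resamples (default 2000, seeded). Variances are compared with a
two-sided F-test (larger variance in the numerator) and means with Welch's
t-test (no equal-variance assumption). When both replicates of a test-retest
pair carry independent multiplicative noise of SD s\*, the Bland-Altman SD
estimates s\*·√2 — the √2 is a property of differencing two noisy
measurements, not a bias.

## Dose-banding Monte Carlo

True BSA is sampled uniformly on [1.2, 2.5] m² (N = 10⁶ by default) and
perturbed multiplicatively, `sBSA = BSA·(1+ε)`, `ε ~ N(0, σ)` with σ the
inter-method SD expressed as a fraction (default 0.0411, the image-vs-Du Bois
value; the inter-method *bias* is not injected — the error model is zero
mean by construction). Bands are half-open [low, high) with the last band
closed; out-of-range values clamp to the outer bands so every sample maps to
a band. The reclassification rate is the fraction whose band changes, with
the MC standard error √(p(1−p)/N) ≈ 0.05 pp at N = 10⁶.

The bundled capecitabine table is a reconstruction: published dose-banding
protocols step doses by the 150 mg tablet increment, and the table's band
width is the one free parameter. Eight contiguous equal-width bands over
[1.2, 2.5] m² (width 0.1625 m², doses 1500–2550 mg) reproduce the reference
reclassification rate (≈32.0% at σ = 4.11%, vs 32.5% reported); seven bands
would give 27.7% and nine 36.0%. No equal-width table simultaneously
reproduces the reported two-or-more-band shift fraction (1.1%); with eight
bands it is ≈0.6% and is reported, not gated. The 150 mg step is 14.3% of
the 1050 mg dose range, consistent with the observation that one band step
exceeds 10% of the range. Any CSV with header `bsa_low,bsa_high,dose_mg`
can be substituted.

`analytic_reclassification` is an independent oracle: for BSA = b in band
[lo, hi), the crossing probability Φ((lo−b)/σb) + Φ̄((hi−b)/σb) (edge bands
lose the clamped side) is integrated over the uniform population by adaptive
quadrature. MC and oracle agree within 3 standard errors across random
tables and σ values.

## The phantom factory

Phantoms are voxelized by centre-sampling (a voxel is tissue iff its centre
is inside the solid) with no anti-aliasing, so any discrepancy between
measured and analytic area is attributable to the measurement pipeline, not
the generator. Analytic truths: 4πr², 6a², 2πr(r+h), Thomsen's ellipsoid
approximation (p = 1.6075, max error ≈1.06% — hence the 3% ellipsoid
tolerance where other solids get 2%). The composite body keeps every
junction coaxial with the z-axis (spheroid torso, neck cylinder into a head
sphere, one leg cylinder below), so each junction patch is a spherical cap
(2πRh, closed form) or a spheroid zone evaluated by adaptive quadrature of
the exact surface-of-revolution integrand — machine-precision truth without
Monte Carlo. Test-retest "acquisitions" are rigid transforms (physical-space
rotation about z + sub-voxel shifts, trilinear resampling) with fresh seeded
noise; a transform that pushes tissue onto the volume border raises "out of
field". Synthetic cohorts draw correlated truncated-normal height/weight
pairs (defaults H ~ N(1.70, 0.09²) m on [1.51, 1.92], W ~ N(75, 15²) kg on
[42, 115], ρ = 0.6 — an adult oncology population).

What the synthetic data do *not* emulate: scanner physics (beam hardening,
kernel-dependent edge response), anatomy (skin folds, body-contact areas
between limbs — a known source of underestimation in real scans), couch
texture, or truncated fields of view. Passing phantoms therefore validates
the geometry and statistics of the pipeline, not its behaviour on every
clinical artefact.

## Problem sizes and numerical choices

Validation runs use 50 mm-scale solids at 0.5–2 mm spacing (grids up to
~10⁷ voxels), 14-replicate accuracy protocols, 200-pair precision
experiments, and 4×10⁵–10⁶-sample simulations — large enough that every
tolerance is dominated by method error, not sample noise. All randomness
flows through seeded `numpy` generators; every CLI report embeds the tool
version, configuration fingerprint, seed and input checksum. Degenerate
inputs fail loudly with typed exceptions (empty masks, non-contiguous band
tables, implausible anthropometrics, zero-extent scans).

## Known limitations

* Real CT of real patients adds error sources the phantoms exclude (contact
  areas, truncation, metal artefacts); the accuracy numbers here bound the
  algorithmic error only.
* The capecitabine band table is a reconstruction; the reclassification
  rate depends on band width, and results should be re-run with the actual
  institutional table for clinical use.
* A single voxel is below the resolution limit: marching cubes returns the
  octahedron through the voxel's face centres (area exactly √3 mm² for a
  1 mm voxel), not the voxel cube.
* No extrapolation from partial-scan iBSA to whole-body BSA; the per-length
  normalisation is the supported partial-scan output.
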
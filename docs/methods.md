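# Methods

This note records the statistical model behind `hipshape`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## Shape space and alignment

A configuration is an ordered set of *k* 2D landmarks in pixels. Shape is
what remains after removing the similarity transform: translation, size
and rotation (4 degrees of freedom, so at most 2k − 4 shape dimensions).

* **Size measure.** Centroid size — the root summed squared distance of
  the landmarks from their centroid — is the geometric-morphometrics
  standard and is used throughout. Every aligned shape has unit centroid
  size ("full" Procrustes: size is removed before modelling, not
  retained as a partial-Procrustes scale).
* **Rotation.** The orthogonal Procrustes solution via SVD of the
  cross-covariance, with the smallest singular value sign-corrected so
  the determinant is +1. Reflections are never introduced by the
  aligner; contralateral (left/right) hips must be mirrored explicitly
  by the caller (`mirror_x` / `--mirror-x`), since side-handling is a
  study-design decision, not an alignment one.
* **GPA.** Initialise the mean as the first normalized configuration;
  rotate all configurations onto it; re-average and renormalize; repeat
  until the mean moves less than `tol = 1e-10` (Euclidean) or
  `max_iter = 100`. Non-convergence warns and flags the result rather
  than raising, because a almost-converged mean is still usable and the
  caller should decide. On realistic inputs convergence takes < 10
  iterations. The per-iteration Procrustes sum of squares is recorded
  (`MeanShape.ss_history`) and is non-increasing.
* **Degenerate inputs.** Zero centroid size (all points coincident) and
  rank-zero cross-covariances raise immediately with a description; they
  indicate corrupt input, not a recoverable state.
* The detached acetabular-eyebrow points are part of the same rigid
  configuration as the femur points and participate identically in
  alignment; the markup treats the joint as one object.

## The shape model

PCA is applied to the covariance matrix (divisor n − 1) of the aligned,
flattened coordinate vectors — covariance, not correlation, because all
coordinates share units and down-weighting low-variance landmarks is not
wanted in a point-distribution model.

* **Numerically-null modes.** After full GPA the four similarity
  degrees of freedom survive only as near-zero curvature directions.
  `build_ssm` therefore drops modes with eigenvalue below `eig_rtol`
  (default 1e-9) times the leading eigenvalue. The threshold is a
  parameter: `eig_rtol=0` keeps every positive mode, which is the
  setting under which the exact reconstruction-completeness identity
  (training shape = mean + Σ score·SD·mode) holds to machine precision.
* **Standardization.** The stored per-mode `score_sds` are the sample
  SDs (divisor n − 1) of the raw training projections. In exact
  arithmetic these equal √eigenvalue (asserted in tests at rtol 1e-6);
  computing them from the projections makes the "training scores have
  SD exactly 1" contract hold to full floating-point precision even for
  small-eigenvalue modes, where √eigenvalue alone would be limited by
  the accuracy of the eigensolver.
* **Sign convention.** Each eigenvector's largest-magnitude entry is
  made positive, so saved models and scores are bit-reproducible across
  runs and platforms. Which anatomical direction "+2 SD" depicts is
  therefore a convention, not an estimate.
* **Truncation.** By default the pipeline retains 10 modes, the usual
  choice for hip DXA models: beyond that point individual modes
  typically carry under ~1.5% of variance and behave like marking
  noise. Variance fractions are *not* renormalized on truncation, so
  cumulative variance explained keeps its meaning.

## Reference-model projection

Projection of a new configuration onto a frozen model: normalize
(centre, unit centroid size), rotate onto the model mean by optimal
rotation, subtract the mean, take inner products with the saved
eigenvectors, divide by the saved training SDs. The model is never
updated — no re-running of GPA on the joint set — so reference scores
mean the same thing for every population scored against the model.
Unit-size normalization is assumed on both sides; no rescaling by the
reference population's size distribution is attempted.

One geometric caveat: aligned shapes live on the unit sphere, and a
linear reconstruction `mean + k·SD·mode` leaves it slightly. Projecting
such a reconstruction back recovers its scores only up to that curvature
(relative error ~k²·λ₁), which is why the projection round-trip test
uses a loose tolerance while the linear scoring round trip is exact.

## Reliability

* **Point-to-point repeatability** is computed on raw pixel coordinates,
  not aligned ones, because placement error is judged in pixels against
  the image (nominally 250 × 180 px); a per-image median distance of
  ≤ 3 px is the conventional "accurate" cut-off.
* **ICC.** The variant is fixed to two-way random effects, absolute
  agreement, single measures — ICC(2,1) — the conservative choice for
  test–retest of continuous scores, computed from the standard two-way
  ANOVA mean squares. A consistency variant (ICC(3,1)) is available as
  `kind="consistency"` for sensitivity analysis. Zero between-subject
  variance warns and can yield non-positive or undefined (NaN) values,
  as it should. Both marking sessions are scored against one fixed
  model, so per-mode ICCs isolate marking noise from model instability.
* Modes with ICC below 0.70 are flagged; in simulations with a few
  strong planted modes, exactly the higher noise-dominated modes fall
  below the flag — the pattern seen in real inter-observer studies.

## Effective number of independent modes

`nyholt_veff` eigen-decomposes the score correlation matrix and applies
V_eff = 1 + (M − 1)(1 − Var(λ)/M) with the *sample* eigenvalue variance
(divisor M − 1); that divisor matches the published matSpD behaviour and
is load-bearing for reproducing reported values at one decimal. The
Li–Ji M_eff (Σ over eigenvalues of the integer part indicator plus the
fractional part) is computed alongside for sensitivity; eigenvalues are
rounded to 12 decimals first because the Li–Ji function is discontinuous
at integers and an exact-integer eigenvalue must not pick up a spurious
unit from floating-point error. Correlations are used as signed values;
no absolute-valuing. Full precision is kept internally; reporting rounds
to one decimal.

## Synthetic data: what it emulates, and what it does not

The generator draws populations from exactly the model a
point-distribution analysis assumes:

    x_i = T_i( base + Σ_m s_im · σ_m · e_m ) + ε_i

* **Base shape**: a parametric 58-point schematic of a proximal femur
  (circular-arc femoral head, neck, trochanter bumps, shaft segments,
  detached two-segment acetabular eyebrow) in a nominal 250 × 180 px
  frame. It is constructed from arcs and line segments, not traced from
  any image. The standard markup labels 13 key anatomical points and
  excludes 5 ({0, 1, 44, 45, 57}), leaving the 53-point model.
* **True modes**: random low-frequency Fourier displacement fields
  (coefficient SD ∝ 1/harmonic, 5 harmonics) projected off the
  similarity-transform tangent space and orthonormalized — planted
  variation must be genuine shape variation, and smooth, as real
  principal modes of outlines are. Default mode SDs in the CLI decay
  geometrically from 12 px.
* **Nuisance**: per-image rotation uniform in ±15°, isotropic scale
  0.9–1.1, translation ±20 px — plausible DXA positioning variation; an
  optional anisotropic x-scale emulates scanner pixel-spacing (aspect
  ratio) differences qualitatively.
* **Marking noise**: i.i.d. Gaussian per coordinate, default 1 px. For
  reference, two sessions with per-coordinate noise σ give Rayleigh
  point-to-point distances with mean σ√π, so ~1.2 px repeatability
  corresponds to σ ≈ 0.69 px.
* Everything is reproducible from the integer seed
  (`numpy.random.default_rng`).

What passing tests on this generator demonstrate: the pipeline removes
similarity nuisance exactly, recovers a planted 3-mode subspace to
within 5° (largest principal angle) and planted scores at r > 0.95 with
n = 500 images and 0.1 px noise, standardizes own-reference scores
exactly, and reproduces published effective-mode counts on published
correlation matrices. What they do not demonstrate: behaviour under real
marking pathologies (point swaps, outline ambiguity at the acetabular
overhang), non-Gaussian population structure, scanner-specific aspect
ratio effects (only qualitatively emulated), or any anatomical claim
about which features each mode describes.

## Problem sizes used in the shipped analyses

The acceptance script measures own-reference standardization on a
500-image population (and total variance capture on a 200-image one),
58-point template, 3 planted modes with SDs (10, 5, 2) px and 1 px
marking noise — large enough that GPA, model build and scoring exercise
the full pipeline while the whole script completes in about a second.
Test-suite simulations use 80–900 images depending on the Monte-Carlo
tolerance required.

## Known limitations

* 2D landmarks only; no 3D, no sliding semi-landmarks, no thin-plate
  spline warping.
* Full Procrustes only (no partial-Procrustes size retention option).
* The projection assumes the reference and target templates are the
  same 53-point roster; no landmark subsetting or correspondence
  re-estimation.
* The exclusion ledger is bookkeeping, not a data-quality classifier:
  stage counts are caller-supplied.
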
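# Methods

This note documents the models, conventions and numerical choices behind
`microtract`, and what its synthetic experiments do and do not show.

## Signal model and conventions

The Standard Model kernel for a fiber segment at ξ = cos(angle to the
gradient) is

    K(b, ξ) = f·exp(−b·D_c·ξ²) + (1−f)·exp(−b·De⊥ − b·(De∥−De⊥)·ξ²),

with f the intracellular (stick) signal fraction, D_c the stick axial
diffusivity, De∥/De⊥ the extracellular axial/radial diffusivities.  Fiber
orientations follow a Watson distribution with concentration κ about the
axis μ̂.  Internal units are b in ms/µm² and diffusivities in µm²/ms (so
b = 6000 s/mm² reads 6.0); O(1) numbers keep the nonlinear fit well
conditioned.  Diffusivities are boxed at 3.5 µm²/ms, the free-water value
at body temperature.

All Legendre projections use the half-interval convention on ξ ∈ [0, 1]
(antipodal symmetry folded in):

    K_l(b) = ∫₀¹ K(b, ξ) P_l(ξ) dξ,
    p_l(κ) = E[P_l(ξ)] under the density ∝ exp(κξ²) on [0, 1],

so p_0 = 1, the shell's spherical mean equals K_0·p_0, and the per-shell
rotational invariants factorize as S_l = K_l·p_l.  The forward signal is

    S(b, ĝ) = s0 Σ_{l even} (2l+1) K_l(b) p_l(κ) P_l(ĝ·μ̂).

With this normalization K_0 for a pure stick is √(π/(4bD))·erf(√(bD)),
≈ 0.2558 at bD = 12 — it equals the spherical mean directly; no extra
factor of ½ applies on the half interval.

**Numerical choices.**  Kernel projections use 64-node Gauss–Legendre
quadrature (the integrands are entire, so convergence is exponential).
Forward synthesis truncates the Legendre series at l_max = 32: at b = 6
the stick kernel is sharp (bD ≈ 13) and the series reaches ~1e-10 pointwise
error only around l = 32, whereas l_max = 8 leaves errors of order 1e-2
along the fiber where the signal itself is ~1e-5.  Cohort simulation uses
l_max = 20 (error ~1e-7, three orders below the noise floor) for speed.
The κ ↔ p₂ inversion is a Brent root solve of the monotone Watson moment,
capped at κ = 1e4.

## Metric estimators

- **Spherical harmonics.** Real, even-order, orthonormal basis;
  least-squares per shell with l_max 4 on 30-direction shells and 6 on
  60-direction shells (well-posed designs).  Spherical "variance" metrics
  are reported on the standard-deviation scale, and all moments are
  normalized by the mean b=0 signal — two conventions fixed here because
  the field uses both.
- **DTI / DKI.** Weighted linear least squares on ln S (weights = squared
  predicted signals from an OLS pre-pass).  DTI uses b ≤ 1.2, DKI b ≤ 2.4
  ms/µm², the standard validity regimes.  The DKI design estimates
  D̄²·W jointly with the tensor; W is recovered after the fit.  Mean
  kurtosis averages the apparent kurtosis over 10 000 deterministic
  (Fibonacci-sphere) directions; axial/radial kurtosis use the principal
  eigenvector and its perpendicular plane.  Negative tensor eigenvalues are
  clipped at zero and the voxel flagged.  Note that kurtosis estimated by
  the b ≤ 2.4 design is the *apparent* (finite-b) value: for a 50/50
  two-Gaussian mixture with D = 1, 2 the b→0 cumulant limit is exactly 1/3,
  and the estimator reproduces it on small-b shells (b ≤ 0.2) to three
  decimals, while the default shells give ~0.27 from truncation of higher
  cumulants — a property of the regime, not a defect of the solver.

## Standard Model fit

Fitting minimizes the misfit of the l ∈ {0, 2} invariants over all weighted
shells (10 data points for the five-shell protocol) in
θ = (f, D_c, De∥, De⊥, p₂), with boxes f ∈ [0.05, 0.95], diffusivities
∈ [0, 3.5], p₂ ∈ [0, 1].  The objective is multimodal (the well-known
branch degeneracy that swaps intra- and extracellular diffusivities), so
the solver multi-starts from a seeded Latin hypercube (default 32 starts;
the Monte-Carlo experiments use 16, which reaches the same global basin on
this protocol).  When two distinct minima lie within 1e-3 in residual the
fit is flagged ambiguous and the branch with D_c ≥ De∥ is preferred — a
deterministic, documented tie-break.  Fits with f ≥ 0.9 are flagged: with
under ~10% extracellular signal the De parameters are not identifiable.

**Magnitude-bias handling.**  Magnitude MRI noise is Rician; at high b the
noise floor inflates the l = 0 invariant and, through the joint fit,
biases κ strongly downward (its inversion from p₂ steepens for aligned
fibers).  `magnitude_bias_correct` applies the moment-matching correction
Ŝ = √(max(M² − 2σ², 0)) per measurement before the spherical-harmonic
fits; σ is known in simulation (and estimable from b=0 repeats in
practice).  In acquired-data pipelines this role is played by the
denoising/preprocessing chain, which is out of scope here.

**Segment averaging.**  Invariants are averaged arithmetically per shell
across the voxels of a tract segment before fitting.  Because invariants
are rotation-invariant, curvature does not bias the average, and the
standard error shrinks as ~1/√N — this is what makes voxel-level-degenerate
BSM fitting reliable at segment level.

## Synthetic study generator

`CohortSpec` defaults encode the study conditions: 92 TD subjects aged
8–18, an age/sex-matched subset of 22 (nearest-age same-sex matching
against the case group), 9 deletion-syndrome (DEL) subjects aged
11.8–15.2 (7F/2M), SNR 50, Rician noise.  Baseline tissue parameters
(f = 0.6, D_c = 2.2, De∥ = 2.0, De⊥ = 0.7, κ = 16) are conventions for
healthy deep white matter.  Effects are multiplicative: age trends linear
in age anchored at the youngest TD age (default f +9% over the 10-year
range, De⊥ −5%, κ −2%), DEL-vs-same-age-TD shifts of f +5%, De⊥ −4.6%,
De∥ −3.6%, κ −1.6%.  Two further variance components make the cohort
realistic rather than degenerate: a seeded smooth ±3% along-tract profile
(identical across subjects) and a 5% CV between-subject multiplicative
variability per parameter.  The latter matters structurally: without it
all eleven metrics are driven by age alone and their correlation matrix is
numerically singular; real developmental cohorts leave most metric
variance unexplained by age (reported age models have r² ≤ 0.55).

Bundle phantoms are jittered copies of parametric centerlines (straight,
arc, helix) — Gaussian transverse jitter for realistic fuzzy bundles, or
uniform-disk offsets when a hard cylindrical support of known volume is
needed.  Voxelization is corner-anchored: a point at x contributes to
voxel floor(x/voxel_size).  Each voxel takes the Standard Model signal of
its nearest of 20 equidistant centerline nodes, with the local fiber axis
set to the mean streamline tangent in that voxel.

**What the generator does not emulate:** crossing fibers, partial-volume
CSF/GM, exchange, T2 compartment differences, axon-diameter (finite-radius)
effects, spatial noise correlations, or motion/distortion artifacts.
Passing recovery tests therefore demonstrate estimator correctness under
the model's own assumptions, not robustness to these confounds.

## Tractometry

Streamlines are resampled to equidistant arc-length points and flipped for
consistent orientation (start-point clustering against the first
streamline).  The centerline is a cubic smoothing spline through the
pointwise mean curve, re-parametrized by arc length, with 20 equidistant
nodes.  Voxels map to their nearest node (ties to the lower index);
profiles align across subjects by a translation+rescale of the node axis
maximizing correlation with the cohort mean (coarse grid, then bounded
1-D refinement).  A reproducible surrogate replaces manual centerline QC:
bundles whose arc-length/endpoint-chord ratio is high (self-folding
centerlines, e.g. a helix) are flagged rather than visually excluded.
Tract volume counts voxels visited by at least one streamline — each
streamline at most once per voxel, so the count is independent of point
density — normalized by brain volume.  On cylinder phantoms with disk
support the volume error is dominated by surface voxels, ~(2h/r)·c with
voxel size h and radius r; the shipped phantom (r = 5, h = 0.5) lands
under 10%, consistent with a 10–20% minimal detectable volume effect.

## BPC and cohort statistics

PCA runs on the correlation matrix of the 11-metric panel of the TD
cohort; Horn's parallel analysis (95th percentile of eigenvalues from 200
seeded normal datasets, consecutive-from-top rule) selects the retained
count; oblimin (γ = 0) rotation — chosen as the most common oblique
default — gives pattern loadings, component correlations, and
regression-method (Thurstone) scores; signs are fixed so each component's
largest-|loading| entry is positive.  Variance explained is reported both
pre-rotation (eigenvalue fractions) and post-rotation (structure-loading
sums), since the two conventions differ once components correlate.

The synthetic loading generator draws metric panels from Σ = ΛΦΛᵀ + Ψ with
the published 11×3 total-white-matter pattern Λ, unique variances
1 − communality (floored at 0.05; oblique pattern loadings can push
nominal communalities past 1), normalized to unit diagonal.  The default
component-correlation matrix uses moderate (0.2–0.3) correlations with
signs matching the components' reported developmental directions
(intracellular signal and tissue complexity rise with age, extracellular
mobility falls).

Age models: OLS of metric on age, compared with the quadratic model by
AICc = AIC + 2k(k+1)/(n−k−1) (k = number of regression coefficients);
predictions at the age-range endpoints give the percent difference with
the younger prediction as denominator.  Group contrasts: Student
pooled-variance t (df = n₁+n₂−2, matching the reporting convention of
small-sample neuroimaging studies; Welch is available behind a flag) with
Hedge's g = (1 − 3/(4N−9))·d and the control-group mean as the
percent-difference denominator.  Benjamini–Hochberg step-up controls FDR,
one family per analysis (all metric age tests; all metric group tests), so
significance thresholds are data-dependent rather than hard-coded.

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` run entirely synthetic
experiments sized for a single CPU: 200 parallel-analysis replicates;
200–500 Monte-Carlo replicates of 50-voxel segments at SNR 50 for Standard
Model precision; 100 end-to-end cohort replicates each for null-FDR
calibration and effect-direction agreement, using a reduced bundle
(~15 voxels per subject) whose voxel count affects only per-subject noise
after segment averaging, not the statistical calibration being tested.

## Known limitations

- Apparent (finite-b) kurtosis bias at the default DKI shells (see above).
- κ is the least precise Standard Model parameter for well-aligned fibers;
  its median error at SNR 50 with 50-voxel averaging is ~8%, several times
  that of De⊥.
- The profile-alignment map is shared across metrics only if the caller
  applies it so; `align_profiles` aligns one quantity at a time.
- `fit_standard_model` estimates all five parameters; constrained variants
  (e.g. fixed D_c) are expressible through the bounds argument but are not
  a tuned code path.
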
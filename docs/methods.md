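# Methods

## Model

For a cohort of N registered volumes on a common P₁×P₂×P₃ grid, the
conditional τ-quantile of age given the image is modelled as

    Q_τ(Y | X) = α_τ + ∫ X(t) β_τ(t) dt,      τ ∈ (0, 1),

with the image X and the coefficient function β_τ expanded in the same
truncated Karhunen–Loève basis.  Orthonormality of the eigenfunctions turns
the functional model into an ordinary linear quantile regression on the
first M functional principal-component scores; fitting it at τ = δ/2, 0.5
and 1−δ/2 yields a median brain age and a nominal (1−δ) prediction interval
per subject.  Quantile regression makes no distributional assumption on the
response, so the intervals remain valid under heteroskedastic or skewed
residuals where least-squares intervals fail; coverage error decays at
O(n^{-1/2}) in the training size.

### Pipeline stages

**Masking.**  A raw binary brain mask is convolved with an isotropic
Gaussian kernel (default SD 2 voxels, reflective boundaries) and
thresholded at 0.5, regularising ragged boundaries.  All computation is
restricted to the n_active masked voxels, vectorised in a fixed raster
order (first axis fastest).

**Basis expansion.**  The design is a tensor product of univariate
quadratic B-splines with equidistant distinct knots spanning each axis
(clamped boundary knots; the final inter-knot interval is clipped to end on
the boundary).  With l_j distinct knots and degree r, the univariate count
is Q_j = l_j + r − 1; this is the only reading of that count under which a
clamped quadratic basis satisfies the unit-sum property on the whole axis,
and it is verified in the tests (partition of unity to 1e−10).  Rows of the
tensor design are restricted to masked voxels and columns to basis
functions with support in the mask.  Each image is projected by ordinary
least squares through one shared factorisation of the normal-equations
matrix (Cholesky; an eigendecomposition-based minimum-norm solve with a
warning when the masked design is rank-deficient, e.g. at one-voxel knot
spacing).  Per-image R² is reported about the image's masked-voxel mean;
constant images get R² = 1 by convention.  Projections are mutually
independent across images, so projecting once up front leaks nothing across
cross-validation folds — only the centring mean and everything after it are
fold-specific.

**Functional PCA.**  The basis Gram matrix W is the unit-weight cross
product over masked voxels (the voxel-volume factor is deliberately
dropped: any positive rescaling of W rescales eigenvalues and scores but
leaves all quantile predictions invariant, which is tested end to end).
The eigenproblem (N−1)⁻¹CᵀCW ξ = λξ with ξᵀWξ = I is solved through
W = LLᵀ: the SVD of A = (N−1)^{-1/2} C L gives λ as squared singular values
and ξ by a triangular solve.  If the plain Cholesky factorisation fails
numerically (near-singular W, as happens at dense knot spacings), a pivoted
Cholesky with rank truncation is used: the permuted triangular solve sets
the coefficients beyond the pivoted rank to zero, which is this package's
choice for the under-determined directions and is flagged in logs.
Singular values below 1e−10 of the largest are discarded.  Eigenfunction
signs are fixed deterministically (largest-magnitude coefficient positive)
— a substitute for sign choices that would otherwise be arbitrary.  The
truncation M is the smallest number of components reaching the
proportion-of-variance threshold (default 0.8; 0.65/0.95 supported for
sensitivity analysis).

**Quantile regression.**  The penalised check-loss problem

    min_{α,b}  Σ_i ρ_τ(y_i − α − ν_i·b) + h Σ_m |b_m|

is solved exactly as a linear program (HiGHS, split-variable formulation);
the required 1e−6 relative objective accuracy is comfortably exceeded, and
the tests pin the h=0 objective against an independently coded LP
formulation to 1e−8 and against an interior-point quantile-regression
implementation.  Score columns are standardised to unit sample variance
before penalisation — without this the first component, whose variance λ₁
can dominate the rest by orders of magnitude, would monopolise the ℓ1
budget — and reported slopes are always back-transformed to the original
score scale.  The intercept and any appended scalar covariates are never
penalised.  The penalty grid is geometric, 25 points from h_max down to
h_max·1e−3, where h_max — the smallest penalty making the intercept-only
model optimal — is computed exactly from the subgradient conditions at the
empirical τ-quantile: a common selection ψ_i must make the intercept
gradient vanish while bounding every slope gradient by h, and the minimal
such h is itself a tiny linear program over the kink selections.  Tuning
minimises seeded 5-fold out-of-fold check loss with identical folds across
the grid; ties prefer the largest (sparsest) penalty.  Tuning is seeded
independently per quantile level and per CV fold, with seeds derived
deterministically from the run seed.  Post-ℓ1 refitting (unpenalised fit on
the selected support) is available but off by default, as the penalised
fits' prediction metrics do not call for debiasing.

**Normative protocol.**  Control subjects are predicted by 10-fold
cross-validation: fold assignment is a seeded uniform shuffle (no
stratification), and each fold's held-out subjects are centred with the
training-fold mean, scored with training-fold eigenfunctions, and predicted
by training-fold regressions.  Case cohorts are scored against a single fit
on all controls.  Per-subject outputs are the three predicted quantiles,
brainPAD = median prediction − chronological age, the coverage flag, and
the ∗-positive/∗-negative flags (age below the lower / above the upper
limit).  Crossed intervals (upper quantile prediction below the lower) are
counted as a sanity diagnostic but still used as the ordered pair
(min, max) rather than excluded; no monotonisation is applied.  Metrics are
MAE and RMSE of brainPAD, the Pearson correlation between median-predicted
and chronological age with its Fisher-z 95% interval
tanh(atanh r ± z₀.₉₇₅/√(n−3)), sample coverage, and the ∗ rates, which sum
to one with coverage in the absence of crossings.

**Coefficient maps.**  β̂_τ = Σ_m b̂_{m,τ} ψ_m is rendered on the grid
through the basis.  Because W is a unit-weight voxel sum, the matching
plug-in prediction is the unit-weight voxel sum of the centred smooth image
times the map — users reading magnitudes off the maps should note the
units are years per unit intensity per voxel, not per mm³.  Maps come from
the full-control fit, not from CV folds.

## Synthetic cohorts

The generator draws volumes from a truncated Karhunen–Loève expansion in a
generating B-spline basis: random coefficient vectors are W-orthonormalised
(QR under the W inner product) into generating eigenfunctions, so an
analysis run with a matching basis can in principle recover them, while a
deliberately different analysis basis probes misspecification.  Ages follow
the linear-in-scores location-scale model

    age = α + ν·b + σ(ν)·ε,

so the true conditional quantile α + ν·b + σ(ν)F_ε⁻¹(τ) is known for every
τ.  Defaults emulate an elderly imaging cohort: α = 75 years, five modes of
image variation with variances (25, 9, 4, 2, 1), slopes (1.0, −0.6, 0.4, 0,
0) years per score unit — i.e. three informative components among five, a
brain-driven age SD of ≈5.4 years — homoskedastic σ₀ = 2 years, a 24³ grid
at 1 mm with 4 mm generating knots (the full pipeline then runs in
seconds).  The location-scale option uses σ(ν) = σ₀ + σ₁ν₁ floored at
0.1σ₀.  A scale monotone in the score keeps the true quantiles inside the
linear-in-scores family the model fits; an even function of a symmetric
score (e.g. |ν₁|) would be invisible to a linear quantile fit — its best
linear approximation of the width is constant — so it could not support a
meaningful heteroskedasticity check.  The error distribution is normal or a
centred unit-rate exponential ("skewed"), exercising the distribution-free
coverage property.  Case subjects take an optional brainPAD shift: their
recorded age is lowered so their brains look older, which the normative
model should flag as ∗-positive.

What the generator does **not** emulate: anatomical structure, realistic
TBM intensity marginals (real TBM values cluster around the template
reference value; intensities here are mean-zero smooth fields), spatial
nonstationarity of the covariance, registration error, or site effects.
Passing tests therefore demonstrate the statistical machinery — projection
accuracy, eigenrecovery, interval calibration, selection behaviour — not
robustness to real acquisition artefacts.  Intensity rescaling conventions
(some TBM pipelines rescale the unit reference for number-format reasons)
are the caller's responsibility: images are taken as-is.

## Problem sizes and numerical choices

Simulation-based checks use desk-scale versions of the study design:
coverage calibration uses 20 replicates of N = 500 cohorts on a 24³ grid
(10-fold CV, unpenalised fits at τ = 0.05/0.5/0.95), slope recovery uses
the same cohorts with tuned LASSO plus post-ℓ1 at PVE 0.95, and the
scalar coverage benchmark uses 1000 training / 5000 test draws over 20
replicates.  The 220³, ~2-million-voxel scale of real cohorts changes only
the projection cost (per-image and embarrassingly parallel), not the
statistics.  Key tolerances: Gram/eigen rank cutoff 1e−10 relative;
W-orthonormality verified to 1e−8; score-space vs voxel-space prediction
identity to 1e−6; LP objectives to 1e−8 against oracles.  Slope entries
below 1e−9 on the standardised scale are snapped to exact zero when
reporting the support.

## Limitations

- Quantile crossing is detected and reported, never corrected
  (rearrangement/isotonisation are out of scope); crossed intervals are
  used as ordered pairs.
- Extreme quantile fits (τ near 0 or 1) are unstable where the training
  cohort is thin — e.g. at the young end of an elderly cohort — and
  undercoverage grows as training folds shrink.
- The truncation-by-PVE criterion selects components by image variance,
  not by association with age; the LASSO stage mitigates but cannot fully
  repair a truncation that discards a weakly expressed, age-relevant
  component.
- brainPAD is mechanically anticorrelated with chronological age (a
  regression-to-the-mean effect of any regression-based brain age);
  no bias correction is applied.
- Registration, bias-field correction and Jacobian computation are assumed
  done upstream; only grid shape and voxel size are validated, not
  orientation.
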
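# Methods

## Scientific setting

The pipeline studies whether regional texture of cerebellar MRI carries
diagnostic information about cognitive impairment. Per subject it expects
three co-registered scalar volumes (T1, T2, FLAIR) and one integer label map
partitioning the cerebellum into 26 regions; per (region, modality) pair it
computes 57 radiomic features; a sparse-representation classifier separates
two diagnostic groups; a cross-validated protocol reports the usual
diagnostic metrics. No imaging data ship with the package, so a synthetic
generator provides cohorts with known ground truth.

## Synthetic cohort generator

Each subject's volume per modality is

    v = gain_m · (baseline + shift_g + b_subject + ε)

with `baseline = 100` (arbitrary units), a per-group additive `shift_g`, a
per-subject random intercept `b_subject ~ N(0, subject_sd²)` shared across
modalities, and `ε` white Gaussian noise smoothed by an isotropic Gaussian
filter of per-group scale `smoothness_g` and rescaled (by the L2 norm of the
effective discrete kernel) so its voxel-level standard deviation equals
`noise_sd_g` exactly. Texture therefore varies between groups through the
spatial correlation length alone, which GLCM/NGTDM-type features track
monotonically; intensity varies through the additive shift.

Defaults (the generator's stated world):

| parameter | HC | MCI | AD | rationale |
|---|---|---|---|---|
| mean shift | 0 | 1 | 2 | 2-noise-s.d. separation between extremes, MCI intermediate |
| smoothness (voxels) | 1.0 | 1.25 | 1.5 | 1.5× texture contrast between extremes |
| noise s.d. | 1 | 1 | 1 | unit scale |
| subject s.d. | 0.5 (all groups) | | | between-subject biological variability; without it every subject of a group is statistically identical and any task is trivially separable |
| modality gain | T1 1.0, T2 0.9, FLAIR 1.1 | | | modalities as gain-scaled replicates |

The parcellation draws 26 seed points inside an ellipsoidal foreground
(semi-axes 45 % of each grid dimension) with a minimum-separation rejection
rule and assigns every foreground voxel to its nearest seed; cells are
convex, hence contiguous, and a sizing error names any region that would
receive fewer than 50 voxels. Grids are isotropic; the slice-thickness
anisotropy of real acquisitions is deliberately not simulated.

**What a green synthetic test does not establish.** The generator's three
modalities are statistically redundant replicates (same group effect,
independent noise); real modalities carry complementary contrast. Group
texture is controlled by a single knob with no per-subject texture
variability, so texture features are far more reliable here than in real
cohorts, and all classification arms saturate near accuracy 1.0 at the
default effect sizes. Green recovery tests establish that the machinery
works end to end and responds monotonically to effect size — not that real
cerebellar MRI attains any particular accuracy.

## Quantization and the feature catalogue

Regions are quantized to 32 equal-width gray levels between the region
minimum and maximum (ties at the maximum go to the top level; a constant
region maps to level 1 and is flagged). Because binning is min–max relative,
every quantized-domain feature is invariant to affine intensity rescaling.

The catalogue is fixed at 57 features per (region, modality): 18 intensity
(12 on raw voxel values; 6 `h_`-prefixed on the level histogram) and 39
texture (8 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM). Conventions, pinned once:

- population (1/n) variance; population skewness; **non-excess** kurtosis
  (Gaussian → 3);
- `h_uniformity` = Σ p_k² on the normalized level histogram; `h_energy` =
  Σ c_k² on the raw bin counts (the two would otherwise coincide);
- GLCM from the 13 unique distance-1 3-D offsets, counted symmetrically and
  **summed over offsets before normalization** (merged-direction strategy);
  sum average over the diagonal-sum distribution p_{x+y}; entropy in bits;
- GLRLM runs along the same 13 directions, summed; GLSZM zones by
  26-connectivity; NGTDM over the 26-voxel neighbourhood with edge-corrected
  (in-region only) neighbour means;
- the run-length/zone pairs printed ambiguously in some catalogue layouts
  (short/long-run emphasis; small/large-zone emphasis) are GLRLM and GLSZM
  features respectively — the only assignment giving 8 + 13 + 13 + 5 = 39.

Features are computed in 3-D (a 2-D per-slice mode is not provided; the
matrices module is written against 3-D arrays throughout).

**Degeneracy policy.** No feature ever returns a non-finite value. Constant
or single-voxel regions produce each feature's documented limit (e.g. GLCM
energy 1, contrast 0, correlation defined as 0) with a per-feature flag;
NGTDM denominators are guarded by ε = 10⁻⁶; regions smaller than
`min_voxels` (default 10) are extracted but fully flagged. Flagged cells are
re-imputed downstream by the per-column median of non-flagged *training*
cells, with the imputer state reused at test time.

## Sparse-representation classifier

Training columns are z-scored per feature (scale floored at 10⁻⁸), screened,
shifted by a constant `dictionary_offset` (default 4 training-s.d. units)
and unit-normalized. The offset is load-bearing: pure z-scoring makes the
two class means exactly antipodal, and since orthogonal matching pursuit
selects by absolute correlation with signed coefficients, either class then
reconstructs a test vector equally well — class-restricted residuals carry
no signal (we measured chance accuracy on cleanly separable data, and the
nearest-subspace ideal is equally blind because span(−v) = span(v)).
Shifting all features to a common positive baseline restores the
positively-correlated-columns regime that residual-based SRC assumes of raw
image or radiomics vectors, while keeping the scale equalization of the
z-score.

OMP adds the column most correlated with the current residual, re-solves
least squares on the support, and stops at `max_atoms` (default
min(30, columns)), at residual ≤ `tol` (10⁻⁶), or when no column correlates.
The ℓ₀ weight γ = 0.01 is carried as metadata; the operative sparsity
controls are `max_atoms` and `tol`. A zero test vector yields the zero code
with residual 0. Ties between class residuals go deterministically to
class 1 and are counted on the results object.

Note the sparsity cap must stay well below the number of screened features:
if the selected dimension is ≤ the atoms OMP may use, any class's columns
span the whole space and residuals degenerate. The defaults (k = 100
features, 30 atoms) respect this.

**Screening.** The ±1 class indicator is sparse-coded against the transposed
training matrix (each feature an atom over subjects, z-scored and
unit-normalized within the resample); over 10 stratified 80 % row subsamples
the absolute coefficients are accumulated; features are ranked by the total,
with ties broken by absolute label correlation and then column index; the
top k (default 100) are kept. Screening runs after modality concatenation.

## Evaluation protocol

`make_split` stratifies by group: per class, floor(n/3) subjects go to the
test side (remainder to cross-validation), and cv subjects are dealt
round-robin into 10 folds (fold sizes differ by ≤ 1 within class). Within
every training partition the imputer, normalizer, screening and dictionary
are re-fit from scratch; a deliberate-leakage experiment in the test suite
demonstrates that pre-fold screening measurably inflates null accuracy.

Fold predictions are pooled for the confusion matrix and ROC. The ROC score
is the signed relative residual (r₁ − r₂)/(r₁ + r₂ + 10⁻¹²) (positive ⇒
class 2); the raw residual pair is also exported. ROC points and AUC come
from the standard threshold sweep (trapezoidal AUC, equal to the normalized
Mann–Whitney U statistic; verified exactly against pair counting, ties ½).
Bracketed intervals are 2.5/97.5 percentiles over re-seeded repetitions of
the entire cross-validation (fold assignment re-drawn, cv/test partition
fixed) — a documented construction, not a reproduction of any published
interval mechanism. Metrics with empty denominators are reported as NA with
a warning. The positive class is CI (= MCI ∪ AD) for the CI-vs-HC task and
AD for the AD-vs-MCI task; both are configurable.

## Numerical and design choices made where the design was open

- **Split rounding:** floor on the test side per class, remainder to cv.
- **Modality fusion:** feature concatenation before screening.
- **Fold re-draw for repeats:** the cv/test partition is part of the design
  and stays fixed; only fold assignment and downstream seeds vary.
- **Modality comparison at ceiling:** at the default effect sizes all arms
  reach ~0.99–1.0 accuracy, so expected-accuracy comparisons between arms
  are only meaningful up to Monte-Carlo error; the acceptance check uses
  paired per-seed differences with a 2-SE one-sided allowance.
- **Seeds:** one master seed per cohort; per-subject seeds are master +
  subject index (recorded in the manifest); every stochastic stage takes an
  explicit seed.

## Known limitations

- No MRI physics: no bias fields, no partial-volume effects, no anisotropic
  voxels, no registration errors; label maps are taken as perfectly
  co-registered.
- The classifier is strictly binary; three-group questions are handled as
  configured binary tasks.
- Texture variability between subjects of a group is estimation noise only;
  real cohorts have biological texture heterogeneity the generator lacks.
- Screening ranks features by accumulated OMP coefficients; with strongly
  collinear informative features the selected set is stable but not unique,
  and downstream accuracy — not the identity of the selected set — is the
  meaningful output.
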
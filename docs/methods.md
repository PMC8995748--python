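# Methods

## Model and procedure

`voxelsurvey` treats binary disease-vs-control classification of
gray-matter-density (GMD) maps as a feature-selection problem wrapped
around a soft-margin SVM. The pipeline is:

1. **Group summaries.** For each voxel, a weighted mean over each group's
   maps yields M (disease) and N (control). Weights default to uniform;
   they are exposed because differential subject weighting (e.g. by scan
   quality) is a natural extension, but the package makes no claim about
   what weighting is appropriate.
2. **Equal-voxel deletion.** Voxels with |vm − vn| ≤ tol are removed.
   Exact float equality is fragile, so "equal" is tolerance-based
   (default tol = 1e−12 absolute). Raising tol is a monotone filter;
   retained + deleted always equals the voxel count.
3. **Similarity bounds.** Each retained voxel is the point
   p_i = (vm_i, vn_i); the similarity is the squared Euclidean distance
   ρ(p_i, p_j) (no square root). The voxel list is split into g contiguous,
   near-equal blocks (remainder spread over the first blocks) and ρ is held
   as the g(g+1)/2 block-pair matrices. C_min and C_max are the numbers of
   distinct voxels participating in at least one off-diagonal ρ within a
   relative tolerance (default 1e−9 of the extremum scale) of the global
   minimum and maximum respectively. Self-similarities are excluded from
   the scan, otherwise the minimum would always be 0. Near-duplicate voxels
   create ties near ρ = 0, so C_min ≥ C_max in practice; if a dataset ever
   produces the reverse, the two are swapped (with a logged warning) so the
   interval stays valid.
4. **Random surveys.** Survey size l ~ Uniform{C_max..C_min}; R is l
   distinct columns drawn without replacement. For each survey an SVM is
   tuned by validation-set grid search and the best-validation survey wins
   (ties: smaller l, then earlier survey). One stratified 6:2:2 split is
   fixed for all surveys of a run; per-survey resplitting would confound
   survey quality with split luck.
5. **Comparison harness.** Repeated fresh-split runs (default 10) evaluate
   linear regression, Lasso, PLS, plain SVM and RS-SVM. Baselines see the
   RS-SVM-selected columns by default ("do the selected features carry the
   signal?"); a mode with all retained columns is available. Continuous
   baselines classify by the sign of their score against the {−1, +1}
   labels.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `tol` | 1e−12 | equal-voxel deletion threshold (density units) |
| `g` | 10 | similarity block count (55 matrices); bounds are invariant to g |
| `extremum_tol` | 1e−9 | relative tie tolerance at the ρ extrema |
| `n_surveys` | 200 | random surveys per fit |
| grid | C ∈ {0.1, 1, 10, 100}; gamma ∈ {0.001, 0.01, 0.1, 0.5, 1}; kernel ∈ {linear, rbf} | always contains the conventional start point (C = 1, gamma = 0.5) |
| ratios | 6:2:2 | train/validation/test split, stratified, remainder train-first |

Grid-search ties break toward smaller C, then smaller gamma, then linear
before RBF — preferring the least-flexible model among equals.

## Evaluation conventions

The positive class is +1 (control). Accuracy, precision and recall are the
standard ratios; the weighted F score is implemented in the form
F = (α² + 1)·P·R / (α²·(P + R)), which differs from the conventional F_β
denominator for α ≠ 1 but coincides with the harmonic mean 2PR/(P+R) at the
default α = 1. Zero-denominator metrics are reported as flagged `None`
("undefined"), never silently 0. ROC curves sweep the unique decision
scores; AUC is trapezoidal and equals the Mann–Whitney rank statistic,
which the tests verify.

## The synthetic cohort generator

The generator emulates the two-group structure of a VBM study: one smooth
baseline field shared by all subjects (smoothed uniform noise, Gaussian
sigma 2 voxels, rescaled to [0.3, 0.7] so a 0.3 shift rarely clips),
a contiguous blob of informative voxels (random seed voxel grown by random
nearest-neighbour accretion; a scattered layout is available) where the
disease group loses `effect_size` density, i.i.d. Gaussian noise per voxel
(sd 0.05 by default), and clipping to [0, 1]. Baseline, mask and noise are
drawn from independent seeded streams, so changing `effect_size` alone
changes nothing else — matched-seed effect contrasts are exact. The default
study conditions are 60 subjects per group, (10, 12, 10) maps, a 40-voxel
lesion, effect 0.3, noise sd 0.05.

What the generator does **not** model: registration and segmentation error,
spatially correlated noise, partial-volume effects, covariates (age, sex,
education), inter-subject anatomical variability, or any claim about the
intensity distribution of real ADNI-style maps. Passing tests therefore
demonstrate the pipeline's mechanics and its recovery behaviour under a
clean planted-signal model, not clinical performance.

A consequence worth knowing: with continuous group summaries the global ρ
extrema are almost surely untied, so on synthetic data C_min = C_max = 2 is
typical and surveys are pairs of voxels. The planted effect (0.3 against
noise sd 0.05, a 6σ separation per voxel) makes any survey containing one
planted voxel a near-perfect classifier, which is why the selected pair
reliably contains a planted voxel (recovery ≈ 0.5 of the selected columns)
and test accuracy saturates. On real data, smoothing-induced near-duplicate
voxels produce many ties at ρ ≈ 0 and hence much larger C_min.

## Numerical choices

- The SVM quadratic program is solved by libsvm (scikit-learn `SVC`); the
  tests verify the returned optimum against an independent SLSQP solve of
  the dual to 1e−6 relative on small instances. Grid-search fits use solver
  tolerance 1e−3; oracle comparisons tighten it to 1e−10.
- Lasso minimizes (1/n)‖y − Xβ‖² + λ‖β‖₁ on centered data by coordinate
  descent (scikit-learn, alpha = λ/2, tol 1e−10); λ = 0 falls back to plain
  least squares. The soft-threshold closed form on orthonormal designs is
  the test oracle.
- PLS is NIPALS-style with deflation (scikit-learn `PLSRegression`,
  unscaled), Y the n×1 label vector; X-score orthogonality and
  full-component OLS equivalence are verified numerically.
- Linear regression uses minimum-norm least squares (`lstsq`) on centered
  data, so underdetermined problems are well-defined.
- All flattening is 0-based C order (last axis fastest), recorded in every
  output; all randomness flows from named seeds (cohort, split, survey) via
  `numpy.random.default_rng` — there is no hidden global RNG.

## Problem sizes

Tests and the acceptance script run the pipeline at (10, 12, 10) maps
(1,200 voxels) with 60 + 60 subjects and 200 surveys — a deliberate
scale-down of a whole-brain 61 × 73 × 61 analysis that keeps every stage
(similarity matrices, survey loop, 10-repetition harness) exact rather than
approximated. Full-resolution maps are supported; the similarity stage is
dense by design (O(n²) in retained voxels), so very large retained sets are
the user's responsibility to block or subsample.

## Known limitations

- The dense similarity stage is quadratic in retained voxels; no
  approximate-nearest-neighbour shortcut is provided.
- Binary contrasts only; no multi-class, no probability calibration, no
  nested cross-validation.
- The acceptance rule for a survey ("best validation accuracy") is a
  pragmatic operationalization; with small validation splits many surveys
  tie at 1.0 and the deterministic tie-breaks (smaller l, earlier survey)
  decide.
- No statistical comparison between models (e.g. DeLong tests on AUC).
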
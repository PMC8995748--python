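# voxelsurvey

Random-survey SVM (RS-SVM) feature detection for voxel-based morphometry
classification.

## The problem

Voxel-based morphometry (VBM) reduces a structural MRI to a 3D map of local
gray-matter density (GMD), one value per voxel. Classifying disease against
healthy controls from such maps — e.g. Alzheimer's disease, where atrophy
shows up as spatially contiguous gray-matter loss — faces a severe
dimensionality problem: tens of thousands of voxels against a few hundred
subjects. `voxelsurvey` implements a feature-detection pipeline for this
setting, aimed at researchers who want a compact, interpretable set of
discriminative voxels rather than a black-box whole-image classifier.

## The method

Labels are y ∈ {−1, +1} with −1 = disease, +1 = control. Starting from a
two-group cohort of GMD maps:

1. **Group matrices.** Per-voxel weighted means M (disease) and N (control)
   are computed; each voxel i becomes a point p_i = (vm_i, vn_i).
2. **Equal-voxel deletion.** Voxels with |vm − vn| ≤ tol carry no
   between-group signal and are dropped; the survivors define the
   subjects × retained-voxels feature matrix X.
3. **Similarity bounds.** The pairwise voxel similarity
   ρ(p_i, p_j) = (vm_i − vm_j)² + (vn_i − vn_j)² is computed blockwise
   (g contiguous blocks give g(g+1)/2 matrices; g = 10 gives 55). The
   number of voxels tied at the global minimum of ρ is C_min, at the global
   maximum C_max; the survey size is confined to l ∈ [C_max, C_min].
4. **Random surveys.** Repeatedly (default 200×) draw l distinct columns R
   at random, fit a soft-margin SVM (min ½‖w‖² + C·Σε, linear or RBF
   kernel) on the training split restricted to R, tune (kernel, C, gamma)
   by grid search on the validation split, and score. Subjects are split
   6:2:2 train/validation/test, stratified by group.
5. **Selection and evaluation.** The survey with the best validation
   accuracy provides the final feature set; the untouched test split
   measures its generalization (accuracy, precision, recall, F-measure,
   ROC/AUC, positive class = control).

A comparison harness benchmarks the selected features across five models —
linear regression, Lasso, PLS, plain SVM and RS-SVM — over repeated fresh
splits.

Because real VBM cohorts are access-restricted, the package ships a seeded
synthetic-cohort generator: a shared smooth baseline density field, a
contiguous "lesion" of informative voxels where the disease group loses a
fixed amount of density, Gaussian noise, clipping to [0, 1], and the
ground-truth voxel mask for recovery scoring.

## Worked example

```python
import voxelsurvey as vs

cohort = vs.generate_cohort(n_disease=20, n_control=20, dims=(8, 9, 8),
                            n_informative=25, effect_size=0.3, noise_sd=0.05,
                            seed=11)
model = vs.RandomSurveySVM.from_cohort(cohort, n_surveys=50)
results = model.fit(split_seed=1, survey_seed=2)
print(results.summary())
```

prints

```
Random-Survey SVM Results
============================================================
Subjects:              40 (train 24 / val 8 / test 8)
Feature columns:       576
Survey-size interval:  [2, 2]
Surveys run:           50
------------------------------------------------------------
Selected |R|:          2
Selected voxels:       [499, 556]
Kernel / C / gamma:    linear / 0.1 / None
Validation accuracy:   1.0000
Test accuracy:         1.0000
Test precision:        1.0000
Test recall:           1.0000
Test F-measure:        1.0000
Test AUC:              1.0000
Planted recovery:      0.5000
============================================================
```

All 576 voxels survive equal-voxel deletion (with continuous noise the two
group means never coincide exactly), the similarity extrema are untied so
the survey size collapses to l = 2, and the winning survey contains one of
the 25 planted voxels ("planted recovery" = 1/2 of the selected columns).
One planted voxel suffices here: a 0.3 density loss against 0.05 noise is a
6-sigma separation, so validation, test accuracy and AUC are all 1.0.

The same pipeline is available from the shell:

```bash
voxelsurvey simulate --n-disease 20 --n-control 20 --dims 8 9 8 \
    --n-informative 25 --seed 11 --out run/cohort
voxelsurvey prep   --cohort run/cohort --out run/prep
voxelsurvey bounds --pairs run/prep/pairs.tsv --groups 10 --out run/bounds
voxelsurvey select --features run/prep/features.npz \
    --bounds run/bounds/bounds.json --surveys 50 --out run/select
voxelsurvey full-run --out run/full   # the whole chain plus the 5-model harness
```

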
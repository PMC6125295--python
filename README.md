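# fdgpattern

Voxel-based classification of Alzheimer's-disease-like metabolic brain
patterns from FDG-PET (or perfusion-SPECT) volumes.

Clinical reading of FDG-PET in suspected dementia is qualitative: a
radiologist judges relative hypometabolism in parieto-temporal, frontal and
posterior cingulate cortex. This package implements the machine-based
alternative — whole-brain *pattern classifiers* that compress each scan into
a single subject score and a binary AD / non-AD designation — for
researchers comparing classifier families or applying a trained pattern
prospectively to new cohorts (MCI conversion, Lewy-body dementias, vascular
dementia).

Five machines are implemented over a common subjects × voxels matrix
(volumes masked by relative thresholding of the cohort mean image at 25% of
its maximum, then proportionally scaled to each scan's in-mask mean):

* **GLM** — per-voxel least squares of uptake on a 0/1 group dummy,
  `y = βx + c`; the β map is the pattern, and with 0/1 coding equals the
  disease-minus-control mean-difference map.
* **SSM/PCA1 and SSM/PCA2** — the scaled subprofile model: log transform,
  subject-mean then voxel-mean (double) centering, SVD for the top-10
  principal components. SSM1 keeps the single PC whose subject scores best
  separate the groups (largest |t|); SSM2 combines the PCs retained by
  stepwise regression of the label on PC scores (entry p < 0.05, removal
  p ≥ 0.10), weighted by the regression coefficients.
* **SVM-ISDA and SVM-SMO** — a linear soft-margin SVM trained by two
  from-scratch dual solvers: the iterative single data algorithm
  (coordinate ascent, bias absorbed by a 0.1 kernel offset, tolerance 0
  interpreted at the 64-bit epsilon floor) and sequential minimal
  optimization (maximal-violating-pair with second-order partner choice,
  explicit bias, tolerance 0.001); both capped at 10⁶ iterations, with a
  one-pass removal of the 5% largest-slack training scans ("outlier
  fraction") and a single refit.

Subject scores are dot products between the pattern map and the scan; for
GLM/SSM they are z-scored to the normal-control mean and SD and thresholded
at the ROC point maximizing sensitivity × specificity, while SVM machines
designate by the sign of the decision value. Evaluation is by stratified
10-fold cross-validation in which the mask, scaling reference, model and
threshold are all re-derived per training fold. Pattern maps are compared
by voxel-wise Pearson correlation with an autocorrelation-preserving
surrogate test (Fourier phase randomization) and optional Bonferroni
correction.

Because clinical scan databases are access-restricted, the package ships a
synthetic phantom generator (`synthetic_cohort`) producing post-
normalization-like volumes with a known planted pattern — smooth
brain-shaped template, multiplicative log-space disease pattern with target
expression effect size (Cohen's d), log-normal global scaling, smoothed
additive noise, and an age covariate — so every pipeline stage is testable
end to end.

## Worked example

```python
import numpy as np
import fdgpattern as fp

# 40 NL + 40 AD phantom volumes, planted effect d = 1.5, 32^3 grid
spec = fp.SyntheticCohortSpec(seed=1)
volumes, manifest, truth = fp.generate_cohort(spec)
labels = list(manifest["group"])

mask = fp.compute_mask(volumes)                      # 25%-of-max mean-image mask
matrix = fp.proportional_scale(fp.extract_matrix(volumes, mask, labels))

glm = fp.train_machine(matrix, "GLM")
r = np.corrcoef(glm.pattern, truth.pattern_volume[mask.include])[0, 1]
print(f"mask voxels: {mask.n_voxels}")
print(f"GLM recovery of planted pattern: r = {r:.3f}")

cv = fp.kfold_cv(volumes, labels, "SVM-ISDA", k=10, seed=1)
print(f"SVM-ISDA 10-fold CV: AUC {cv.auc:.3f}, "
      f"sens {cv.sensitivity:.3f}, spec {cv.specificity:.3f}")
```

prints

```
mask voxels: 4305
GLM recovery of planted pattern: r = 0.940
SVM-ISDA 10-fold CV: AUC 0.868, sens 0.600, spec 0.950
```

i.e. the β map recovers the planted hypo/hypermetabolism topography almost
exactly, and held-out classification reaches the ceiling the planted
expression overlap allows (at Cohen's d = 1.5 between near-normal score
distributions, AUC is bounded near Φ(1.5/√2) ≈ 0.86 regardless of
classifier; see `docs/methods.md`).

The same workflow is available from the shell:

```bash
fdgpattern simulate --out cohort/ --seed 1
fdgpattern train    --manifest cohort/manifest.tsv --out models/
fdgpattern crossval --manifest cohort/manifest.tsv --out cv/ --seed 1
fdgpattern apply    --model models/SVM-ISDA --manifest newcohort/manifest.tsv --out report/
fdgpattern compare  --map-a models/GLM_pattern.nii --map-b models/SSM1_pattern.nii \
                    --mask models/GLM_mask.nii
```

`crossval` writes a summary table with one row per machine and a `*` on the
best sensitivity × specificity; `apply` reports per-group "x of n"
AD-designation counts. All artifacts embed the config hash and seed, and
identical invocations are byte-identical.

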
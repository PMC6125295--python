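# Methods

## Problem setting

All machines operate on spatially normalized, smoothed 3D uptake volumes
that share one grid. No registration or smoothing is performed here; the
loader rejects non-finite data and grids that disagree. The pipeline's
common currency is the subjects × voxels matrix extracted under a
whole-brain mask; voxel order within the matrix is fixed as row-major (C
order) over mask-true cells, so pattern vectors are portable between runs
that share a mask.

### Masking and global normalization

The analysis mask keeps voxels whose *cohort mean* uptake is at least a
fraction (default 0.25) of that mean image's maximum. Using the mean image
rather than any single scan makes the mask deterministic and robust to
single-scan artifacts. Each scan is then proportionally scaled by dividing
by its own in-mask mean, removing dose and scanner-sensitivity factors.
Inside cross-validation the mask is recomputed from the training fold only;
for prospective application of a frozen model the training mask is reused
as-is (`apply` and the `mask=` argument).

## The five machines

**GLM.** Per voxel, uptake is regressed on a 0/1 group dummy
(disease = 1) with intercept. The slope map is the pattern; with 0/1
coding it equals the disease-minus-control mean-difference map, which the
test suite verifies against a generic normal-equations solver at 1e-10.
The intercept is fitted but not stored: it shifts every score equally and
is absorbed by z-referencing. The disease-positive coding is a convention
(higher score = more AD-like) asserted in tests; the choice of which group
carries code 1 is symmetric up to sign.

**SSM/PCA.** Values must be strictly positive. Natural log (base is a
convention of the subprofile-model literature), then each subject's mean
log value is removed — this cancels any multiplicative global factor
exactly, which is why SSM scores are invariant to rescaling a scan — and
then the across-subject voxel mean of the row-centered data (the group
mean profile, GMP) is removed and stored. Centering order matters: the GMP
is defined *after* row centering, which is what makes prospective scoring
well-defined. SVD of the doubly centered matrix gives orthonormal voxel
patterns (PCs), subject scores as projections, and variance fractions
σ²ⱼ/Σσ². Raw PC signs are fixed by making the largest-|loading| voxel
positive; at selection time the pattern is re-oriented so the disease
group's mean score is positive.

*SSM1* selects the PC with the largest pooled-variance two-sample |t| on
subject scores (ties go to the lowest index). *SSM2* runs stepwise linear
regression of the 0/1 label on PC scores — forward entry at p < 0.05,
backward removal at p ≥ 0.10, via ordinary least squares — and combines
the retained PCs with the fitted coefficients. Scores for the combined
pattern are recomputed by projecting the centered data onto it (equivalent
to combining per-PC scores up to scale; stated for determinism). If no PC
enters, the machine falls back to the single best PC with a warning.
Stepwise selection retains the truly informative component essentially
always, but like any forward selection at a fixed entry level it admits a
spurious component in roughly 1 − 0.95^k of replicates with k noise
candidates; the tests assert the former and bound the latter.

Prospective scoring of a new scan replays the chain — log, subtract the
scan's own mean, subtract the *training* GMP, project onto the pattern —
and z-scores against the training control reference. On training data this
reproduces the SVD subject scores exactly (projection is linear), which is
asserted at 1e-6.

**Linear SVM.** Both solvers maximize the soft-margin dual with kernel
K(x, z) = x·z/scale² + offset, box constraint C (default 1; the reference
implementation's default, exposed in config), and are capped at 10⁶
iterations.

* *ISDA* drops the equality constraint; the bias lives in the kernel
  offset (0.1) and is reported as offset × Σαᵢyᵢ. Each step exactly
  maximizes the dual in one coordinate (clipped to [0, C]); sweeps run in
  ascending subject order for reproducibility. The stated tolerance of 0
  is unachievable in floating point and is interpreted as
  1e-12 × max(1, initial |gradient|). Consequence: on image matrices,
  whose rows are strongly collinear, the dual Hessian is extremely
  ill-conditioned and ISDA routinely terminates at the iteration cap with
  a warning flag — the behaviour a zero tolerance implies — while
  decision values are long since stable; small well-conditioned problems
  converge to ~1e-15 KKT residual and match a generic box-QP solution.
* *SMO* keeps Σαᵢyᵢ = 0 (offset 0), selects the maximally KKT-violating
  index with a second-order max-gain partner, solves each two-variable
  subproblem analytically with box clipping, and recovers the bias from
  the KKT margins of unbounded support vectors (midpoint of the
  feasibility interval if none are free). Tolerance 0.001 on the
  up/low-set violation gap.

Robust learning ("outlier fraction" 0.05): after convergence the
⌈0.05·n⌉ training subjects with the largest hinge slack are removed and
the machine is refit once; removed ids are recorded. The exact algorithm
behind the reference implementation's option is not published; this
remove-and-refit reading implements its stated intent (tolerating an
assumed 5% of mislabeled training scans) and is flagged as an
approximation. SVM designation is by sign of w·x + b; no ROC threshold is
fitted, though z-scores are still reported for plotting parity.

## Evaluation

**ROC.** The empirical curve of "score ≥ threshold ⇒ positive", AUC by the
trapezoidal rule (ties contribute diagonal segments, making the AUC equal
to the Mann–Whitney pair-count statistic exactly — asserted on tie-heavy
score sets). The operating threshold is placed midway between adjacent
distinct scores at the maximum of sensitivity × specificity; exact product
ties resolve toward higher specificity (fewer false positives), then the
larger threshold.

**Cross-validation.** Stratified folds (per-group seeded permutation,
sizes within ±1); per fold, mask → scaling → model → z reference → ROC
threshold are derived from the training fold only, and held-out subjects
are scored prospectively. Metrics are pooled over all held-out scores
(not averaged over folds). A fold whose training part lacks two subjects
of either class fails loudly rather than silently re-stratifying.

**Cohort application.** A frozen model designates every subject of a
(possibly multi-group) cohort; the report gives per-group "x of n"
AD-designation counts, plus sensitivity/specificity when the caller flags
which groups count as true positives.

**Topographic similarity.** Pearson correlation of two pattern maps over
mask voxels. Significance comes from surrogate maps that preserve the
comparison map's spatial autocorrelation: the map is embedded in the mask
bounding box (zeros outside the mask), its FFT amplitude spectrum is kept,
phases are taken from a white-noise field (Hermitian by construction), and
the surrogate is re-masked. p = (1 + #{|r_surr| ≥ |r|})/(1 + n_surr),
multiplied by a caller-supplied Bonferroni factor for multi-pair tables;
999 surrogates by default. The published method this reconstructs is cited
but not described in the source literature, so this phase-randomization
null is a stated stand-in; calibration simulations (smooth independent
maps) put its type-I error slightly below nominal (≈0.03–0.05 at α = 0.05)
— mildly conservative because zero-filling outside the mask flattens the
spectrum, never anti-conservative in our measurements.

## Synthetic phantoms

Each phantom volume is

    scale · template · exp(expr · P) + noise,  truncated at 0

where the template is a strictly positive ellipsoidal envelope (peak 100,
radii 48/56/44 mm) plus Gaussian texture blobs; P is the planted log-space
pattern — three hypometabolic parieto-temporal-like blobs (factor 0.75)
and two hypermetabolic sensorimotor/cerebellar-like blobs (factor 1.15);
`scale` is log-normal (sd 0.1); and the additive noise is white noise
smoothed to the same 8 mm FWHM as real smoothed scans (so the similarity
test's calibration is honest), scaled to 5% of the in-support template
mean. Expression is `expression_sd` × Normal(loading × d, 1), so the
Cohen's d of ground-truth expression between a loading-1 group and
controls equals `effect_size` directly for any positive `expression_sd`
(setting it to 0 gives a fully degenerate cohort identical to the
template). Controls additionally receive a small positive age slope
(0.02/yr around age 73 ± 6), emulating the empirical age correlation of
AD-pattern expression in healthy subjects. Defaults: 32³ grid at 4 mm
(≈4.3k in-mask voxels), 40 subjects per arm, d = 1.5, seed-deterministic
to the bit. `make_dlb_like_cohort` re-uses the machinery to build one-arm
cohorts expressing the same pattern at an intermediate mean loading
(PDD/DLB-like ≈ 1, healthy-PD-like ≈ 0).

The phantom plants the pattern multiplicatively in log space — exactly the
scaled subprofile model's generative assumption — so SSM recovery is a
fair test while GLM and SVM see the same data. What phantoms do *not*
model: real anatomy, scanner point-spread, attenuation artifacts,
site/scanner batch effects, or disease heterogeneity; passing tests show
algorithmic correctness and statistical calibration, not clinical
performance.

### A ceiling worth knowing about

With expression drawn as Normal(μ_g, 1) and group means differing by d,
any subject score that is a monotone function of expression plus
independent noise has population AUC at most Φ(d/√2) — about 0.856 at
d = 1.5 — regardless of classifier. The default phantom's cross-validated
AUCs (≈0.85–0.88 across the five machines) sit at this ceiling; pushing
AUC higher requires a larger planted d, not a better classifier. This is
why the pattern-recovery correlations (≈0.93–0.997) are the sharper
measure of implementation quality at desk scale.

## Problem sizes and numerical choices

Test and acceptance workloads use the 32³ default phantom for recovery,
self-consistency and CV checks, a 16³ variant for the 100-replicate null
calibration (the solver cost, not the voxel count, dominates), 200
replicates × 199 surrogates for similarity calibration, and 30-sample
2-feature problems for the QP-oracle comparisons — sizes chosen so the
full suite runs in minutes on one CPU while keeping every Monte-Carlo
bound comfortably powered. Other numerics: sample SD (n−1) for the
z-reference; SVD sign fixed by largest loading; curvature floors of 1e-12
in both solvers; errors (not NaNs) on degenerate scans, constant control
scores, empty masks, and single-group fits.

## Known limitations

* The ISDA iteration-cap behaviour on collinear image data is inherited
  from the zero-tolerance setting; decision values are stable but the
  final KKT residual can be large. Increase `kkt_tolerance` for a clean
  convergence certificate.
* The surrogate similarity null is a reconstruction, not a reproduction,
  of the cited autocorrelation correction, and is slightly conservative.
* The robust-learning (outlier fraction) step is a one-pass
  interpretation of an underdocumented reference option.
* Prospective cohorts are z-scored against the training (derivation)
  reference by default; site-specific re-referencing is the caller's
  choice.
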
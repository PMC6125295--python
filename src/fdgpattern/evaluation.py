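"""Cross-validated evaluation, ROC thresholds, cohort reports, map similarity.

The evaluation protocol mirrors clinical pattern-classification practice:

* ROC analysis over subject scores gives the AUC (trapezoidal rule over the
  empirical curve, which equals the Mann-Whitney pair-count statistic) and
  the score threshold maximizing sensitivity x specificity.
* Stratified 10-fold cross-validation re-derives everything — mask,
  z-score reference, model, ROC threshold — from each training fold only;
  held-out subjects are scored prospectively and metrics are pooled over
  all held-out scores.
* Cohort application reports per-group AD-designation counts ("x of n").
* Topographic similarity between two pattern maps is the voxel-wise
  Pearson correlation, with significance assessed against surrogate maps
  that preserve the comparison map's spatial autocorrelation (Fourier
  phase randomization within the mask bounding box) and an optional
  Bonferroni factor for multi-pair tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, LabelError, MaskMismatchError, ModelStateError
from .glm_pattern import (
    METHODS,
    PatternModel,
    ScoreTable,
    fit_glm_pattern,
    score_subjects,
)
from .imaging_io import (
    BrainMask,
    BrainVolume,
    VoxelMatrix,
    compute_mask,
    encode_binary,
    proportional_scale,
)
from .ssm_pca import (
    DEFAULT_N_COMPONENTS,
    log_double_center,
    select_best_pc,
    ssm_svd,
    stepwise_combine,
)
from .svm_linear import SvmConfig, train_svm

__all__ = [
    "RocResult",
    "CvResult",
    "CohortReport",
    "SimilarityResult",
    "roc_analysis",
    "train_machine",
    "stratified_folds",
    "kfold_cv",
    "apply_to_cohort",
    "topographic_similarity",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    optimal_threshold: float
    optimal_sens: float
    optimal_spec: float

    @property
    def sens_x_spec(self) -> float:
        return self.optimal_sens * self.optimal_spec


def roc_analysis(scores: np.ndarray | ScoreTable, codes: np.ndarray) -> RocResult:
    """Empirical ROC curve of "score >= threshold => positive".

    AUC is the trapezoidal area under the curve (ties contribute diagonal
    segments, so this equals the Mann-Whitney statistic with ties counted
    half).  The optimal threshold is placed midway between adjacent
    distinct scores at the point maximizing sensitivity x specificity;
    exact ties in the product go to the higher-specificity (higher
    threshold) operating point.
    """
    if isinstance(scores, ScoreTable):
        scores = scores.z_score
    scores = np.asarray(scores, dtype=np.float64).ravel()
    codes = np.asarray(codes).ravel()
    if scores.size != codes.size:
        raise LabelError("scores and labels differ in length")
    if not np.isfinite(scores).all():
        raise LabelError("non-finite subject scores")
    pos, neg = scores[codes == 1], scores[codes == 0]
    if pos.size == 0 or neg.size == 0:
        raise LabelError("ROC analysis needs both groups")

    # empirical curve over descending distinct score values
    distinct = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for v in distinct:
        tpr.append(float((pos >= v).mean()))
        fpr.append(float((neg >= v).mean()))
    auc = float(np.trapezoid(tpr, fpr))

    # candidate thresholds: midpoints between adjacent distinct scores,
    # plus one beyond each extreme
    asc = distinct[::-1]
    cand = np.concatenate(
        ([asc[0] - 1.0], (asc[:-1] + asc[1:]) / 2.0, [asc[-1] + 1.0])
    )
    sens = (pos[:, None] >= cand[None, :]).mean(axis=0)
    spec = (neg[:, None] < cand[None, :]).mean(axis=0)
    product = sens * spec
    best = np.flatnonzero(product == product.max())
    # ties: higher specificity wins, then the larger threshold
    best = best[np.lexsort((cand[best], spec[best]))][-1]
    return RocResult(
        auc=auc,
        thresholds=cand,
        sensitivities=sens,
        specificities=spec,
        optimal_threshold=float(cand[best]),
        optimal_sens=float(sens[best]),
        optimal_spec=float(spec[best]),
    )


# ---------------------------------------------------------------------------
# training dispatch


def train_machine(
    matrix: VoxelMatrix,
    method: str,
    positive: str | None = None,
    svm_config: SvmConfig | None = None,
    n_components: int = DEFAULT_N_COMPONENTS,
    set_threshold: bool = True,
) -> PatternModel:
    """Train one of the five machines on a proportionally scaled matrix.

    For GLM/SSM machines the ROC-optimal z threshold over the training
    scores is stored on the model (``set_threshold=False`` skips this);
    SVM machines designate by sign and get no threshold.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "GLM":
        model = fit_glm_pattern(matrix, positive=positive)
    elif method in ("SSM1", "SSM2"):
        decomp = log_double_center(matrix)
        k = min(n_components, matrix.n_subjects - 1, matrix.mask.n_voxels)
        decomp = ssm_svd(decomp, k=k)
        if method == "SSM1":
            model = select_best_pc(decomp, matrix, positive=positive)
        else:
            model = stepwise_combine(decomp, matrix, positive=positive)
    else:
        solver = method.split("-", 1)[1]
        if svm_config is None:
            config = SvmConfig(solver=solver)
        elif svm_config.solver != solver:
            from dataclasses import replace

            config = replace(svm_config, solver=solver, kkt_tolerance=None, kernel_offset=None)
        else:
            config = svm_config
        model = train_svm(matrix, config=config, positive=positive)
    if set_threshold and method in ("GLM", "SSM1", "SSM2"):
        codes = encode_binary(matrix.labels, positive=positive)
        table = score_subjects(model, matrix, designate=False)
        roc = roc_analysis(table.z_score, codes)
        model.z_threshold = roc.optimal_threshold
    return model


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CvResult:
    method: str
    k: int
    seed: int
    fold_assignment: np.ndarray
    scores: ScoreTable
    auc: float
    sensitivity: float
    specificity: float
    per_fold_models: list[dict] = field(default_factory=list)

    @property
    def sens_x_spec(self) -> float:
        return self.sensitivity * self.specificity


def stratified_folds(labels: list[str], k: int, seed: int) -> np.ndarray:
    """Fold index per subject; within every group, fold sizes differ by <= 1."""
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if k > len(labels):
        raise ConfigError(f"k={k} exceeds the {len(labels)} available subjects")
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=np.int64)
    start = 0  # stagger groups so overall fold sizes stay balanced
    for g in sorted(set(labels)):
        idx = np.flatnonzero(np.asarray(labels, dtype=object) == g)
        rng.shuffle(idx)
        folds[idx] = (np.arange(idx.size) + start) % k
        start += idx.size
    return folds


def kfold_cv(
    volumes: list[BrainVolume],
    labels: list[str],
    method: str,
    k: int = 10,
    seed: int = 0,
    mask: BrainMask | None = None,
    rel_threshold: float = 0.25,
    positive: str | None = None,
    svm_config: SvmConfig | None = None,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> CvResult:
    """Stratified k-fold cross-validation of one machine, leakage-free.

    Unless a fixed ``mask`` is supplied, the whole-brain mask is recomputed
    from each training fold, so no test information reaches training.
    Held-out subjects are scored prospectively with the training fold's
    model, z reference and threshold (or sign rule); sensitivity,
    specificity and AUC are pooled over all held-out scores.
    """
    n = len(volumes)
    if len(labels) != n:
        raise LabelError(f"{n} volumes but {len(labels)} labels")
    codes = encode_binary(labels, positive=positive)
    folds = stratified_folds(labels, k, seed)
    stack = np.stack([v.data for v in volumes])
    ids = [v.subject_id or f"subj{i:03d}" for i, v in enumerate(volumes)]
    spacing = volumes[0].spacing

    raw = np.empty(n)
    z = np.empty(n)
    desig = np.empty(n, dtype=object)
    summaries: list[dict] = []

    for f in range(k):
        tr = np.flatnonzero(folds != f)
        te = np.flatnonzero(folds == f)
        tr_labels = [labels[i] for i in tr]
        counts = {g: tr_labels.count(g) for g in set(labels)}
        if min(counts.values(), default=0) < 2:
            raise LabelError(
                f"training fold {f} lacks subjects in some group ({counts}); "
                "use fewer folds or more subjects"
            )
        fold_mask = mask if mask is not None else compute_mask(
            [volumes[i] for i in tr], rel_threshold
        )
        inc = fold_mask.include

        def fold_matrix(idx: np.ndarray) -> VoxelMatrix:
            return proportional_scale(
                VoxelMatrix(
                    values=stack[idx][:, inc],
                    subject_ids=[ids[i] for i in idx],
                    labels=[labels[i] for i in idx],
                    mask=fold_mask,
                    scaled=False,
                )
            )

        model = train_machine(
            fold_matrix(tr),
            method,
            positive=positive,
            svm_config=svm_config,
            n_components=n_components,
        )
        table = score_subjects(model, fold_matrix(te))
        raw[te] = table.raw_score
        z[te] = table.z_score
        desig[te] = table.designation
        summaries.append(
            {
                "fold": f,
                "n_train": int(tr.size),
                "n_test": int(te.size),
                "n_voxels": fold_mask.n_voxels,
                "z_threshold": model.z_threshold,
                "bias": model.bias,
                "selected_pcs": model.extras.get("selected_pcs"),
                "removed_outliers": model.extras.get("removed_outliers"),
            }
        )

    is_ad = desig == "AD"
    sens = float(is_ad[codes == 1].mean())
    spec = float((~is_ad[codes == 0]).mean())
    auc = roc_analysis(z, codes).auc
    table = ScoreTable(
        subject_ids=ids, raw_score=raw, z_score=z,
        designation=list(desig), fold=folds,
    )
    return CvResult(
        method=method,
        k=k,
        seed=seed,
        fold_assignment=folds,
        scores=table,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        per_fold_models=summaries,
    )


# ---------------------------------------------------------------------------
# prospective cohort application


@dataclass
class CohortReport:
    """Per-group AD-designation counts under a fixed trained machine."""

    groups: list[str]
    n: dict[str, int]
    n_ad: dict[str, int]
    scores: ScoreTable
    sensitivity: float | None = None
    specificity: float | None = None

    def fraction(self, group: str) -> float:
        return self.n_ad[group] / self.n[group]

    def formatted(self, group: str) -> str:
        return f"{self.n_ad[group]} of {self.n[group]}"

    @property
    def sens_x_spec(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity * self.specificity

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "group": self.groups,
                "n": [self.n[g] for g in self.groups],
                "n_ad": [self.n_ad[g] for g in self.groups],
                "fraction_ad": [self.fraction(g) for g in self.groups],
                "designated": [self.formatted(g) for g in self.groups],
            }
        )


def apply_to_cohort(
    model: PatternModel,
    matrix: VoxelMatrix,
    positive_groups: set[str] | None = None,
) -> CohortReport:
    """Designate every subject in a (possibly multi-group) cohort.

    When ``positive_groups`` is given and splits the cohort into exactly
    positive and negative groups, sensitivity and specificity are reported
    alongside the per-group "x of n" counts.
    """
    table = score_subjects(model, matrix)
    groups = sorted(set(matrix.labels))
    is_ad = np.asarray([d == "AD" for d in table.designation])
    lab = np.asarray(matrix.labels, dtype=object)
    n = {g: int((lab == g).sum()) for g in groups}
    n_ad = {g: int(is_ad[lab == g].sum()) for g in groups}
    sens = spec = None
    if positive_groups:
        positive_groups = set(positive_groups)
        unknown = positive_groups - set(groups)
        if unknown:
            log.warning("positive groups %s not present in cohort", sorted(unknown))
        pos = np.isin(lab, sorted(positive_groups & set(groups)))
        if pos.any() and (~pos).any():
            sens = float(is_ad[pos].mean())
            spec = float((~is_ad[~pos]).mean())
    return CohortReport(
        groups=groups, n=n, n_ad=n_ad, scores=table,
        sensitivity=sens, specificity=spec,
    )


# ---------------------------------------------------------------------------
# topographic similarity


@dataclass
class SimilarityResult:
    r: float
    p_uncorrected: float
    p_corrected: float
    n_surrogates: int
    significant: bool


def _phase_randomize(box: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate field with the amplitude spectrum of ``box`` and the phases
    of a white-noise field (Hermitian by construction, hence real)."""
    amp = np.abs(np.fft.fftn(box))
    noise = np.fft.fftn(rng.standard_normal(box.shape))
    with np.errstate(invalid="ignore", divide="ignore"):
        phases = np.where(np.abs(noise) > 0, noise / np.abs(noise), 1.0)
    return np.fft.ifftn(amp * phases).real


def topographic_similarity(
    pattern_a: np.ndarray,
    pattern_b: np.ndarray,
    mask: BrainMask,
    n_surrogates: int = 999,
    seed: int = 0,
    bonferroni: int = 1,
) -> SimilarityResult:
    """Voxel-wise Pearson correlation of two pattern maps with an
    autocorrelation-aware permutation p-value.

    The null distribution comes from surrogate maps sharing pattern B's
    amplitude spectrum (Fourier phase randomization within the mask
    bounding box, re-masked), so smooth maps are not spuriously declared
    similar.  ``p = (1 + #{|r_surr| >= |r|}) / (1 + n_surrogates)``, then
    multiplied by the caller's Bonferroni factor for multi-pair tables.
    """
    a = np.asarray(pattern_a, dtype=np.float64).ravel()
    b = np.asarray(pattern_b, dtype=np.float64).ravel()
    if a.size != mask.n_voxels or b.size != mask.n_voxels:
        raise MaskMismatchError("patterns and mask disagree on voxel count")
    if n_surrogates < 99:
        raise ConfigError("n_surrogates must be >= 99 for a usable p-value")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ModelStateError("constant pattern: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])

    # embed B in its bounding box for the FFT
    ix, iy, iz = np.nonzero(mask.include)
    sl = tuple(slice(int(c.min()), int(c.max()) + 1) for c in (ix, iy, iz))
    box = np.zeros(mask.shape, dtype=np.float64)
    box[mask.include] = b
    box = box[sl]
    submask = mask.include[sl]

    rng = np.random.default_rng(seed)
    ac = a - a.mean()
    ac_norm = np.sqrt((ac**2).sum())
    count = 0
    for _ in range(n_surrogates):
        surr = _phase_randomize(box, rng)[submask]
        sc = surr - surr.mean()
        denom = ac_norm * np.sqrt((sc**2).sum())
        r_s = float(ac @ sc / denom) if denom > 0 else 0.0
        if abs(r_s) >= abs(r):
            count += 1
    p = (1 + count) / (1 + n_surrogates)
    p_corr = min(1.0, p * max(1, int(bonferroni)))
    return SimilarityResult(
        r=r,
        p_uncorrected=p,
        p_corrected=p_corr,
        n_surrogates=n_surrogates,
        significant=p_corr < 0.05,
    )
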
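"""Scaled subprofile model PCA (SSM/PCA) classifiers.

The SSM removes nuisance scaling before PCA: voxel values are
log-transformed, each subject's mean log value is subtracted (removing
multiplicative global factors exactly), and the across-subject voxel mean
of the row-centered data — the group mean profile (GMP) — is subtracted and
stored.  Singular value decomposition of the doubly centered matrix yields
voxel covariance patterns (PCs) and per-subject expression scores.

Two machines are derived from the decomposition:

* SSM1 — the single PC whose subject scores best separate the two groups
  (largest |two-sample t|), oriented so the disease group's mean score is
  positive.
* SSM2 — a linear combination of PCs retained by stepwise regression of the
  0/1 group label on PC scores (entry p < 0.05, removal p >= 0.10), with
  the fitted regression coefficients as combination weights.

New scans are scored prospectively by replaying the centering chain with
the *training* GMP and projecting onto the stored pattern, which makes
scores invariant to any global rescaling of the new scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import LabelError, ModelStateError, NonPositiveValueError
from .glm_pattern import PatternModel, ScoreTable, score_subjects, zscore_reference
from .imaging_io import VoxelMatrix, encode_binary

__all__ = [
    "SsmDecomposition",
    "log_double_center",
    "ssm_svd",
    "select_best_pc",
    "stepwise_combine",
    "prospective_score",
    "combination_report",
    "DEFAULT_N_COMPONENTS",
]

log = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 10
STEPWISE_P_ENTER = 0.05
STEPWISE_P_REMOVE = 0.10


@dataclass
class SsmDecomposition:
    """Doubly centered log data and (after :func:`ssm_svd`) its PCA.

    ``pcs`` rows are orthonormal voxel loading vectors; ``subject_scores``
    columns are the projections of the centered rows onto them (mutually
    orthogonal); ``vaf`` is the variance fraction accounted for per PC,
    non-increasing.
    """

    centered: np.ndarray
    gmp: np.ndarray
    pcs: np.ndarray | None = None
    subject_scores: np.ndarray | None = None
    singular_values: np.ndarray | None = None
    vaf: np.ndarray | None = None


def log_double_center(matrix: VoxelMatrix) -> SsmDecomposition:
    """Natural log, then subject-mean (row) centering, then voxel-mean
    (column) centering; the column means removed are stored as the GMP.

    Row centering first removes subject global scaling exactly; column
    centering then removes the shared metabolic topography.  Both margins
    of the result are zero: rows exactly, columns by construction, each
    within accumulation error.
    """
    if np.any(matrix.values <= 0):
        raise NonPositiveValueError("log transform requires strictly positive values")
    logs = np.log(matrix.values)
    logs -= logs.mean(axis=1, keepdims=True)
    gmp = logs.mean(axis=0)
    centered = logs - gmp[None, :]
    return SsmDecomposition(centered=centered, gmp=gmp)


def ssm_svd(decomp: SsmDecomposition, k: int = DEFAULT_N_COMPONENTS) -> SsmDecomposition:
    """Top-``k`` principal components of the doubly centered matrix.

    Returns the same decomposition with ``pcs`` (k x voxels, orthonormal),
    ``subject_scores`` (n x k), ``singular_values`` and ``vaf`` filled in.
    Each PC's sign is fixed deterministically: the loading of largest
    magnitude is positive (group orientation happens later, at selection).
    """
    n, v = decomp.centered.shape
    kmax = min(n - 1, v)
    if not 1 <= k <= kmax:
        raise ModelStateError(f"k must be in [1, {kmax}] for an {n} x {v} matrix, got {k}")
    u, s, vt = np.linalg.svd(decomp.centered, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ModelStateError("centered matrix is identically zero; no components")
    rank = int((s > s[0] * 1e-12).sum())
    if rank < k:
        log.warning("centered matrix has rank %d < k=%d; trailing PCs are noise", rank, k)
    pcs = vt[:k]
    scores = u[:, :k] * s[:k]
    # deterministic sign: largest-|loading| voxel positive
    for j in range(k):
        jmax = int(np.argmax(np.abs(pcs[j])))
        if pcs[j, jmax] < 0:
            pcs[j] = -pcs[j]
            scores[:, j] = -scores[:, j]
    decomp.pcs = pcs
    decomp.subject_scores = scores
    decomp.singular_values = s[:k].copy()
    decomp.vaf = s[:k] ** 2 / total
    return decomp


def _two_group_scores(decomp: SsmDecomposition, labels, positive):
    if decomp.subject_scores is None:
        raise ModelStateError("run ssm_svd before selecting components")
    x = encode_binary(labels, positive=positive)
    if min(int(x.sum()), int((1 - x).sum())) < 2:
        raise LabelError("need >= 2 subjects per group")
    return x


def _finalize(
    decomp: SsmDecomposition,
    matrix: VoxelMatrix,
    pattern: np.ndarray,
    x: np.ndarray,
    method: str,
    extras: dict,
) -> PatternModel:
    """Orient disease-positive, recompute scores by projection, set z reference."""
    raw = decomp.centered @ pattern
    if raw[x == 1].mean() < raw[x == 0].mean():
        pattern = -pattern
        raw = -raw
        extras["weights"] = [-w for w in extras["weights"]]
    model = PatternModel(
        method=method,
        pattern=pattern,
        bias=0.0,
        mask=matrix.mask,
        extras={"gmp": decomp.gmp.copy(), "log_base": "natural", **extras},
    )
    model.ref_mean, model.ref_sd = zscore_reference(raw[x == 0])
    return model


def select_best_pc(
    decomp: SsmDecomposition,
    matrix: VoxelMatrix,
    positive: str | None = None,
) -> PatternModel:
    """SSM1: keep the single PC whose subject scores best separate the groups.

    Discrimination is measured by the pooled-variance two-sample t statistic
    on subject scores; the PC with the largest |t| wins, ties going to the
    lowest PC index.
    """
    x = _two_group_scores(decomp, matrix.labels, positive)
    scores = decomp.subject_scores
    tvals = np.array(
        [
            stats.ttest_ind(scores[x == 1, j], scores[x == 0, j]).statistic
            for j in range(scores.shape[1])
        ]
    )
    tvals = np.nan_to_num(tvals, nan=0.0)
    best = int(np.argmax(np.abs(tvals)))  # argmax takes the first (lowest) index on ties
    log.info("SSM1 selected PC%d (|t| = %.3f)", best + 1, abs(tvals[best]))
    return _finalize(
        decomp,
        matrix,
        decomp.pcs[best].copy(),
        x,
        "SSM1",
        {"selected_pcs": [best], "weights": [1.0], "t_statistics": tvals.tolist()},
    )


def stepwise_combine(
    decomp: SsmDecomposition,
    matrix: VoxelMatrix,
    positive: str | None = None,
    p_enter: float = STEPWISE_P_ENTER,
    p_remove: float = STEPWISE_P_REMOVE,
) -> PatternModel:
    """SSM2: stepwise linear regression of the 0/1 label on PC subject scores.

    Forward steps add the candidate PC with the smallest coefficient p-value
    when it is below ``p_enter``; after each addition, backward steps drop
    any retained PC whose p-value has risen to ``p_remove`` or above.  The
    final regression coefficients weight the retained PCs into a single
    combined pattern.  If no PC enters, the machine falls back to
    :func:`select_best_pc` with a warning.
    """
    import statsmodels.api as sm

    x = _two_group_scores(decomp, matrix.labels, positive)
    scores = decomp.subject_scores
    k = scores.shape[1]
    included: list[int] = []

    def pvalues(cols: list[int]) -> np.ndarray:
        design = sm.add_constant(scores[:, cols])
        fit = sm.OLS(x.astype(float), design).fit()
        return fit.pvalues[1:], fit.params[1:]

    changed = True
    while changed:
        changed = False
        candidates = [j for j in range(k) if j not in included]
        best_p, best_j = np.inf, None
        for j in candidates:
            p, _ = pvalues(included + [j])
            if p[-1] < best_p:
                best_p, best_j = p[-1], j
        if best_j is not None and best_p < p_enter:
            included.append(best_j)
            changed = True
            while len(included) > 1:
                p, _ = pvalues(included)
                worst = int(np.argmax(p))
                if p[worst] >= p_remove:
                    log.info("SSM2 removed PC%d (p = %.3f)", included[worst] + 1, p[worst])
                    included.pop(worst)
                else:
                    break
    if not included:
        warnings.warn(
            "stepwise regression retained no PC; falling back to best single PC",
            stacklevel=2,
        )
        model = select_best_pc(decomp, matrix, positive)
        model.method = "SSM2"
        return model
    _, weights = pvalues(included)
    order = np.argsort(included)
    included = [included[i] for i in order]
    weights = [float(weights[i]) for i in order]
    pattern = np.zeros_like(decomp.pcs[0])
    for j, w in zip(included, weights):
        pattern += w * decomp.pcs[j]
    log.info("SSM2 retained %s", " + ".join(f"PC{j + 1}" for j in included))
    return _finalize(
        decomp,
        matrix,
        pattern,
        x,
        "SSM2",
        {"selected_pcs": included, "weights": weights},
    )


def combination_report(model: PatternModel) -> str:
    """Human-readable PC combination, e.g. ``4.204 x PC1 + 0.865 x PC2 - 1.825 x PC4``."""
    pcs = model.extras.get("selected_pcs")
    weights = model.extras.get("weights")
    if not pcs:
        return "(no PC combination stored)"
    parts = []
    for i, (j, w) in enumerate(zip(pcs, weights)):
        term = f"{abs(w):.3f} × PC{j + 1}"
        if i == 0:
            parts.append(("−" if w < 0 else "") + term)
        else:
            parts.append(("− " if w < 0 else "+ ") + term)
    return " ".join(parts)


def prospective_score(
    model: PatternModel, new_matrix: VoxelMatrix, designate: bool = True
) -> ScoreTable:
    """Score new scans under a trained SSM machine.

    Each row is log-transformed, centered to its own mean, has the training
    GMP subtracted, and is projected onto the pattern; z-scoring uses the
    training control reference.  On training data this reproduces the
    SVD-derived subject scores exactly (projection is linear).
    """
    if model.method not in ("SSM1", "SSM2"):
        raise ModelStateError("prospective_score applies to SSM models only")
    return score_subjects(model, new_matrix, designate=designate)
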
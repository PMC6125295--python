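"""Linear soft-margin SVM trained by two from-scratch dual solvers.

Both solvers maximize the soft-margin dual

    D(a) = sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j),   0 <= a_i <= C

with the linear kernel ``K(x, z) = x.z / scale^2 + offset``.

* ISDA (iterative single data algorithm) drops the equality constraint
  ``sum a_i y_i = 0`` entirely: the bias is absorbed by a positive kernel
  offset (default 0.1), and each step exactly maximizes the dual in one
  coordinate, clipped to the box.  The reported bias is
  ``offset * sum(a_i y_i)``.
* SMO (sequential minimal optimization) keeps the equality constraint
  (offset 0), picks the maximally KKT-violating index and a second-order
  max-gain partner, solves the two-variable subproblem analytically, and
  recovers the bias from the KKT margins of unbounded support vectors.

Robust learning: after convergence, the ``ceil(outlier_fraction * n)``
training subjects with the largest hinge slack are removed and the machine
is refit once on the remainder — a tolerance for an assumed fraction of
mislabeled training scans (default 5%).

Designation of new scans is by the sign of ``w.x + b``; no ROC threshold
is fitted for SVM machines.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import ConfigError, LabelError, ModelStateError
from .glm_pattern import PatternModel, zscore_reference
from .imaging_io import VoxelMatrix, encode_binary

__all__ = [
    "SvmConfig",
    "DualState",
    "train_svm",
    "isda_step",
    "smo_step",
    "dual_objective",
    "kkt_violations",
]

log = logging.getLogger(__name__)

_SOLVER_DEFAULTS = {
    # tolerance for gradient difference; kernel offset
    "ISDA": {"kkt_tolerance": 0.0, "kernel_offset": 0.1},
    "SMO": {"kkt_tolerance": 0.001, "kernel_offset": 0.0},
}
#: a stated tolerance of exactly 0 is interpreted as this machine-epsilon floor
ZERO_TOL_FLOOR = 1e-12
_TAU = 1e-12


@dataclass
class SvmConfig:
    """Solver settings; unset tolerance/offset fall back to per-solver defaults
    (ISDA: tolerance 0 -> machine-epsilon floor, offset 0.1; SMO: 0.001, 0)."""

    solver: str = "ISDA"
    C: float = 1.0
    kkt_tolerance: float | None = None
    max_iterations: int = 1_000_000
    kernel_offset: float | None = None
    kernel_scale: float = 1.0
    outlier_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.solver not in _SOLVER_DEFAULTS:
            raise ConfigError(f"solver must be ISDA or SMO, got {self.solver!r}")
        if self.kkt_tolerance is None:
            self.kkt_tolerance = _SOLVER_DEFAULTS[self.solver]["kkt_tolerance"]
        if self.kernel_offset is None:
            self.kernel_offset = _SOLVER_DEFAULTS[self.solver]["kernel_offset"]
        if self.C <= 0:
            raise ConfigError("box constraint C must be positive")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ConfigError("outlier_fraction must be in [0, 0.5)")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.kernel_scale <= 0:
            raise ConfigError("kernel_scale must be positive")


@dataclass
class DualState:
    """Mutable solver state: box-constrained duals and the dual gradient
    ``grad_i = 1 - y_i * sum_j alpha_j y_j K_ij``."""

    K: np.ndarray
    y: np.ndarray
    C: float
    alphas: np.ndarray = field(default=None)  # type: ignore[assignment]
    grad: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.K.shape[0]
        if self.alphas is None:
            self.alphas = np.zeros(n)
        if self.grad is None:
            q = (self.y[:, None] * self.y[None, :]) * self.K
            self.grad = 1.0 - q @ self.alphas


def dual_objective(state: DualState) -> float:
    """sum(a) - 1/2 a^T Q a with Q = (y y^T) * K."""
    qa = (state.y * (state.K @ (state.alphas * state.y)))
    return float(state.alphas.sum() - 0.5 * state.alphas @ qa)


def kkt_violations(state: DualState) -> np.ndarray:
    """Per-point KKT residual: how far grad_i is from its optimality box."""
    g, a, C = state.grad, state.alphas, state.C
    v = np.abs(g)
    v = np.where(a <= 0, np.maximum(g, 0.0), v)
    v = np.where(a >= C, np.maximum(-g, 0.0), v)
    return v


# ---------------------------------------------------------------------------
# ISDA


def isda_step(state: DualState, i: int) -> DualState:
    """Exactly maximize the dual in coordinate ``i``, clipped to [0, C].

    The dual objective never decreases.  Zero kernel curvature (K_ii = 0)
    skips the coordinate with a log entry.
    """
    kii = state.K[i, i]
    if kii <= 0:
        log.warning("ISDA: zero curvature at subject %d, coordinate skipped", i)
        return state
    new = min(max(state.alphas[i] + state.grad[i] / kii, 0.0), state.C)
    delta = new - state.alphas[i]
    if delta != 0.0:
        state.alphas[i] = new
        state.grad -= (delta * state.y[i]) * (state.y * state.K[:, i])
    return state


@njit(cache=True)
def _isda_solve(K, y, alphas, grad, C, tol, max_iter):  # pragma: no cover - numba
    n = K.shape[0]
    it = 0
    while it < max_iter:
        maxviol = 0.0
        for i in range(n):
            g = grad[i]
            a = alphas[i]
            if a <= 0.0:
                v = g if g > 0.0 else 0.0
            elif a >= C:
                v = -g if g < 0.0 else 0.0
            else:
                v = abs(g)
            if v > maxviol:
                maxviol = v
            kii = K[i, i]
            if kii <= 0.0:
                continue
            na = a + g / kii
            if na < 0.0:
                na = 0.0
            elif na > C:
                na = C
            d = na - a
            it += 1
            if d != 0.0:
                alphas[i] = na
                yi = y[i]
                for j in range(n):
                    grad[j] -= d * yi * y[j] * K[j, i]
            if it >= max_iter:
                break
        if maxviol <= tol:
            break
    return it


# ---------------------------------------------------------------------------
# SMO


def _smo_select(state: DualState, tol: float):
    """Maximal-violating index i, second-order max-gain partner j.

    Returns (i, j, gap); j = -1 signals convergence (gap <= tol)."""
    y, a, g, C = state.y, state.alphas, state.grad, state.C
    up = ((y > 0) & (a < C)) | ((y < 0) & (a > 0))
    low = ((y < 0) & (a < C)) | ((y > 0) & (a > 0))
    score = y * g  # = -y_i G_i with G the minimization gradient Q a - e
    if not up.any() or not low.any():
        return -1, -1, 0.0
    i = int(np.flatnonzero(up)[np.argmax(score[up])])
    m = score[i]
    M = score[low].min()
    if m - M <= tol:
        return i, -1, m - M
    cand = low & (score < m)
    if not cand.any():
        return i, -1, m - M
    idx = np.flatnonzero(cand)
    diff = m - score[idx]
    quad = state.K[i, i] + state.K[idx, idx] - 2.0 * state.K[i, idx]
    quad = np.maximum(quad, _TAU)
    j = int(idx[np.argmax(diff * diff / quad)])
    return i, j, m - M


def smo_step(state: DualState, tol: float = 0.001):
    """One analytic two-variable update preserving ``sum a_i y_i = 0``.

    Returns ``(state, converged)``; converged is True when no pair violates
    the KKT conditions by more than ``tol`` (no update is applied then).
    The dual objective is non-decreasing across steps.
    """
    i, j, _gap = _smo_select(state, tol)
    if j < 0:
        return state, True
    K, y, a, g, C = state.K, state.y, state.alphas, state.grad, state.C
    # libsvm-style minimization gradient G = -grad
    Gi, Gj = -g[i], -g[j]
    quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
    if quad <= 0:
        quad = _TAU
    ai_old, aj_old = a[i], a[j]
    if y[i] != y[j]:
        delta = (-Gi - Gj) / quad
        diff = ai_old - aj_old
        ai, aj = ai_old + delta, aj_old + delta
        if diff > 0:
            if aj < 0:
                aj, ai = 0.0, diff
            if ai > C:
                ai, aj = C, C - diff
        else:
            if ai < 0:
                ai, aj = 0.0, -diff
            if aj > C:
                aj, ai = C, C + diff
    else:
        delta = (Gi - Gj) / quad
        total = ai_old + aj_old
        ai, aj = ai_old - delta, aj_old + delta
        if total > C:
            if ai > C:
                ai, aj = C, total - C
            if aj > C:
                aj, ai = C, total - C
        else:
            if aj < 0:
                aj, ai = 0.0, total
            if ai < 0:
                ai, aj = 0.0, total
    dai, daj = ai - ai_old, aj - aj_old
    a[i], a[j] = ai, aj
    state.grad -= state.y * (dai * y[i] * K[:, i] + daj * y[j] * K[:, j])
    return state, False


def _smo_bias(state: DualState) -> float:
    """Bias from KKT margins: average of ``y_i - w.x_i`` over unbounded
    support vectors, midpoint of the feasibility interval otherwise."""
    y, a, g, C = state.y, state.alphas, state.grad, state.C
    score = y * g  # equals b_i = y_i - w.x_i at each point
    free = (a > _TAU) & (a < C - _TAU)
    if free.any():
        return float(score[free].mean())
    up = ((y > 0) & (a < C)) | ((y < 0) & (a > 0))
    low = ((y < 0) & (a < C)) | ((y > 0) & (a > 0))
    if up.any() and low.any():
        return float((score[up].max() + score[low].min()) / 2.0)
    return 0.0


# ---------------------------------------------------------------------------
# training


def _solve(K: np.ndarray, y: np.ndarray, config: SvmConfig) -> tuple[DualState, int, float]:
    state = DualState(K=K, y=y, C=config.C)
    tol = config.kkt_tolerance
    if config.solver == "ISDA":
        if tol <= 0:
            tol = ZERO_TOL_FLOOR * max(1.0, float(np.abs(state.grad).max()))
        iters = int(
            _isda_solve(K, y, state.alphas, state.grad, config.C, tol, config.max_iterations)
        )
        final = float(kkt_violations(state).max())
    else:
        tol = max(tol, _TAU)
        iters = 0
        converged = False
        while iters < config.max_iterations:
            state, converged = smo_step(state, tol)
            if converged:
                break
            iters += 1
        _i, _j, final = _smo_select(state, tol)
        final = float(max(final, 0.0))
    if iters >= config.max_iterations:
        warnings.warn(
            f"{config.solver} hit max_iterations={config.max_iterations} "
            f"(KKT residual {final:.2e})",
            stacklevel=3,
        )
    return state, iters, final


def train_svm(
    matrix: VoxelMatrix,
    config: SvmConfig | None = None,
    positive: str | None = None,
) -> PatternModel:
    """Train a linear SVM on a proportionally scaled two-group matrix.

    Returns a :class:`PatternModel` whose pattern is the hyperplane normal
    ``w = sum a_i y_i x_i / scale^2`` and whose extras record the dual
    coefficients, support-vector ids, removed outliers, iteration count and
    final KKT residual.  z-scores use the control-score reference (reported
    for plotting parity only; designation is by raw-score sign).
    """
    if config is None:
        config = SvmConfig()
    if not matrix.scaled:
        raise ModelStateError("train_svm requires a proportionally scaled matrix")
    codes = encode_binary(matrix.labels, positive=positive)
    if min(int(codes.sum()), int((1 - codes).sum())) < 1:
        raise LabelError("both classes must be present")
    X = matrix.values
    if np.allclose(X, X[0], rtol=0.0, atol=1e-15):
        raise ModelStateError("all training rows identical; SVM problem is degenerate")
    y = np.where(codes == 1, 1.0, -1.0)
    keep = np.arange(X.shape[0])

    def fit(sub: np.ndarray) -> tuple[DualState, int, float]:
        Xs = X[sub] / config.kernel_scale
        K = Xs @ Xs.T + config.kernel_offset
        return _solve(K, y[sub], config)

    state, iters, final = fit(keep)
    removed: list[int] = []
    if config.outlier_fraction > 0:
        # one remove-and-refit pass on the largest-slack training points;
        # y_i f(x_i) = 1 - grad_i (+ y_i b for SMO's explicit bias)
        b0 = _smo_bias(state) if config.solver == "SMO" else 0.0
        slack = np.maximum(state.grad - state.y * b0, 0.0)
        n_drop = math.ceil(config.outlier_fraction * keep.size)
        order = np.lexsort((keep, -slack))  # largest slack first, index as tie-break
        removed = sorted(int(keep[t]) for t in order[:n_drop])
        keep = np.array([t for t in keep if t not in set(removed)])
        if len(set(matrix.labels[t] for t in keep)) < 2:
            raise LabelError("outlier removal emptied one class; lower outlier_fraction")
        state, iters, final = fit(keep)
        log.info("robust refit after removing %d outliers: %s", n_drop, removed)

    Xs = X[keep] / config.kernel_scale
    w = (state.alphas * state.y) @ Xs / config.kernel_scale
    if config.solver == "ISDA":
        bias = config.kernel_offset * float((state.alphas * state.y).sum())
    else:
        bias = _smo_bias(state)
    model = PatternModel(
        method=f"SVM-{config.solver}",
        pattern=w,
        bias=bias,
        mask=matrix.mask,
        extras={
            "alphas": state.alphas.copy(),
            "support_ids": [matrix.subject_ids[keep[t]]
                            for t in np.flatnonzero(state.alphas > _TAU)],
            "kept_indices": keep.tolist(),
            "removed_outliers": [matrix.subject_ids[t] for t in removed],
            "solver_iterations": iters,
            "final_kkt_violation": final,
            "config": {
                "solver": config.solver,
                "C": config.C,
                "kkt_tolerance": config.kkt_tolerance,
                "max_iterations": config.max_iterations,
                "kernel_offset": config.kernel_offset,
                "kernel_scale": config.kernel_scale,
                "outlier_fraction": config.outlier_fraction,
            },
        },
    )
    raw = matrix.values @ model.pattern + model.bias
    controls = codes == 0
    if controls.sum() >= 2 and np.std(raw[controls]) > 0:
        model.ref_mean, model.ref_sd = zscore_reference(raw[controls])
    else:
        model.ref_mean, model.ref_sd = 0.0, 1.0
    return model
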
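"""Voxel-wise GLM classifier and the shared pattern-model / scoring machinery.

The GLM machine regresses each voxel's proportionally scaled value on a 0/1
group dummy (disease = 1).  The per-voxel slope map ("beta map") is the
metabolic pattern; with 0/1 coding the least-squares slope equals the
disease-minus-control voxel mean difference.  A subject's raw score is the
dot product of their scaled image with the pattern; scores are z-scored to
the mean and standard deviation of the normal (control) training subjects,
and a z threshold chosen by ROC analysis turns scores into AD / non-AD
designations.

:class:`PatternModel` and :func:`score_subjects` are shared by all five
machines.  SSM models score through the scaled-subprofile centering chain
(log, subject-mean removal, group-mean-profile removal); SVM models use the
sign of the raw decision value instead of a z threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import (
    LabelError,
    MaskMismatchError,
    ModelStateError,
    NonPositiveValueError,
)
from .imaging_io import (
    BrainMask,
    VoxelMatrix,
    encode_binary,
    insert_matrix,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = [
    "PatternModel",
    "ScoreTable",
    "METHODS",
    "fit_glm_pattern",
    "zscore_reference",
    "score_subjects",
    "save_model",
    "load_model",
]

#: canonical method identifiers
METHODS = ("GLM", "SSM1", "SSM2", "SVM-ISDA", "SVM-SMO")
_SSM_METHODS = ("SSM1", "SSM2")
_SVM_METHODS = ("SVM-ISDA", "SVM-SMO")


@dataclass
class PatternModel:
    """A trained classification machine.

    ``pattern`` is the map over mask voxels (beta map, combined PC, or
    hyperplane normal w), ``bias`` the additive offset (0 for GLM/SSM, b for
    SVM).  ``ref_mean``/``ref_sd`` are the control-score normalization
    constants; ``z_threshold`` is set by ROC analysis for GLM/SSM machines
    and must stay ``None`` for SVM machines (sign rule).  ``extras`` holds
    method-specific state (SSM centering profile and PC weights, SVM duals).
    """

    method: str
    pattern: np.ndarray
    bias: float
    mask: BrainMask
    ref_mean: float | None = None
    ref_sd: float | None = None
    z_threshold: float | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ModelStateError(f"unknown method {self.method!r}")
        self.pattern = np.asarray(self.pattern, dtype=np.float64).ravel()
        if self.pattern.size != self.mask.n_voxels:
            raise MaskMismatchError(
                f"pattern length {self.pattern.size} != mask voxels {self.mask.n_voxels}"
            )
        if self.ref_sd is not None and self.ref_sd <= 0:
            raise ModelStateError("ref_sd must be positive")
        if self.z_threshold is not None and self.method in _SVM_METHODS:
            raise ModelStateError("SVM models designate by score sign, not z threshold")


@dataclass
class ScoreTable:
    """Per-subject raw scores, z-scores and AD / non-AD designations."""

    subject_ids: list[str]
    raw_score: np.ndarray
    z_score: np.ndarray
    designation: list[str]  # "AD" or "non-AD"
    fold: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "raw_score": self.raw_score,
                "z_score": self.z_score,
                "designation": self.designation,
            }
        )
        if self.fold is not None:
            df["fold"] = self.fold
        return df

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def zscore_reference(control_scores: np.ndarray) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of control scores."""
    s = np.asarray(control_scores, dtype=np.float64).ravel()
    if s.size < 2:
        raise LabelError(f"need >= 2 control scores, got {s.size}")
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    if sd <= 0:
        raise LabelError("control scores are constant; z-reference undefined")
    return mean, sd


def fit_glm_pattern(
    matrix: VoxelMatrix, positive: str | None = None
) -> PatternModel:
    """Fit the voxel-wise GLM beta map on a proportionally scaled two-group matrix.

    Each voxel's value is regressed on the 0/1 group dummy (with intercept);
    the slope map is the pattern.  The intercept is fitted but not stored —
    it shifts all raw scores equally and is absorbed by z-scoring.
    """
    if not matrix.scaled:
        raise ModelStateError("fit_glm_pattern requires a proportionally scaled matrix")
    x = encode_binary(matrix.labels, positive=positive).astype(np.float64)
    n1, n0 = int(x.sum()), int((1 - x).sum())
    if min(n0, n1) < 2:
        raise LabelError(f"need >= 2 subjects per group, got {n0} / {n1}")
    # least-squares slope via the centered normal equations
    xc = x - x.mean()
    beta = xc @ matrix.values / (xc @ xc)
    model = PatternModel(method="GLM", pattern=beta, bias=0.0, mask=matrix.mask)
    raw = matrix.values @ model.pattern
    try:
        model.ref_mean, model.ref_sd = zscore_reference(raw[x == 0])
    except LabelError:
        # degenerate (constant) control scores: keep the pattern usable but
        # leave the z reference unset; scoring will demand one
        model.ref_mean, model.ref_sd = float(raw[x == 0].mean()), None
    return model


def _ssm_center_rows(values: np.ndarray, gmp: np.ndarray) -> np.ndarray:
    """Log-transform, remove each subject's mean, subtract the training GMP."""
    if np.any(values <= 0):
        raise NonPositiveValueError("SSM scoring requires strictly positive voxel values")
    logs = np.log(values)
    logs -= logs.mean(axis=1, keepdims=True)
    return logs - gmp[None, :]


def raw_scores(model: PatternModel, matrix: VoxelMatrix) -> np.ndarray:
    """Decision values for each row of ``matrix`` under ``model``.

    GLM and SVM machines score the proportionally scaled rows directly;
    SSM machines first pass the rows through the log / subject-mean /
    group-mean-profile centering chain stored in the model.
    """
    if matrix.mask.checksum() != model.mask.checksum():
        raise MaskMismatchError("matrix and model were built on different masks")
    if model.method in _SSM_METHODS:
        gmp = np.asarray(model.extras["gmp"], dtype=np.float64)
        rows = _ssm_center_rows(matrix.values, gmp)
    else:
        if not matrix.scaled:
            raise ModelStateError("scoring requires a proportionally scaled matrix")
        rows = matrix.values
    return rows @ model.pattern + model.bias


def score_subjects(
    model: PatternModel, matrix: VoxelMatrix, designate: bool = True
) -> ScoreTable:
    """Score every subject in ``matrix`` and designate AD / non-AD.

    GLM/SSM machines designate by ``z_score >= z_threshold`` (the threshold
    must have been set by ROC analysis unless ``designate=False``); SVM
    machines designate by the sign of the raw decision value.
    """
    raw = raw_scores(model, matrix)
    if model.ref_mean is None or model.ref_sd is None:
        raise ModelStateError("model has no z-score reference (ref_mean/ref_sd)")
    z = (raw - model.ref_mean) / model.ref_sd
    if model.method in _SVM_METHODS:
        desig = ["AD" if r > 0 else "non-AD" for r in raw]
    elif model.z_threshold is not None:
        desig = ["AD" if zz >= model.z_threshold else "non-AD" for zz in z]
    elif designate:
        raise ModelStateError(
            f"{model.method} model has no z_threshold; run roc_analysis first "
            "or pass designate=False"
        )
    else:
        desig = ["?"] * len(raw)
    return ScoreTable(
        subject_ids=list(matrix.subject_ids),
        raw_score=raw,
        z_score=z,
        designation=desig,
    )


# ---------------------------------------------------------------------------
# serialization: NIfTI pattern map + JSON sidecar


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_model(model: PatternModel, prefix: str | os.PathLike) -> None:
    """Write ``<prefix>_pattern.nii``, ``<prefix>_mask.nii``, ``<prefix>_model.json``
    (and ``<prefix>_gmp.nii`` for SSM machines)."""
    prefix = os.fspath(prefix)
    write_volume(insert_matrix(model.pattern, model.mask), prefix + "_pattern.nii")
    write_mask(model.mask, prefix + "_mask.nii")
    extras = dict(model.extras)
    if "gmp" in extras:
        write_volume(
            insert_matrix(np.asarray(extras.pop("gmp")), model.mask), prefix + "_gmp.nii"
        )
    sidecar = {
        "method": model.method,
        "bias": model.bias,
        "ref_mean": model.ref_mean,
        "ref_sd": model.ref_sd,
        "z_threshold": model.z_threshold,
        "mask_checksum": model.mask.checksum(),
        "mask_source_threshold": model.mask.source_threshold,
        "extras": _jsonable(extras),
    }
    with open(prefix + "_model.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(prefix: str | os.PathLike) -> PatternModel:
    prefix = os.fspath(prefix)
    with open(prefix + "_model.json") as fh:
        sidecar = json.load(fh)
    mask = read_mask(prefix + "_mask.nii", sidecar.get("mask_source_threshold", float("nan")))
    pattern = read_volume(prefix + "_pattern.nii").data[mask.include]
    extras = sidecar.get("extras", {})
    if os.path.exists(prefix + "_gmp.nii"):
        extras["gmp"] = read_volume(prefix + "_gmp.nii").data[mask.include]
    model = PatternModel(
        method=sidecar["method"],
        pattern=pattern,
        bias=float(sidecar["bias"]),
        mask=mask,
        ref_mean=sidecar["ref_mean"],
        ref_sd=sidecar["ref_sd"],
        z_threshold=sidecar["z_threshold"],
        extras=extras,
    )
    if sidecar.get("mask_checksum") and model.mask.checksum() != sidecar["mask_checksum"]:
        raise MaskMismatchError("mask NIfTI does not match sidecar checksum")
    return model
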
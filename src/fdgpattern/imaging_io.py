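"""Volume I/O, whole-brain masking and vectorization.

All classifiers in this package operate on a subjects x voxels matrix
(:class:`VoxelMatrix`) extracted from spatially normalized uptake volumes
under a whole-brain mask.  The mask is built by relative thresholding of
the cohort mean image (default: voxels at or above 25% of the mean image's
maximum), and every image is proportionally scaled to its own in-mask mean
so that global tracer dose and scanner sensitivity drop out.

Voxel linear order is fixed: row-major (C order) over the 3D grid,
restricted to mask-true cells.  Pattern vectors produced by any classifier
are therefore portable across runs that share a mask.

Volumes must already live on a common grid; no resampling or registration
is performed here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .exceptions import (
    DegenerateScanError,
    DimensionError,
    EmptyMaskError,
    LabelError,
    MissingFileError,
    NonFiniteDataError,
    NotNiftiError,
    ShapeMismatchError,
)

__all__ = [
    "BrainVolume",
    "BrainMask",
    "VoxelMatrix",
    "GroupLabel",
    "encode_binary",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "compute_mask",
    "extract_matrix",
    "proportional_scale",
    "insert_matrix",
]

DEFAULT_MASK_THRESHOLD = 0.25

#: group labels understood by the manifest reader
KNOWN_GROUPS = (
    "NL",
    "AD",
    "stable-MCI",
    "prodromal-AD",
    "PDND",
    "PD-MCI",
    "PDD",
    "DLB",
    "FTD",
    "VaD",
)


@dataclass
class BrainVolume:
    """One subject's 3D uptake grid.

    Parameters
    ----------
    data
        3D array of uptake values (arbitrary tracer units).
    spacing
        Voxel edge lengths in mm, one per axis, strictly positive.
    subject_id
        Identifier carried through score tables.
    modality
        One of ``FDG-PET``, ``perfusion-SPECT`` or ``synthetic``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    modality: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionError(
                f"volume must be 3D with all dims >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ShapeMismatchError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise NonFiniteDataError(f"volume '{self.subject_id}' contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BrainMask:
    """Boolean analysis mask on the common grid."""

    include: np.ndarray
    source_threshold: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 3:
            raise DimensionError("mask grid must be 3D")
        if self.n_voxels < 1:
            raise EmptyMaskError("mask selects zero voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.include.shape

    def checksum(self) -> str:
        """Hex digest identifying the grid and the voxel set (order included)."""
        import hashlib

        h = hashlib.sha256()
        h.update(str(self.shape).encode())
        h.update(np.packbits(self.include.ravel(order="C")).tobytes())
        return h.hexdigest()[:16]


@dataclass
class GroupLabel:
    """A diagnostic group label with its 0/1 code for a two-group fit.

    ``binary_code`` is 1 for the "disease" class (scores oriented so higher
    means more AD-like) and 0 for the reference class.
    """

    value: str
    binary_code: int

    def __post_init__(self) -> None:
        if self.binary_code not in (0, 1):
            raise LabelError(f"binary_code must be 0 or 1, got {self.binary_code}")


def encode_binary(labels: list[str], positive: str | None = None) -> np.ndarray:
    """Map a two-group label list to a 0/1 dummy vector.

    The positive (code 1) group is ``positive`` if given; otherwise, when one
    of the two groups is ``NL``, the other group is positive.  Raises
    :class:`LabelError` when the coding is ambiguous or not two-group.
    """
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise LabelError(f"exactly two distinct groups required, got {uniq}")
    if positive is None:
        if "NL" in uniq:
            positive = uniq[0] if uniq[1] == "NL" else uniq[1]
        else:
            raise LabelError(
                f"cannot infer disease group from {uniq}; pass positive= explicitly"
            )
    if positive not in uniq:
        raise LabelError(f"positive group {positive!r} not among {uniq}")
    return np.asarray([1 if lab == positive else 0 for lab in labels], dtype=np.int64)


@dataclass
class VoxelMatrix:
    """Subjects x in-mask-voxels matrix — the common currency of all classifiers."""

    values: np.ndarray
    subject_ids: list[str]
    labels: list[str]
    mask: BrainMask
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, v = self.values.shape
        if n != len(self.subject_ids) or n != len(self.labels):
            raise LabelError(
                f"{n} rows vs {len(self.subject_ids)} ids / {len(self.labels)} labels"
            )
        if v != self.mask.n_voxels:
            raise ShapeMismatchError(
                f"{v} columns but mask has {self.mask.n_voxels} voxels"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def read_volume(path: str | os.PathLike) -> BrainVolume:
    """Load a NIfTI-1/NIfTI-2 volume.

    4D files with a singleton 4th dimension are squeezed to 3D.  Raises
    distinct errors for a missing file, a non-NIfTI payload, non-finite
    voxels, and more than 3 non-singleton dimensions.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MissingFileError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise NotNiftiError(f"not a readable NIfTI volume: {path} ({exc})") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if sum(1 for d in data.shape if d > 1) > 3:
        raise DimensionError(f"{path}: more than 3 non-singleton dimensions {data.shape}")
    if data.ndim > 3:
        data = data.squeeze()
        while data.ndim < 3:  # keep singleton spatial axes
            data = data[..., None]
    if not np.isfinite(data).all():
        raise NonFiniteDataError(f"{path}: volume contains non-finite voxels")
    zooms = img.header.get_zooms()[:3]
    sid = os.path.basename(path)
    for suffix in (".nii.gz", ".nii"):
        if sid.endswith(suffix):
            sid = sid[: -len(suffix)]
    return BrainVolume(data=data, spacing=tuple(float(z) for z in zooms), subject_id=sid)


def write_volume(volume: BrainVolume, path: str | os.PathLike) -> None:
    """Write a volume as float64 NIfTI-1 (bit-exact round trip)."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, os.fspath(path))


def write_mask(mask: BrainMask, path: str | os.PathLike) -> None:
    """Write a mask as a 0/1 uint8 NIfTI."""
    img = nib.Nifti1Image(mask.include.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, os.fspath(path))


def read_mask(path: str | os.PathLike, source_threshold: float = float("nan")) -> BrainMask:
    vol = read_volume(path)
    return BrainMask(include=vol.data > 0.5, source_threshold=source_threshold,
                     spacing=vol.spacing)


def compute_mask(
    volumes: list[BrainVolume], rel_threshold: float = DEFAULT_MASK_THRESHOLD
) -> BrainMask:
    """Whole-brain mask by relative thresholding of the cohort mean image.

    A voxel is included iff ``mean >= rel_threshold * max(mean)`` where
    ``mean`` is the voxel-wise average over ``volumes``.  The mean image
    (rather than any single scan) is used so single-scan artifacts cannot
    carve holes in the mask.
    """
    if not volumes:
        raise LabelError("compute_mask needs at least one volume")
    if not 0 < rel_threshold < 1:
        raise ShapeMismatchError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    shape = volumes[0].shape
    for v in volumes:
        if v.shape != shape:
            raise ShapeMismatchError(f"grid mismatch: {v.shape} vs {shape}")
    mean = np.zeros(shape, dtype=np.float64)
    for v in volumes:
        mean += v.data
    mean /= len(volumes)
    include = mean >= rel_threshold * mean.max()
    if not include.any():
        raise EmptyMaskError("relative threshold excluded every voxel")
    return BrainMask(include=include, source_threshold=float(rel_threshold),
                     spacing=volumes[0].spacing)


def extract_matrix(
    volumes: list[BrainVolume], mask: BrainMask, labels: list[str]
) -> VoxelMatrix:
    """Vectorize a cohort: row i holds volume i's in-mask voxels, C order."""
    if len(volumes) != len(labels):
        raise LabelError(f"{len(volumes)} volumes but {len(labels)} labels")
    for v in volumes:
        if v.shape != mask.shape:
            raise ShapeMismatchError(f"volume grid {v.shape} != mask grid {mask.shape}")
    values = np.empty((len(volumes), mask.n_voxels), dtype=np.float64)
    for i, v in enumerate(volumes):
        values[i] = v.data[mask.include]  # boolean indexing is row-major
    return VoxelMatrix(
        values=values,
        subject_ids=[v.subject_id for v in volumes],
        labels=list(labels),
        mask=mask,
        scaled=False,
    )


def proportional_scale(matrix: VoxelMatrix) -> VoxelMatrix:
    """Divide each row by its own in-mask mean (global-value normalization).

    Idempotent: scaling an already row-mean-1 matrix is a no-op up to
    floating point.  Refuses matrices flagged as scaled and rows whose mean
    is not strictly positive.
    """
    if matrix.scaled:
        raise DegenerateScanError("matrix is already proportionally scaled")
    means = matrix.values.mean(axis=1)
    bad = np.nonzero(means <= 0)[0]
    if bad.size:
        sid = matrix.subject_ids[bad[0]]
        raise DegenerateScanError(
            f"subject '{sid}' has non-positive in-mask mean ({means[bad[0]]:g})"
        )
    return replace(matrix, values=matrix.values / means[:, None], scaled=True)


def insert_matrix(row: np.ndarray, mask: BrainMask) -> BrainVolume:
    """Put a pattern vector back on the grid; out-of-mask voxels are 0."""
    row = np.asarray(row, dtype=np.float64).ravel()
    if row.size != mask.n_voxels:
        raise ShapeMismatchError(f"row length {row.size} != mask n_voxels {mask.n_voxels}")
    data = np.zeros(mask.shape, dtype=np.float64)
    data[mask.include] = row
    return BrainVolume(data=data, spacing=mask.spacing, subject_id="pattern")
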
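"""Shared fixtures: phantom cohorts and matrix builders.

The default phantom (32^3 grid, 40 NL / 40 AD, planted effect d = 1.5,
seed 1) is expensive enough to share session-wide; smaller cohorts are
built per test.
"""

import warnings

import numpy as np
import pytest

import fdgpattern as fp

# ISDA with the tolerance-0 (epsilon-floored) setting legitimately hits the
# iteration cap on collinear image matrices; the warning is expected there.
warnings.filterwarnings("ignore", message=r"ISDA hit max_iterations")


def make_matrix(values, labels, scaled=True, subject_ids=None):
    """Wrap a plain 2D array as a VoxelMatrix with a trivial line mask."""
    values = np.asarray(values, dtype=np.float64)
    mask = fp.BrainMask(
        include=np.ones((values.shape[1], 1, 1), dtype=bool), source_threshold=0.25
    )
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(values.shape[0])]
    return fp.VoxelMatrix(
        values=values, subject_ids=subject_ids, labels=list(labels),
        mask=mask, scaled=scaled,
    )


def two_group_labels(n0, n1, g0="NL", g1="AD"):
    return [g0] * n0 + [g1] * n1


@pytest.fixture(scope="session")
def default_phantom():
    """The default study cohort: 32^3 grid, 40/40, d = 1.5, seed 1."""
    spec = fp.SyntheticCohortSpec(seed=1)
    volumes, manifest, truth = fp.generate_cohort(spec)
    return spec, volumes, manifest, truth


@pytest.fixture(scope="session")
def default_matrix(default_phantom):
    """Mask + proportionally scaled matrix of the default phantom."""
    _spec, volumes, manifest, _truth = default_phantom
    mask = fp.compute_mask(volumes)
    labels = [str(g) for g in manifest["group"]]
    matrix = fp.proportional_scale(fp.extract_matrix(volumes, mask, labels))
    return mask, matrix


@pytest.fixture(scope="session")
def default_ssm1(default_matrix):
    _mask, matrix = default_matrix
    decomp = fp.ssm_svd(fp.log_double_center(matrix), k=10)
    model = fp.select_best_pc(decomp, matrix)
    return decomp, model, matrix


@pytest.fixture()
def small_cohort():
    """Fast cohort for CLI / plumbing tests: 16^3 grid, 10/10, strong effect."""
    spec = fp.SyntheticCohortSpec(
        shape=(16, 16, 16), spacing=(8.0, 8.0, 8.0),
        n_per_group={"NL": 10, "AD": 10}, effect_size=3.0, seed=5,
    )
    volumes, manifest, truth = fp.generate_cohort(spec)
    return spec, volumes, manifest, truth
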
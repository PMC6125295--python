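"""Scaled subprofile model: centering, SVD, PC selection, prospective scoring."""

import numpy as np
import pytest

import fdgpattern as fp
from fdgpattern.exceptions import ModelStateError, NonPositiveValueError

from conftest import make_matrix, two_group_labels


def random_positive_matrix(seed, n=12, v=30):
    rng = np.random.default_rng(seed)
    return make_matrix(
        rng.gamma(4.0, 2.0, (n, v)) + 0.5, two_group_labels(n // 2, n - n // 2)
    )


class TestLogDoubleCenter:
    def test_analytic_two_by_two(self):
        e = np.e
        mat = make_matrix([[e, e**3], [e**3, e**5]], ["NL", "AD"])
        decomp = fp.log_double_center(mat)
        np.testing.assert_allclose(decomp.centered, 0.0, atol=1e-12)
        np.testing.assert_allclose(decomp.gmp, [-1.0, 1.0], atol=1e-12)

    def test_constant_matrix_centers_to_zero(self):
        mat = make_matrix(np.full((3, 4), 7.0), ["NL", "NL", "AD"])
        np.testing.assert_allclose(fp.log_double_center(mat).centered, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_both_margins_vanish(self, seed):
        decomp = fp.log_double_center(random_positive_matrix(seed))
        assert np.abs(decomp.centered.mean(axis=1)).max() < 1e-12
        assert np.abs(decomp.centered.mean(axis=0)).max() < 1e-12

    def test_non_positive_value_is_rejected(self):
        mat = make_matrix([[1.0, 0.0], [1.0, 2.0]], ["NL", "AD"])
        with pytest.raises(NonPositiveValueError):
            fp.log_double_center(mat)


class TestSvd:
    def test_rank_one_matrix_recovers_direction(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=8)
        u -= u.mean()
        v = rng.normal(size=20)
        v -= v.mean()
        centered = np.outer(u, v)
        decomp = fp.ssm_svd(fp.SsmDecomposition(centered=centered, gmp=np.zeros(20)), k=1)
        direction = v / np.linalg.norm(v)
        assert abs(abs(decomp.pcs[0] @ direction) - 1.0) < 1e-10
        assert decomp.vaf[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(30)
        mat = make_matrix(rng.gamma(4.0, 2.0, (30, 100)) + 0.5,
                          two_group_labels(15, 15))
        decomp = fp.ssm_svd(fp.log_double_center(mat), k=10)
        cov = decomp.centered.T @ decomp.centered
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for j in range(10):
            ev = evecs[:, order[j]]
            assert min(
                np.abs(decomp.pcs[j] - ev).max(), np.abs(decomp.pcs[j] + ev).max()
            ) < 1e-8

    def test_orthonormality_and_vaf(self):
        decomp = fp.ssm_svd(fp.log_double_center(random_positive_matrix(5)), k=5)
        gram = decomp.pcs @ decomp.pcs.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        cross = decomp.subject_scores.T @ decomp.subject_scores
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(cross)).max()
        assert (np.diff(decomp.vaf) <= 1e-12).all()
        assert decomp.vaf.sum() <= 1.0 + 1e-12

    def test_k_too_large(self):
        decomp = fp.log_double_center(random_positive_matrix(1, n=5, v=9))
        with pytest.raises(ModelStateError):
            fp.ssm_svd(decomp, k=7)


def synthetic_decomposition(score_cols, seed=0, v=40):
    """Build a decomposition with prescribed subject-score columns and random
    orthonormal voxel loadings, so centered = scores @ pcs."""
    rng = np.random.default_rng(seed)
    k = score_cols.shape[1]
    pcs, _ = np.linalg.qr(rng.normal(size=(v, k)))
    pcs = pcs.T
    centered = score_cols @ pcs
    return fp.SsmDecomposition(
        centered=centered, gmp=np.zeros(v), pcs=pcs,
        subject_scores=score_cols.astype(float),
        singular_values=np.linalg.norm(score_cols, axis=0),
        vaf=np.full(k, 1.0 / k),
    )


class TestSelectBestPc:
    def test_selects_the_only_discriminating_pc(self):
        rng = np.random.default_rng(6)
        n = 20
        labels = two_group_labels(10, 10)
        scores = rng.normal(size=(n, 4))
        scores[:, 1] += 4.0 * np.asarray(fp.encode_binary(labels))
        decomp = synthetic_decomposition(scores)
        matrix = make_matrix(np.ones((n, 40)), labels)
        model = fp.select_best_pc(decomp, matrix)
        assert model.extras["selected_pcs"] == [1]

    def test_tie_break_goes_to_lowest_index(self):
        labels = two_group_labels(4, 4)
        x = np.asarray(fp.encode_binary(labels), dtype=float)
        base = x - x.mean() + np.array([0.1, -0.1, 0.2, -0.2, 0.1, -0.1, 0.2, -0.2])
        scores = np.column_stack([base, -base])  # identical |t| by symmetry
        decomp = synthetic_decomposition(scores)
        matrix = make_matrix(np.ones((8, 40)), labels)
        model = fp.select_best_pc(decomp, matrix)
        assert model.extras["selected_pcs"] == [0]

    def test_disease_positive_orientation(self, default_ssm1):
        decomp, model, matrix = default_ssm1
        codes = np.asarray(fp.encode_binary(matrix.labels))
        raw = fp.score_subjects(model, matrix, designate=False).raw_score
        assert raw[codes == 1].mean() > raw[codes == 0].mean()


class TestStepwise:
    def test_informative_pc_is_reliably_retained(self):
        retained_inform = 0
        spurious = 0
        n_rep = 100
        labels = two_group_labels(20, 20)
        x = np.asarray(fp.encode_binary(labels), dtype=float)
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            scores = rng.standard_normal((40, 10))
            scores[:, 0] += 1.5 * x
            decomp = synthetic_decomposition(scores, seed=rep, v=60)
            matrix = make_matrix(np.ones((40, 60)), labels)
            model = fp.stepwise_combine(decomp, matrix)
            sel = model.extras["selected_pcs"]
            retained_inform += int(0 in sel)
            spurious += len([j for j in sel if j != 0])
        assert retained_inform >= 95
        assert spurious / n_rep < 1.0  # noise entry stays near the nominal rate

    def test_label_orthogonal_scores_fall_back_with_warning(self):
        labels = two_group_labels(6, 6)
        x = np.asarray(fp.encode_binary(labels), dtype=float)
        xc = x - x.mean()
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((12, 3))
        # project the label direction out of every score column: nothing can enter
        scores -= np.outer(xc, xc @ scores) / (xc @ xc)
        decomp = synthetic_decomposition(scores)
        matrix = make_matrix(np.ones((12, 40)), labels)
        with pytest.warns(UserWarning, match="falling back"):
            model = fp.stepwise_combine(decomp, matrix)
        assert model.method == "SSM2"
        assert len(model.extras["selected_pcs"]) == 1

    def test_combination_report_format(self):
        mask = make_matrix(np.ones((2, 3)), ["NL", "AD"]).mask
        model = fp.PatternModel(
            method="SSM2", pattern=np.zeros(3), bias=0.0, mask=mask,
            ref_mean=0.0, ref_sd=1.0,
            extras={"selected_pcs": [0, 2, 3], "weights": [4.204, 1.126, -1.825]},
        )
        report = fp.combination_report(model)
        assert report == "4.204 × PC1 + 1.126 × PC3 − 1.825 × PC4"


class TestProspective:
    def test_training_scores_reproduced_exactly(self, default_ssm1):
        decomp, model, matrix = default_ssm1
        j = model.extras["selected_pcs"][0]
        sign = 1.0 if model.extras["weights"][0] > 0 else -1.0
        svd_scores = sign * decomp.subject_scores[:, j]
        table = fp.prospective_score(model, matrix, designate=False)
        assert np.abs(table.raw_score - svd_scores).max() < 1e-8

    def test_gmp_scan_scores_zero(self, default_ssm1):
        _decomp, model, matrix = default_ssm1
        gmp = model.extras["gmp"]
        scan = np.exp(gmp + 3.0)[None, :]
        new = make_matrix(scan, ["NL"])
        new.mask = matrix.mask
        table = fp.prospective_score(model, new, designate=False)
        assert abs(table.raw_score[0]) < 1e-8

    def test_global_scaling_invariance(self, default_ssm1):
        _decomp, model, matrix = default_ssm1
        scaled = make_matrix(matrix.values * 3.7, matrix.labels)
        scaled.mask = matrix.mask
        a = fp.prospective_score(model, matrix, designate=False).raw_score
        b = fp.prospective_score(model, scaled, designate=False).raw_score
        assert np.abs(a - b).max() < 1e-9

    def test_glm_model_is_rejected(self, default_matrix):
        _mask, matrix = default_matrix
        glm = fp.fit_glm_pattern(matrix)
        with pytest.raises(ModelStateError):
            fp.prospective_score(glm, matrix)
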
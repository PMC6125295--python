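"""ISDA and SMO dual solvers: closed forms, QP oracles, solver invariants."""

import numpy as np
import pytest
from scipy.optimize import minimize

import fdgpattern as fp
from fdgpattern.exceptions import ConfigError, ModelStateError
from fdgpattern.svm_linear import DualState, dual_objective

from conftest import make_matrix


def toy_problem(seed, n=30, sep=0.8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    X[y > 0] += sep
    labels = ["AD" if t > 0 else "NL" for t in y]
    return X, y, labels


def qp_box_dual(K, y, C):
    """Generic convex-QP oracle for the box-constrained (ISDA-form) dual."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        method="L-BFGS-B",
        bounds=[(0.0, C)] * n,
        options={"ftol": 1e-16, "gtol": 1e-14, "maxiter": 50000},
    )
    return res.x


def qp_equality_dual(K, y, C):
    """Generic convex-QP oracle for the equality-constrained (SMO-form) dual."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.full(n, min(C, 1.0) * 0.5),
        jac=lambda a: Q @ a - 1.0,
        method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        options={"ftol": 1e-14, "maxiter": 2000},
    )
    return res.x


class TestClosedForms:
    def test_two_point_maximal_margin_smo(self):
        m = make_matrix([[1.0, 0.0], [-1.0, 0.0]], ["AD", "NL"])
        cfg = fp.SvmConfig(solver="SMO", C=10.0, outlier_fraction=0.0)
        model = fp.train_svm(m, cfg)
        np.testing.assert_allclose(model.pattern, [1.0, 0.0], atol=1e-8)
        assert abs(model.bias) < 1e-8
        np.testing.assert_allclose(model.extras["alphas"], [0.5, 0.5], atol=1e-8)

    def test_two_point_maximal_margin_isda(self):
        m = make_matrix([[1.0, 0.0], [-1.0, 0.0]], ["AD", "NL"])
        cfg = fp.SvmConfig(solver="ISDA", C=10.0, outlier_fraction=0.0)
        model = fp.train_svm(m, cfg)
        np.testing.assert_allclose(model.pattern, [1.0, 0.0], atol=1e-8)
        assert abs(model.bias) < 1e-8

    def test_one_subject_isda_closed_form(self):
        K = np.array([[1.1]])
        state = DualState(K=K, y=np.array([1.0]), C=0.5)
        state = fp.isda_step(state, 0)
        assert state.alphas[0] == pytest.approx(min(0.5, 1 / 1.1))
        # with a large box the unconstrained optimum is reached instead
        state = DualState(K=K, y=np.array([1.0]), C=10.0)
        state = fp.isda_step(state, 0)
        assert state.alphas[0] == pytest.approx(1 / 1.1)


class TestStepInvariants:
    def test_isda_fixed_point_and_monotone_objective(self):
        X, y, _ = toy_problem(3, n=20)
        K = X @ X.T + 0.1
        state = DualState(K=K, y=y, C=1.0)
        prev = dual_objective(state)
        for sweep in range(50):
            for i in range(20):
                state = fp.isda_step(state, i)
                cur = dual_objective(state)
                assert cur >= prev - 1e-12
                prev = cur
        # converged: another step is a fixed point
        alphas = state.alphas.copy()
        state = fp.isda_step(state, 0)
        np.testing.assert_allclose(state.alphas, alphas, atol=1e-12)

    def test_smo_preserves_equality_and_objective(self):
        X, y, _ = toy_problem(4, n=24)
        K = X @ X.T
        state = DualState(K=K, y=y, C=1.0)
        prev = dual_objective(state)
        converged = False
        for _ in range(5000):
            state, converged = fp.smo_step(state, tol=1e-10)
            if converged:
                break
            assert abs(state.alphas @ state.y) < 1e-8
            cur = dual_objective(state)
            assert cur >= prev - 1e-12
            prev = cur
        assert converged
        state2, flag = fp.smo_step(state, tol=1e-10)
        assert flag  # already-optimal state reports convergence

    def test_two_point_solved_in_one_pair_step(self):
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        state = DualState(K=K, y=np.array([1.0, -1.0]), C=10.0)
        state, converged = fp.smo_step(state, tol=1e-10)
        assert not converged
        np.testing.assert_allclose(state.alphas, [0.5, 0.5], atol=1e-12)


class TestAgainstOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_isda_matches_box_qp(self, seed):
        X, y, labels = toy_problem(seed)
        m = make_matrix(X, labels)
        cfg = fp.SvmConfig(solver="ISDA", C=1.0, outlier_fraction=0.0)
        model = fp.train_svm(m, cfg)
        a = qp_box_dual(X @ X.T + 0.1, y, 1.0)
        w = (a * y) @ X
        b = 0.1 * (a * y).sum()
        np.testing.assert_allclose(
            X @ model.pattern + model.bias, X @ w + b, atol=1e-4
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_smo_matches_equality_qp_and_sklearn(self, seed):
        X, y, labels = toy_problem(seed)
        m = make_matrix(X, labels)
        cfg = fp.SvmConfig(solver="SMO", C=1.0, outlier_fraction=0.0,
                           kkt_tolerance=1e-8)
        model = fp.train_svm(m, cfg)
        ours = X @ model.pattern + model.bias

        a = qp_equality_dual(X @ X.T, y, 1.0)
        w = (a * y) @ X
        free = (a > 1e-6) & (a < 1.0 - 1e-6)
        b = float(np.mean(y[free] - X[free] @ w))
        np.testing.assert_allclose(ours, X @ w + b, atol=1e-4)

        sklearn = pytest.importorskip("sklearn.svm")
        sk = sklearn.SVC(kernel="linear", C=1.0, tol=1e-10).fit(X, y)
        np.testing.assert_allclose(ours, sk.decision_function(X), atol=1e-4)

    def test_cross_solver_designation_agreement_on_separable_phantom(self):
        # a widely separated phantom cohort: both solvers must designate
        # 100 held-out subjects identically
        spec = fp.SyntheticCohortSpec(
            shape=(12, 12, 12), spacing=(8.0, 8.0, 8.0),
            n_per_group={"NL": 10, "AD": 10}, effect_size=8.0,
            noise_sd=0.01, seed=6,
        )
        volumes, manifest, _ = fp.generate_cohort(spec)
        mask = fp.compute_mask(volumes)
        train = fp.proportional_scale(
            fp.extract_matrix(volumes, mask, list(manifest["group"]))
        )
        held = fp.SyntheticCohortSpec(
            shape=(12, 12, 12), spacing=(8.0, 8.0, 8.0),
            n_per_group={"NL": 50, "AD": 50}, effect_size=8.0,
            noise_sd=0.01, seed=61,
        )
        volumes_te, manifest_te, _ = fp.generate_cohort(held)
        te = fp.proportional_scale(
            fp.extract_matrix(volumes_te, mask, list(manifest_te["group"]))
        )
        designations = {}
        for solver in ("ISDA", "SMO"):
            cfg = fp.SvmConfig(solver=solver, outlier_fraction=0.0)
            model = fp.train_svm(train, cfg)
            designations[solver] = fp.score_subjects(model, te).designation
        assert designations["ISDA"] == designations["SMO"]
        # and both recover the planted group structure exactly
        assert designations["SMO"] == ["non-AD"] * 50 + ["AD"] * 50


class TestTrainedModelInvariants:
    @pytest.mark.parametrize("solver", ["ISDA", "SMO"])
    def test_dual_feasibility_and_reconstruction(self, solver):
        X, y, labels = toy_problem(11, n=40)
        m = make_matrix(X, labels)
        cfg = fp.SvmConfig(solver=solver, C=2.0, outlier_fraction=0.0,
                           kkt_tolerance=None if solver == "ISDA" else 1e-8)
        model = fp.train_svm(m, cfg)
        a = model.extras["alphas"]
        assert (a >= -1e-12).all() and (a <= 2.0 + 1e-12).all()
        if solver == "SMO":
            assert abs((a * y).sum()) < 1e-8
        w = (a * y) @ X
        np.testing.assert_allclose(model.pattern, w, atol=1e-8)
        assert model.extras["final_kkt_violation"] <= 1e-6

    def test_robust_learning_removes_planted_outlier(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 2))
        y = np.where(np.arange(40) < 20, 1.0, -1.0)
        X[y > 0, 0] += 4.0
        X[0] = [-4.0, 0.0]  # an AD subject deep inside NL territory
        labels = ["AD" if t > 0 else "NL" for t in y]
        m = make_matrix(X, labels)
        cfg = fp.SvmConfig(solver="SMO", outlier_fraction=0.05)
        model = fp.train_svm(m, cfg)
        assert len(model.extras["removed_outliers"]) == 2  # ceil(0.05 * 40)
        assert "s000" in model.extras["removed_outliers"]

    def test_scale_behaviour(self):
        X, y, labels = toy_problem(13, n=20, sep=3.0)
        m1 = make_matrix(X, labels)
        m2 = make_matrix(2.0 * X, labels)
        signs = {}
        for name, m, C in (("base", m1, 1.0), ("scaled", m2, 0.25)):
            cfg = fp.SvmConfig(solver="SMO", C=C, outlier_fraction=0.0)
            model = fp.train_svm(m, cfg)
            raw = fp.score_subjects(model, m).raw_score
            signs[name] = np.sign(raw)
        np.testing.assert_array_equal(signs["base"], signs["scaled"])

    def test_degenerate_identical_rows(self):
        m = make_matrix(np.ones((6, 3)), ["NL"] * 3 + ["AD"] * 3)
        with pytest.raises(ModelStateError):
            fp.train_svm(m, fp.SvmConfig())

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            fp.SvmConfig(solver="PEGASOS")
        with pytest.raises(ConfigError):
            fp.SvmConfig(C=-1.0)
        with pytest.raises(ConfigError):
            fp.SvmConfig(outlier_fraction=0.6)
        cfg = fp.SvmConfig(solver="SMO")
        assert cfg.kkt_tolerance == 0.001 and cfg.kernel_offset == 0.0
        cfg = fp.SvmConfig(solver="ISDA")
        assert cfg.kkt_tolerance == 0.0 and cfg.kernel_offset == 0.1
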
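"""Radius-margin SVM with learned PSD metric."""

import numpy as np
import pytest
from sklearn.svm import SVC

from alcoeeg import fsvm
from alcoeeg.fsvm import (
    FSVMConfig,
    fit_fsvm,
    fsvm_objective,
    grad_K,
    init_K,
    kernel_pca_embed,
    predict,
    project_psd,
    rbf_kernel,
    scatter_matrix,
    solve_svm_given_K,
)


def _two_moons(n=40, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, np.pi, n // 2)
    a = np.c_[np.cos(t), np.sin(t)] + rng.normal(0, noise, (n // 2, 2))
    b = np.c_[1 - np.cos(t), 0.5 - np.sin(t)] + rng.normal(0, noise, (n // 2, 2))
    X = np.vstack([a, b])
    y = np.r_[np.ones(n // 2), -np.ones(n // 2)].astype(int)
    return X, y


class TestRbfKernel:
    def test_self_similarity_one(self):
        X = np.array([[1.0, 2.0]])
        np.testing.assert_allclose(rbf_kernel(X, X, 0.5), [[1.0]])

    def test_unit_distance_value(self):
        np.testing.assert_allclose(
            rbf_kernel(np.array([[0.0]]), np.array([[1.0]]), 1.0), [[np.exp(-1)]]
        )

    def test_symmetric_psd_on_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(rng.integers(3, 12), 3))
            K = rbf_kernel(X, X, rng.uniform(0.1, 3))
            np.testing.assert_allclose(K, K.T, atol=1e-12)
            assert np.linalg.eigvalsh(K).min() >= -1e-8
            assert K.max() <= 1.0 and K.min() > 0.0


class TestKernelPcaEmbed:
    def test_full_ratio_reconstructs_centered_kernel(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        emb, Z = kernel_pca_embed(X, gamma=0.7, ratio=1.0)
        K = rbf_kernel(X, X, 0.7)
        rm = K.mean(axis=0)
        Kc = K - rm[None, :] - rm[:, None] + K.mean()
        np.testing.assert_allclose(Z @ Z.T, Kc, atol=1e-8)

    def test_two_points_single_dimension(self):
        emb, Z = kernel_pca_embed(np.array([[0.0], [1.0]]), gamma=1.0, ratio=0.9)
        assert emb.G == 1

    def test_transform_self_consistency(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4))
        emb, Z = kernel_pca_embed(X, gamma=0.3, ratio=0.95)
        np.testing.assert_allclose(emb.transform(X), Z, atol=1e-8)

    def test_ratio_controls_dimension(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        g_small = kernel_pca_embed(X, 0.5, ratio=0.5)[0].G
        g_large = kernel_pca_embed(X, 0.5, ratio=0.999)[0].G
        assert g_small <= g_large

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError):
            kernel_pca_embed(np.ones((5, 2)), gamma=1.0)


class TestScatterMatrix:
    def test_identical_points_zero(self):
        np.testing.assert_allclose(scatter_matrix(np.ones((6, 3))), 0.0, atol=1e-15)

    def test_matches_covariance_oracle(self):
        from alcoeeg.coveig import covariance_matrix

        rng = np.random.default_rng(4)
        Z = rng.normal(size=(20, 4))
        np.testing.assert_allclose(scatter_matrix(Z), covariance_matrix(Z), atol=1e-12)

    def test_trace_is_total_variance(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(25, 3))
        np.testing.assert_allclose(
            np.trace(scatter_matrix(Z)), np.var(Z, axis=0, ddof=1).sum(), rtol=1e-10
        )


class TestInitK:
    def test_identity_fixed_point(self):
        K0, A0 = init_K(np.eye(4))
        np.testing.assert_allclose(K0, np.eye(4), atol=1e-10)

    def test_hand_value_diag(self):
        K0, _ = init_K(np.diag([4.0, 1.0]))
        np.testing.assert_allclose(K0, np.diag([0.5, 1.0]), atol=1e-10)

    def test_transform_factorization(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            B = rng.normal(size=(5, 5))
            N = B @ B.T
            K0, A0 = init_K(N)
            np.testing.assert_allclose(A0.T @ A0, K0, atol=1e-10)

    def test_singular_scatter_still_invertible(self):
        N = np.diag([1.0, 0.0])
        K0, _ = init_K(N, eps_psd=1e-8)
        assert np.isfinite(np.linalg.inv(K0)).all()


class TestSolveSvmGivenK:
    def test_identity_K_reduces_to_linear_svm(self):
        X, y = _two_moons(seed=7)
        w, b, delta = solve_svm_given_K(X, y, np.eye(2), Zparam=5.0)
        ref = SVC(kernel="linear", C=5.0, tol=1e-8).fit(X, y)
        ours = X @ w + b
        theirs = ref.decision_function(X)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_separable_toy_zero_slack(self):
        # margin-2 construction: classes at x = +-1 along the first axis
        X = np.array([[1.0, 0.0], [1.0, 1.0], [-1.0, 0.0], [-1.0, 1.0]])
        y = np.array([1, 1, -1, -1])
        w, b, delta = solve_svm_given_K(X, y, np.eye(2), Zparam=1e4)
        np.testing.assert_allclose(delta, 0.0, atol=1e-6)
        assert np.all(np.sign(X @ w + b) == y)

    def test_scaling_K_preserves_separable_boundary(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [-1.0, 0.0], [-1.0, 1.0]])
        y = np.array([1, 1, -1, -1])
        w1, b1, _ = solve_svm_given_K(X, y, np.eye(2), Zparam=1e4)
        w2, b2, _ = solve_svm_given_K(X, y, 4.0 * np.eye(2), Zparam=1e4)
        d1, d2 = X @ w1 + b1, X @ w2 + b2
        np.testing.assert_allclose(np.sign(d1), np.sign(d2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            solve_svm_given_K(np.zeros((4, 2)), np.ones(4), np.eye(2), 1.0)


class TestObjectiveAndGradient:
    def test_zero_everything(self):
        val = fsvm_objective(np.eye(2), np.zeros(2), np.zeros(3), 1.0, 1.0,
                             np.zeros((2, 2)))
        np.testing.assert_allclose(val, 0.0, atol=1e-12)

    def test_hand_value(self):
        val = fsvm_objective(np.eye(2), np.array([1.0, 0.0]), np.array([0.0]),
                             1.0, 1.0, np.eye(2))
        np.testing.assert_allclose(val, 2.5)

    def test_grad_zero_w(self):
        N = np.diag([1.0, 2.0])
        np.testing.assert_allclose(grad_K(np.eye(2), np.zeros(2), 0.3, N), 0.3 * N)

    def test_grad_identity_K_no_radius(self):
        w = np.array([2.0, -1.0])
        np.testing.assert_allclose(
            grad_K(np.eye(2), w, 1.0, np.zeros((2, 2))), -0.5 * np.outer(w, w)
        )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        h = 1e-6
        for _ in range(50):
            G = int(rng.integers(2, 7))
            A = rng.normal(size=(G, G))
            K = A @ A.T + 0.5 * np.eye(G)
            w = rng.normal(size=G)
            B = rng.normal(size=(G, G))
            N = B @ B.T / G
            rho = rng.uniform(0.01, 1.0)
            g = grad_K(K, w, rho, N)
            fd = np.zeros_like(K)
            for i in range(G):
                for j in range(G):
                    Kp, Km = K.copy(), K.copy()
                    Kp[i, j] += h
                    Km[i, j] -= h
                    fd[i, j] = (
                        fsvm_objective(Kp, w, [0.0], 1.0, rho, N)
                        - fsvm_objective(Km, w, [0.0], 1.0, rho, N)
                    ) / (2 * h)
            fd = (fd + fd.T) / 2
            assert np.linalg.norm(fd - g) / np.linalg.norm(g) <= 1e-5


class TestProjectPsd:
    def test_idempotent_on_psd(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(4, 4))
        M = A @ A.T + 1e-3 * np.eye(4)
        np.testing.assert_allclose(project_psd(M, 1e-8), M, atol=1e-10)

    def test_clips_negative_eigenvalue(self):
        out = project_psd(np.diag([2.0, -1.0]), eps=1e-8)
        np.testing.assert_allclose(out, np.diag([2.0, 1e-8]))

    def test_projection_optimality(self):
        # variational characterization: <M - P, Q - P> <= 0 for any PSD Q
        # with eigenvalues >= eps, so P is the Frobenius-nearest such matrix
        rng = np.random.default_rng(10)
        for _ in range(30):
            M = rng.normal(size=(4, 4))
            M = (M + M.T) / 2
            P = project_psd(M, eps=1e-8)
            for _ in range(10):
                B = rng.normal(size=(4, 4))
                Q = B @ B.T + 1e-8 * np.eye(4)
                assert np.sum((M - P) * (Q - P)) <= 1e-8

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            project_psd(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestFitAndPredict:
    def test_separable_two_moons_training_accuracy(self):
        X, y = _two_moons(seed=11)
        model = fit_fsvm(X, y, FSVMConfig(Z=10.0, gamma=1.0))
        assert np.mean(predict(model, X) == y) == 1.0

    def test_objective_trace_non_increasing(self):
        X, y = _two_moons(seed=12, noise=0.3)
        model = fit_fsvm(X, y, FSVMConfig(Z=2.0, gamma=0.8))
        tr = np.asarray(model.objective_trace)
        assert np.all(np.diff(tr) <= 1e-10)

    def test_K_stays_psd(self):
        X, y = _two_moons(seed=13, noise=0.2)
        model = fit_fsvm(X, y, FSVMConfig(Z=1.0, gamma=0.5))
        vals = np.linalg.eigvalsh((model.K + model.K.T) / 2)
        assert vals.min() >= 0.5 * model.config.eps_psd

    def test_determinism(self):
        X, y = _two_moons(seed=14)
        m1 = fit_fsvm(X, y, FSVMConfig(Z=3.0, gamma=1.2))
        m2 = fit_fsvm(X, y, FSVMConfig(Z=3.0, gamma=1.2))
        np.testing.assert_array_equal(m1.K, m2.K)
        np.testing.assert_array_equal(m1.w, m2.w)
        assert m1.b == m2.b

    def test_predict_reproduces_training_decisions(self):
        X, y = _two_moons(seed=15)
        model = fit_fsvm(X, y, FSVMConfig(Z=10.0, gamma=1.0))
        d1 = fsvm.decision_function(model, X)
        d2 = model.embedding.transform(X) @ model.w + model.b
        np.testing.assert_allclose(d1, d2)

    def test_far_points_reach_vanishing_kernel_limit(self):
        # as the RBF row vanishes, the decision value converges to the
        # embedding of the zero kernel vector, independent of direction
        X, y = _two_moons(seed=16)
        model = fit_fsvm(X, y, FSVMConfig(Z=5.0, gamma=1.0))
        emb = model.embedding
        far = 1e3 * np.array([[1.0, 1.0], [-1.0, 2.0], [0.5, -1.0]])
        d = fsvm.decision_function(model, far)
        z_inf = (emb.total_mean - emb.row_means) @ emb.U / np.sqrt(emb.eigvals)
        limit = float(z_inf @ model.w + model.b)
        np.testing.assert_allclose(d, limit, atol=1e-10)

    def test_labels_signed(self):
        X, y = _two_moons(seed=17)
        model = fit_fsvm(X, y, FSVMConfig())
        assert set(predict(model, X)) <= {-1, 1}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_fsvm(np.zeros((3, 2)), np.array([1, -1, 1]))
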
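"""Radius-margin SVM with a learned positive-semidefinite metric (F-SVM).

The classifier jointly learns a linear hyperplane and a PSD matrix ``K``
acting as a feature-space metric, minimising

    f(K, w, b) = 1/2 w^T K^{-1} w  +  Z * sum_i delta_i  +  rho * tr(K N)

over hinge slacks ``delta_i = max(0, 1 - y_i (w^T z_i + b))``, where ``N``
is the scatter (covariance) of the kernel-PCA embedded training points and
``tr(K N)`` is the radius surrogate penalising spread in the learned
metric.  Inputs are first embedded by RBF kernel PCA, keeping dimensions
until a set fraction (default 0.9) of the kernel eigenvalue mass is
retained.

The fit alternates exact coordinate descent steps: (a) with ``K`` fixed the
problem is a standard linear soft-margin SVM in the ``K^{1/2}``-transformed
space; (b) with ``(w, b)`` fixed, ``K`` takes a projected-gradient step,
``K <- P_+(K - t grad f)``, with backtracking on the step size and
eigenvalue clipping as the PSD projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf
from sklearn.svm import SVC

__all__ = [
    "FSVMConfig",
    "KernelEmbedding",
    "FSVMModel",
    "rbf_kernel",
    "kernel_pca_embed",
    "scatter_matrix",
    "init_K",
    "solve_svm_given_K",
    "fsvm_objective",
    "grad_K",
    "project_psd",
    "fit_fsvm",
    "predict",
    "decision_function",
]


@dataclass
class FSVMConfig:
    """Hyperparameters of the radius-margin fit.

    ``Z`` is the margin/slack trade-off (the SVM cost), ``gamma`` the RBF
    width, ``rho`` the weight of the radius term tr(KN).  ``kpca_ratio`` is
    the cumulative kernel-eigenvalue mass retained by the embedding.  ``t1``
    is the initial gradient step on K, halved until the objective does not
    increase; ``eps_psd`` floors eigenvalues wherever K must stay invertible.
    """

    Z: float = 1.0
    gamma: float = 0.1
    rho: float = 0.01
    kpca_ratio: float = 0.9
    t1: float = 1e-3
    eps_psd: float = 1e-8
    max_alternations: int = 20
    tol: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("Z", "gamma", "rho", "t1", "eps_psd", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.kpca_ratio <= 1.0:
            raise ValueError("kpca_ratio must lie in (0, 1]")
        if self.max_alternations < 1:
            raise ValueError("max_alternations must be >= 1")


@dataclass
class KernelEmbedding:
    """Centered RBF kernel-PCA basis fitted on training points."""

    X_train: np.ndarray
    gamma: float
    eigvals: np.ndarray  # retained, descending, > 0
    U: np.ndarray  # n_train x G eigenvectors of the centered kernel
    G: int
    row_means: np.ndarray  # column means of the training kernel
    total_mean: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Embed points; training inputs reproduce their training coordinates."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.X_train.shape[1]:
            raise ValueError("dimension mismatch with training data")
        Knew = rbf_kernel(X, self.X_train, self.gamma)
        Kc = (
            Knew
            - Knew.mean(axis=1, keepdims=True)
            - self.row_means[None, :]
            + self.total_mean
        )
        return Kc @ self.U / np.sqrt(self.eigvals)[None, :]


@dataclass
class FSVMModel:
    embedding: KernelEmbedding
    K: np.ndarray
    w: np.ndarray
    b: float
    N: np.ndarray
    config: FSVMConfig
    objective_trace: list = field(default_factory=list)


def rbf_kernel(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """k(x, y) = exp(-gamma * ||x - y||^2); entries in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return _sk_rbf(np.atleast_2d(X), np.atleast_2d(Y), gamma=gamma)


def kernel_pca_embed(
    X: np.ndarray, gamma: float, ratio: float = 0.9
) -> tuple[KernelEmbedding, np.ndarray]:
    """Double-centered RBF kernel PCA.

    Retains the smallest G with cumulative eigenvalue mass >= ``ratio``
    (over the positive spectrum); coordinates are scaled ``U sqrt(L)`` so
    the retained components reconstruct the centered kernel exactly when
    ``ratio = 1``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Kmat = rbf_kernel(X, X, gamma)
    n = Kmat.shape[0]
    row_means = Kmat.mean(axis=0)
    total_mean = float(Kmat.mean())
    Kc = Kmat - row_means[None, :] - row_means[:, None] + total_mean
    vals, vecs = np.linalg.eigh(Kc)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    pos = np.clip(vals, 0.0, None)
    total = pos.sum()
    if total <= n * 1e-12:
        raise ValueError("degenerate kernel: all points coincide")
    cum = np.cumsum(pos) / total
    G = int(np.searchsorted(cum, ratio - 1e-12) + 1)
    # never keep numerically-zero directions (they are not invertible scale)
    G = min(G, int(np.sum(pos > total * 1e-12)))
    G = max(G, 1)
    eigvals = pos[:G]
    U = vecs[:, :G]
    emb = KernelEmbedding(
        X_train=X,
        gamma=gamma,
        eigvals=eigvals,
        U=U,
        G=G,
        row_means=row_means,
        total_mean=total_mean,
    )
    Z_emb = U * np.sqrt(eigvals)[None, :]
    return emb, Z_emb


def scatter_matrix(Z_emb: np.ndarray) -> np.ndarray:
    """Sample covariance of the embedded coordinates (uniform weights, n-1)."""
    Z_emb = np.atleast_2d(np.asarray(Z_emb, dtype=float))
    if Z_emb.shape[0] < 2:
        raise ValueError("need at least 2 embedded samples")
    N = np.cov(Z_emb, rowvar=False, ddof=1)
    return np.atleast_2d(N)


def _floored_eigh(M: np.ndarray, floor: float) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    return np.maximum(vals, floor), vecs


def init_K(N: np.ndarray, eps_psd: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """K0 = D L^{-1/2} D^T from the eigendecomposition N = D L D^T.

    Also returns the transform A0 = L^{-1/4} D^T with A0^T A0 = K0.
    Eigenvalues are floored at ``eps_psd * tr(N) / G`` so a singular scatter
    still yields an invertible K0.
    """
    N = np.asarray(N, dtype=float)
    G = N.shape[0]
    floor = eps_psd * max(np.trace(N), 1.0) / G
    vals, vecs = _floored_eigh(N, floor)
    K0 = (vecs * vals**-0.5) @ vecs.T
    A0 = (vals**-0.25)[:, None] * vecs.T
    return K0, A0


def _psd_sqrt(K: np.ndarray, eps: float) -> np.ndarray:
    vals, vecs = _floored_eigh(K, eps * max(np.trace(K), 1.0) / K.shape[0])
    return (vecs * np.sqrt(vals)) @ vecs.T


def _psd_inv(K: np.ndarray, eps: float) -> np.ndarray:
    vals, vecs = _floored_eigh(K, eps * max(np.trace(K), 1.0) / K.shape[0])
    return (vecs / vals) @ vecs.T


def solve_svm_given_K(
    Z_emb: np.ndarray, y: np.ndarray, K: np.ndarray, Zparam: float
) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact SVM sub-problem for fixed K.

    Transforms ``z' = K^{1/2} z``, solves the standard linear soft-margin
    SVM with cost ``Zparam``, and maps the solution back as ``w = K^{1/2} v``
    so that ``w^T K^{-1} w = ||v||^2``.  Returns ``(w, b, slacks)``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Ks = _psd_sqrt(np.asarray(K, dtype=float), 1e-12)
    Zt = Z_emb @ Ks
    clf = SVC(kernel="linear", C=Zparam, tol=1e-8)
    clf.fit(Zt, y)
    v = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    w = Ks @ v
    margins = y * (Z_emb @ w + b)
    delta = np.maximum(0.0, 1.0 - margins)
    return w, b, delta


def fsvm_objective(
    K: np.ndarray,
    w: np.ndarray,
    delta: np.ndarray,
    Zparam: float,
    rho: float,
    N: np.ndarray,
    eps_psd: float = 1e-8,
) -> float:
    """f = 1/2 w^T K^{-1} w + Z * sum(delta) + rho * tr(K N)."""
    Kinv = _psd_inv(np.asarray(K, dtype=float), eps_psd)
    return float(
        0.5 * w @ Kinv @ w + Zparam * np.sum(delta) + rho * np.trace(K @ N)
    )


def grad_K(
    K: np.ndarray, w: np.ndarray, rho: float, N: np.ndarray, eps_psd: float = 1e-8
) -> np.ndarray:
    """grad f(K) = -1/2 K^{-1} w w^T K^{-1} + rho N (symmetric)."""
    Kinv = _psd_inv(np.asarray(K, dtype=float), eps_psd)
    u = Kinv @ w
    g = -0.5 * np.outer(u, u) + rho * np.asarray(N, dtype=float)
    return (g + g.T) / 2.0


def project_psd(M: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping: the Frobenius-nearest PSD matrix up to the eps floor."""
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8 * max(np.linalg.norm(M), 1.0)):
        raise ValueError("project_psd requires a symmetric matrix")
    vals, vecs = np.linalg.eigh(M)
    return (vecs * np.maximum(vals, eps)) @ vecs.T


def fit_fsvm(X: np.ndarray, y: np.ndarray, config: FSVMConfig | None = None) -> FSVMModel:
    """Alternating fit: embed, init K from the scatter, then repeat
    [SVM solve given K -> backtracked projected-gradient step on K]
    until the relative Frobenius change of K drops below ``tol``.

    The recorded ``objective_trace`` (one entry per alternation, after the
    SVM solve) is non-increasing: both half-steps only ever lower f, and if
    a re-solve under the updated K comes back worse than the carried-over
    hyperplane (possible at solver tolerance) the previous (w, b) is kept.
    """
    config = config or FSVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    embedding, Z_emb = kernel_pca_embed(X, config.gamma, config.kpca_ratio)
    N = scatter_matrix(Z_emb)
    K, _ = init_K(N, config.eps_psd)
    eps_floor = config.eps_psd

    w, b, delta = solve_svm_given_K(Z_emb, y, K, config.Z)
    f = fsvm_objective(K, w, delta, config.Z, config.rho, N, eps_floor)
    trace = [f]
    for _ in range(config.max_alternations):
        # (b) projected-gradient step on K with backtracking; delta does not
        # depend on K, so only the margin and radius terms move
        g = grad_K(K, w, config.rho, N, eps_floor)
        t = config.t1
        K_new, f_new = K, f
        for _ in range(40):
            cand = project_psd(K - t * g, eps_floor)
            f_cand = fsvm_objective(cand, w, delta, config.Z, config.rho, N, eps_floor)
            if f_cand <= f:
                K_new, f_new = cand, f_cand
                break
            t /= 2.0
        _assert_psd(K_new, eps_floor)
        rel_change = np.linalg.norm(K_new - K) / max(np.linalg.norm(K), 1e-12)
        K = K_new

        # (a) re-solve the hyperplane under the new K; keep the old one if the
        # solver's answer is not at least as good
        w2, b2, delta2 = solve_svm_given_K(Z_emb, y, K, config.Z)
        f2 = fsvm_objective(K, w2, delta2, config.Z, config.rho, N, eps_floor)
        if f2 <= f_new:
            w, b, delta, f = w2, b2, delta2, f2
        else:
            f = f_new
        trace.append(f)
        if rel_change < config.tol:
            break

    return FSVMModel(
        embedding=embedding, K=K, w=w, b=b, N=N, config=config, objective_trace=trace
    )


def _assert_psd(K: np.ndarray, eps: float) -> None:
    vals = np.linalg.eigvalsh((K + K.T) / 2.0)
    if vals.min() < eps * 0.5:
        raise AssertionError(f"K left the PSD cone: min eigenvalue {vals.min():g}")


def decision_function(model: FSVMModel, Xnew: np.ndarray) -> np.ndarray:
    Z_new = model.embedding.transform(Xnew)
    return Z_new @ model.w + model.b


def predict(model: FSVMModel, Xnew: np.ndarray) -> np.ndarray:
    """Signed labels; exact zeros go to the positive class."""
    d = decision_function(model, Xnew)
    return np.where(d >= 0, 1, -1)
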
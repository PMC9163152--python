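"""Dense PCA and sparse PCA by variable projection.

Sparse PCA is posed as

    min_B  1/(2n) ||X - X B A^T||_F^2 + alpha * psi(B)   s.t.  A^T A = I,

where B (variables x components) is the sparse weight matrix mapping the
standardized design to component scores Z = X B, A is orthonormal, and
psi is an L1, L2 or elastic-net penalty.  The problem is solved by
alternating minimization:

* A-step: orthogonal Procrustes given B — the SVD of (X^T X / n) B;
* B-step: a penalized quadratic per component, solved exactly by cyclic
  coordinate descent with soft-thresholding (L1) / scaled shrinkage (L2).

Both steps minimize their subproblem exactly, so the recorded objective
trace is non-increasing.  With alpha = 0 the iteration is stationary at the
top-k principal directions, recovering dense PCA.

Because sparse components are generally correlated, per-component explained
variance uses the adjusted (sequential-orthogonalization) definition: the
QR decomposition of the score matrix attributes shared variance to the
earlier component.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

from .preprocessing import StandardizedMatrix

_PENALTIES = ("l1", "l2", "elasticnet")


def _as_array(X) -> np.ndarray:
    if isinstance(X, StandardizedMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _canonical_signs(B: np.ndarray) -> np.ndarray:
    """Per-column sign flips making the largest-magnitude weight positive."""
    signs = np.ones(B.shape[1])
    for j in range(B.shape[1]):
        col = B[:, j]
        if np.any(col != 0):
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                signs[j] = -1.0
    return signs


def adjusted_explained_variance(Z: np.ndarray, total_variance: float, n: int) -> np.ndarray:
    """Sequential-QR variance fractions for (possibly correlated) scores.

    Component j is credited with the squared j-th diagonal of the triangular
    factor of Z = QR, i.e. the score variance left after projecting out
    components 1..j-1, divided by the total variance of the design.
    """
    if Z.shape[1] == 0:
        raise ValueError("no components")
    R = np.linalg.qr(Z, mode="r")
    contrib = np.diag(R) ** 2 / (n - 1)
    return contrib / total_variance


class PCA(BaseEstimator, TransformerMixin):
    """Dense PCA with a deterministic sign convention.

    Thin wrapper over the standard SVD decomposition; ``components_`` rows
    are the orthonormal loadings, sign-flipped so each component's
    largest-magnitude loading is positive.
    """

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = _as_array(X)
        n, p = X.shape
        if not 1 <= self.n_components <= p:
            raise ValueError(f"n_components must be in [1, {p}], got {self.n_components}")
        inner = _SkPCA(n_components=self.n_components, svd_solver="full")
        inner.fit(X)
        V = inner.components_.T  # p x k
        signs = _canonical_signs(V)
        self.components_ = (V * signs).T
        self.explained_variance_ratio_ = inner.explained_variance_ratio_.copy()
        self.mean_ = inner.mean_
        self.n_samples_ = n
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_array(X)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


class SparsePCA(BaseEstimator, TransformerMixin):
    """Sparse PCA by alternating Procrustes / penalized-regression updates.

    Parameters
    ----------
    n_components : number of components k.
    alpha : penalty strength (lambda_SPCA), on the per-subject objective
        scale (the reconstruction term is divided by n).
    penalty : 'l1', 'l2' or 'elasticnet'.
    l1_ratio : elastic-net mixing (1 = pure L1); ignored unless
        penalty='elasticnet'.
    support_tol : |weight| below this counts as an exact zero.

    Fitted attributes: ``weights_`` (B, p x k), ``ortho_`` (A, p x k,
    orthonormal), ``components_`` (= B.T), ``objective_trace_``,
    ``explained_variance_ratio_`` (adjusted), ``n_iter_``, ``converged_``.
    """

    def __init__(
        self,
        n_components: int,
        alpha: float = 0.0,
        penalty: str = "l1",
        l1_ratio: float = 0.95,
        max_iter: int = 1000,
        tol: float = 1e-6,
        support_tol: float = 1e-8,
        init: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.penalty = penalty
        self.l1_ratio = l1_ratio
        self.max_iter = max_iter
        self.tol = tol
        self.support_tol = support_tol
        self.init = init

    # -- internals ---------------------------------------------------------

    def _mixing(self) -> tuple[float, float]:
        if self.penalty not in _PENALTIES:
            raise ValueError(f"penalty must be one of {_PENALTIES}")
        if self.penalty == "l1":
            return 1.0, 0.0
        if self.penalty == "l2":
            return 0.0, 1.0
        return self.l1_ratio, 1.0 - self.l1_ratio

    def _objective(self, GB: np.ndarray, B: np.ndarray, A: np.ndarray, trG: float) -> float:
        """Objective from the precomputed product GB = (X'X/n) B."""
        l1, l2 = self._mixing()
        recon = 0.5 * (trG - 2.0 * float(np.sum(GB * A)) + float(np.sum(GB * B)))
        pen = self.alpha * (l1 * np.abs(B).sum() + 0.5 * l2 * (B ** 2).sum())
        return float(recon + pen)

    def _b_step(self, G: np.ndarray, B: np.ndarray, A: np.ndarray) -> np.ndarray:
        """Exact cyclic coordinate descent on the penalized quadratic:
        soft-thresholding for the L1 part, scaled shrinkage for the L2 part.
        The components decouple, so each variable's row of B (one weight per
        component) is updated in a single vectorized step."""
        l1, l2 = self._mixing()
        thr = self.alpha * l1
        ridge = self.alpha * l2
        diag = np.diag(G)
        GA = G @ A
        p = G.shape[0]
        for _ in range(5):
            delta = 0.0
            for i in range(p):
                r = GA[i] - G[i] @ B + diag[i] * B[i]
                new = np.sign(r) * np.maximum(np.abs(r) - thr, 0.0) / (diag[i] + ridge)
                d = np.abs(new - B[i]).max()
                if d > 0.0:
                    B[i] = new
                    delta = max(delta, d)
            if delta < 1e-11:
                break
        return B

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        X = _as_array(X)
        n, p = X.shape
        k = self.n_components
        if not 1 <= k <= p:
            raise ValueError(f"n_components must be in [1, {p}], got {k}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        G = X.T @ X / n
        trG = float(np.trace(G))
        if self.init is not None:
            B0, A0 = self.init
            B, A = np.array(B0, dtype=float), np.array(A0, dtype=float)
            if B.shape != (p, k) or A.shape != (p, k):
                raise ValueError("init matrices must be (n_vars, n_components)")
        else:
            w, V = np.linalg.eigh(G)
            order = np.argsort(w)[::-1][:k]
            A = V[:, order]
            A = A * _canonical_signs(A)
            B = A.copy()
        trace = [self._objective(G @ B, B, A, trG)]
        converged = False
        for _ in range(self.max_iter):
            B = self._b_step(G, B, A)
            GB = G @ B
            U, _, Vt = np.linalg.svd(GB, full_matrices=False)
            A = U @ Vt
            trace.append(self._objective(GB, B, A, trG))
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= self.tol * max(1.0, abs(prev)):
                converged = True
                break
        signs = _canonical_signs(B)
        B = B * signs
        A = A * signs
        B[np.abs(B) < self.support_tol] = 0.0
        self.weights_ = B
        self.ortho_ = A
        self.components_ = B.T
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace) - 1
        self.converged_ = converged
        self.n_samples_ = n
        self.n_features_in_ = p
        Z = X @ B
        total = float(np.trace(np.cov(X, rowvar=False, ddof=1))) if p > 1 else float(np.var(X, ddof=1))
        self.total_variance_ = total
        self.explained_variance_ratio_ = adjusted_explained_variance(Z, total, n)
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_array(X)
        return X @ self.weights_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def support(self, tol: float | None = None) -> list[np.ndarray]:
        """Per-component index sets of variables with |weight| above tol."""
        t = self.support_tol if tol is None else tol
        return [np.flatnonzero(np.abs(self.weights_[:, j]) > t) for j in range(self.weights_.shape[1])]

    def reconstruction_error(self, X) -> float:
        """1/2 ||X - X B A^T||_F^2 (unnormalized)."""
        X = _as_array(X)
        R = X - X @ self.weights_ @ self.ortho_.T
        return 0.5 * float((R ** 2).sum())


# -- functional surface ----------------------------------------------------

def fit_pca(X, k: int) -> PCA:
    return PCA(n_components=k).fit(X)


def fit_spca(X, k: int, lambda_spca: float, penalty: str = "l1", l1_ratio: float = 0.95, **kw) -> SparsePCA:
    return SparsePCA(n_components=k, alpha=lambda_spca, penalty=penalty, l1_ratio=l1_ratio, **kw).fit(X)


def explained_variance(fit: SparsePCA, X) -> np.ndarray:
    """Adjusted explained-variance fractions of a fit on design X."""
    X = _as_array(X)
    if fit.weights_.shape[1] == 0:
        raise ValueError("fit has no components")
    Z = X @ fit.weights_
    p = X.shape[1]
    total = float(np.trace(np.cov(X, rowvar=False, ddof=1))) if p > 1 else float(np.var(X, ddof=1))
    return adjusted_explained_variance(Z, total, X.shape[0])


def support(fit: SparsePCA, tol: float = 1e-8) -> list[np.ndarray]:
    return fit.support(tol)
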
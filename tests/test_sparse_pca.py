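"""Dense PCA and sparse PCA: closed forms, descent, sparsity, reductions."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from spcacox.sparse_pca import (
    PCA,
    SparsePCA,
    adjusted_explained_variance,
    explained_variance,
)

from conftest import block_correlation, exact_correlation_sample


def test_pca_two_column_closed_form():
    rho = 0.8
    X = exact_correlation_sample(500, np.array([[1.0, rho], [rho, 1.0]]), seed=2)
    fit = PCA(n_components=2).fit(X)
    assert fit.explained_variance_ratio_[0] == pytest.approx((1 + rho) / 2, abs=1e-10)
    assert np.allclose(np.abs(fit.components_[0]), 1 / np.sqrt(2), atol=1e-10)
    # sign convention: the dominant loading is positive
    assert fit.components_[0].max() > 0


def test_pca_isotropic_ratios_and_completeness():
    X = exact_correlation_sample(300, np.eye(5), seed=3)
    fit = PCA(n_components=5).fit(X)
    assert np.allclose(fit.explained_variance_ratio_, 0.2, atol=1e-10)
    assert fit.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-10)


def test_pca_k_out_of_range():
    X = exact_correlation_sample(50, np.eye(3), seed=4)
    with pytest.raises(ValueError):
        PCA(n_components=4).fit(X)
    with pytest.raises(ValueError):
        PCA(n_components=0).fit(X)


@pytest.mark.parametrize("k", [1, 2, 3])
def test_spca_reduces_to_pca_at_zero_penalty(two_block_X, k):
    spca = SparsePCA(n_components=k, alpha=0.0).fit(two_block_X)
    pca = PCA(n_components=k).fit(two_block_X)
    angles = subspace_angles(spca.weights_, pca.components_.T)
    assert np.max(angles) < 1e-6
    # scores agree up to per-component sign
    zs = spca.transform(two_block_X)
    zp = pca.transform(two_block_X)
    for j in range(k):
        assert min(np.max(np.abs(zs[:, j] - zp[:, j])), np.max(np.abs(zs[:, j] + zp[:, j]))) < 1e-6


@pytest.mark.parametrize("alpha", [0.0, 0.05, 0.2, 0.5])
def test_spca_constraint_and_descent(two_block_X, alpha):
    fit = SparsePCA(n_components=2, alpha=alpha).fit(two_block_X)
    assert np.allclose(fit.ortho_.T @ fit.ortho_, np.eye(2), atol=1e-8)
    assert np.all(np.diff(fit.objective_trace_) <= 1e-10)


def test_spca_support_shrinks_with_penalty(two_block_X):
    sizes = []
    for alpha in [0.01, 0.05, 0.1, 0.3, 0.6, 1.0]:
        fit = SparsePCA(n_components=2, alpha=alpha).fit(two_block_X)
        sizes.append(sum(s.size for s in fit.support()))
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_spca_reconstruction_bound(two_block_X):
    base = SparsePCA(n_components=2, alpha=0.0).fit(two_block_X)
    for alpha in [0.1, 0.5]:
        pen = SparsePCA(n_components=2, alpha=alpha).fit(two_block_X)
        assert base.reconstruction_error(two_block_X) <= pen.reconstruction_error(two_block_X) + 1e-8


def test_support_reports_nonzero_rows():
    fit = SparsePCA(n_components=2)
    fit.weights_ = np.array([[0.0, 0.5], [0.7, 0.0], [0.7, 0.0], [0.0, 0.0]])
    sup = fit.support()
    assert sup[0].tolist() == [1, 2]
    assert sup[1].tolist() == [0]
    fit.weights_ = np.zeros((4, 1))
    assert fit.support()[0].size == 0


def test_dense_limit_has_full_supports():
    # generic data: blocks plus cross-block correlation, so every loading is dense
    X = exact_correlation_sample(800, block_correlation([2, 2], [0.9, 0.9], 0.25), seed=19)
    fit = SparsePCA(n_components=2, alpha=0.0).fit(X)
    assert all(s.size == 4 for s in fit.support())


def test_explained_variance_matches_pca_at_zero_penalty(two_block_X):
    spca = SparsePCA(n_components=3, alpha=0.0).fit(two_block_X)
    pca = PCA(n_components=3).fit(two_block_X)
    assert np.allclose(spca.explained_variance_ratio_, pca.explained_variance_ratio_, atol=1e-8)


def test_explained_variance_orthogonal_blocks_equals_naive():
    # two independent blocks; a penalized fit with disjoint supports has
    # uncorrelated scores, so the QR adjustment reduces to naive variances
    R = block_correlation([2, 2], [0.9, 0.9])
    X = exact_correlation_sample(2000, R, seed=12)
    fit = SparsePCA(n_components=2, alpha=0.3).fit(X)
    supports = [set(s.tolist()) for s in fit.support()]
    assert supports[0].isdisjoint(supports[1]) and all(supports)
    Z = X @ fit.weights_
    naive = Z.var(axis=0, ddof=1) / X.shape[1]
    assert np.allclose(fit.explained_variance_ratio_, naive, atol=1e-6)


def test_explained_variance_fractions_valid(two_block_X):
    for alpha in [0.0, 0.2]:
        fit = SparsePCA(n_components=3, alpha=alpha).fit(two_block_X)
        f = explained_variance(fit, two_block_X)
        assert np.all(f >= -1e-12) and np.all(f <= 1 + 1e-8)
        assert np.all(np.diff(np.cumsum(f)) >= -1e-12)
        assert f.sum() <= 1 + 1e-8


def test_adjusted_explained_variance_requires_components():
    with pytest.raises(ValueError):
        adjusted_explained_variance(np.empty((10, 0)), 4.0, 10)


def test_nonconvergence_is_flagged_not_silent(two_block_X):
    fit = SparsePCA(n_components=2, alpha=0.3, max_iter=1, tol=0.0).fit(two_block_X)
    assert fit.converged_ is False
    assert len(fit.objective_trace_) == 2
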
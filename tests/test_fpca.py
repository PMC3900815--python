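import numpy as np
import pytest

from conftest import curveset_from_matrix
from mortfda.fpca import fit_fpca, reconstruct, trapezoid_weights, variance_explained


def _orthonormal_pair(grid):
    w = trapezoid_weights(grid)
    phi1 = np.sin(np.pi * (grid - grid[0]) / (grid[-1] - grid[0]))
    phi1 /= np.sqrt(w @ phi1**2)
    phi2 = np.cos(np.pi * (grid - grid[0]) / (grid[-1] - grid[0]))
    phi2 -= (w @ (phi2 * phi1)) * phi1
    phi2 /= np.sqrt(w @ phi2**2)
    return phi1, phi2


def test_rank1_recovery(grid):
    w = trapezoid_weights(grid)
    phi, _ = _orthonormal_pair(grid)
    mu = 4.0 + 0.01 * grid
    beta = np.array([-1.0, -0.4, 0.1, 0.5, 0.8])
    curves = mu + np.outer(beta, phi)
    b = fit_fpca(curveset_from_matrix(curves, grid), K=1)
    assert b.var_explained[0] == pytest.approx(1.0, abs=1e-8)
    sign = np.sign(b.basis[0] @ phi)
    np.testing.assert_allclose(sign * b.basis[0], phi, atol=1e-8)
    np.testing.assert_allclose(sign * b.scores[:, 0], beta - beta.mean(), atol=1e-8)
    np.testing.assert_allclose(b.resid_var_curve, 0.0, atol=1e-12)


def test_identical_curves_zero_scores(grid):
    mu = 3.0 + 0.02 * grid
    curves = np.tile(mu, (6, 1))
    b = fit_fpca(curveset_from_matrix(curves, grid), K=2)
    np.testing.assert_allclose(b.scores, 0.0, atol=1e-10)
    np.testing.assert_allclose(b.mean_curve, mu)
    np.testing.assert_allclose(b.var_explained, 0.0)


def test_two_equal_eigenvalue_components(grid):
    phi1, phi2 = _orthonormal_pair(grid)
    # scores chosen with equal population variance and zero cross-correlation
    b1 = np.array([1.0, -1.0, 1.0, -1.0])
    b2 = np.array([1.0, 1.0, -1.0, -1.0])
    curves = 5.0 + np.outer(b1, phi1) + np.outer(b2, phi2)
    b = fit_fpca(curveset_from_matrix(curves, grid), K=2)
    np.testing.assert_allclose(b.var_explained, [0.5, 0.5], atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_svd_oracle_small_random_sets(seed):
    """Basis, eigenvalues, scores agree with a dense SVD of the centered,
    quadrature-weighted matrix computed independently."""
    rng = np.random.default_rng(seed)
    T = int(rng.integers(3, 7))
    G = int(rng.integers(4, 10))
    grid = np.linspace(40.0, 90.0, G)
    curves = rng.normal(3.0, 1.0, size=(T, G))
    K = min(T - 1, G)
    b = fit_fpca(curveset_from_matrix(curves, grid), K=K)

    w = trapezoid_weights(grid)
    M = (curves - curves.mean(axis=0)) * np.sqrt(w)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    np.testing.assert_allclose(b.eigenvalues, S[:K] ** 2 / T, atol=1e-8)
    for k in range(K):
        if S[k] < 1e-10:
            continue
        phi_oracle = Vt[k] / np.sqrt(w)
        sign = np.sign(b.basis[k] @ phi_oracle)
        np.testing.assert_allclose(sign * b.basis[k], phi_oracle, atol=1e-8)
        np.testing.assert_allclose(sign * b.scores[:, k], U[:, k] * S[k], atol=1e-8)


def test_orthonormal_zero_mean_uncorrelated(default_surface):
    from mortfda import log_transform, smooth_surface

    surface, _ = default_surface
    b = fit_fpca(smooth_surface(log_transform(surface)), K=3)
    w = trapezoid_weights(b.grid)
    gram = (b.basis * w) @ b.basis.T
    np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)
    np.testing.assert_allclose(b.scores.mean(axis=0), 0.0, atol=1e-8)
    corr = b.scores.T @ b.scores
    np.testing.assert_allclose(corr - np.diag(np.diag(corr)), 0.0, atol=1e-6)
    assert (b.resid_var_curve >= 0).all()
    assert (np.diff(b.var_explained) <= 1e-12).all()
    assert b.var_explained.sum() <= 1.0 + 1e-12


def test_parseval_full_order(grid):
    rng = np.random.default_rng(9)
    curves = rng.normal(0, 1, size=(6, len(grid)))
    cs = curveset_from_matrix(curves, grid)
    b = fit_fpca(cs, K=5)
    w = trapezoid_weights(grid)
    centered = curves - curves.mean(axis=0)
    total = np.mean([(c * w) @ c for c in centered])
    assert b.eigenvalues.sum() == pytest.approx(total, rel=1e-6)


def test_constant_shift_only_moves_mean(grid):
    rng = np.random.default_rng(10)
    curves = rng.normal(0, 1, size=(5, len(grid)))
    b1 = fit_fpca(curveset_from_matrix(curves, grid), K=2)
    b2 = fit_fpca(curveset_from_matrix(curves + 7.5, grid), K=2)
    np.testing.assert_allclose(b2.mean_curve, b1.mean_curve + 7.5, atol=1e-10)
    np.testing.assert_allclose(b2.basis, b1.basis, atol=1e-10)
    np.testing.assert_allclose(b2.scores, b1.scores, atol=1e-10)


def test_refit_bit_reproducible(grid):
    rng = np.random.default_rng(11)
    curves = rng.normal(0, 1, size=(5, len(grid)))
    b1 = fit_fpca(curveset_from_matrix(curves, grid), K=3)
    b2 = fit_fpca(curveset_from_matrix(curves.copy(), grid), K=3)
    np.testing.assert_array_equal(b1.basis, b2.basis)
    np.testing.assert_array_equal(b1.scores, b2.scores)


def test_reconstruct(grid):
    rng = np.random.default_rng(12)
    curves = rng.normal(4, 1, size=(6, len(grid)))
    b = fit_fpca(curveset_from_matrix(curves, grid), K=5)
    np.testing.assert_allclose(reconstruct(b, np.zeros(5)), b.mean_curve)
    # complete basis: training years reconstruct exactly
    for t in range(6):
        np.testing.assert_allclose(reconstruct(b, b.scores[t]), curves[t], atol=1e-6)
    # random score vector equals the dense product computed independently
    s = rng.normal(size=5)
    np.testing.assert_allclose(
        reconstruct(b, s), b.mean_curve + sum(s[k] * b.basis[k] for k in range(5))
    )
    with pytest.raises(ValueError, match="scores"):
        reconstruct(b, np.zeros(3))


def test_k_out_of_range(grid):
    curves = np.random.default_rng(13).normal(size=(4, len(grid)))
    cs = curveset_from_matrix(curves, grid)
    with pytest.raises(ValueError, match="out of range"):
        fit_fpca(cs, K=4)  # K must be <= T - 1 = 3
    with pytest.raises(ValueError, match="out of range"):
        fit_fpca(cs, K=0)


def test_variance_explained_accessor(grid):
    curves = np.random.default_rng(14).normal(size=(5, len(grid)))
    b = fit_fpca(curveset_from_matrix(curves, grid), K=2)
    np.testing.assert_array_equal(variance_explained(b), b.var_explained)
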
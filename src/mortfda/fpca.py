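"""Functional principal components decomposition of smooth curves.

The centered annual curves are decomposed against orthonormal
eigenfunctions of their empirical covariance operator, with all inner
products taken under trapezoidal quadrature on the shared age grid:

    f_t(x) = mu(x) + sum_k beta_{t,k} phi_k(x) + e_t(x)

The basis functions phi_k are orthonormal under the quadrature, the score
series beta_{.,k} have zero mean and are mutually uncorrelated, and the
residual variance curve v(x) is the pointwise variance (denominator T) of
the reconstruction residuals e_t(x).

The decomposition is computed from the singular value decomposition of
the centered, quadrature-weighted curve matrix rather than by forming the
covariance, which is numerically stabler.  Signs follow a deterministic
convention: each phi_k integrates to a positive value; when the integral
is indistinguishable from zero the first nonzero element is made
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FPCABasis", "fit_fpca", "variance_explained", "reconstruct", "trapezoid_weights"]


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoidal quadrature weights for a (not necessarily uniform) grid."""
    grid = np.asarray(grid, dtype=float)
    w = np.zeros(len(grid))
    dx = np.diff(grid)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    return w


@dataclass
class FPCABasis:
    """Mean curve, orthonormal basis and per-year scores of a curve set."""

    grid: np.ndarray
    mean_curve: np.ndarray      # G
    basis: np.ndarray           # K x G
    scores: np.ndarray          # T x K
    var_explained: np.ndarray   # K proportions, non-increasing
    resid_var_curve: np.ndarray # G, pointwise variance of e_t(x)
    eigenvalues: np.ndarray     # K, score variances (denominator T)
    total_variance: float       # total centered-curve variance under quadrature
    years: np.ndarray

    @property
    def K(self) -> int:
        return self.basis.shape[0]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Basis as (age, mean, phi_1..phi_K) and scores as (year, beta_1..beta_K)."""
        bdf = pd.DataFrame({"age": self.grid, "mean": self.mean_curve})
        for k in range(self.K):
            bdf[f"phi_{k + 1}"] = self.basis[k]
        sdf = pd.DataFrame({"year": self.years})
        for k in range(self.K):
            sdf[f"beta_{k + 1}"] = self.scores[:, k]
        return bdf, sdf


def _fix_signs(basis: np.ndarray, scores: np.ndarray, w: np.ndarray) -> None:
    for k in range(basis.shape[0]):
        integral = float(w @ basis[k])
        if abs(integral) > 1e-12:
            flip = integral < 0
        else:
            nz = np.nonzero(np.abs(basis[k]) > 1e-12)[0]
            flip = len(nz) > 0 and basis[k, nz[0]] < 0
        if flip:
            basis[k] = -basis[k]
            scores[:, k] = -scores[:, k]


def fit_fpca(curveset, K: int) -> FPCABasis:
    """Fit the functional principal components decomposition.

    Parameters
    ----------
    curveset : SmoothCurveSet
        Smooth curves on a shared grid.
    K
        Basis order; must satisfy ``1 <= K <= min(T - 1, G)``.
    """
    curves = np.asarray(curveset.curves, dtype=float)
    grid = np.asarray(curveset.grid, dtype=float)
    T, G = curves.shape
    if T < 2:
        raise ValueError("need at least 2 curves")
    if not (1 <= K <= min(T - 1, G)):
        raise ValueError(f"K={K} out of range [1, {min(T - 1, G)}]")

    w = trapezoid_weights(grid)
    sqrt_w = np.sqrt(w)
    mean_curve = curves.mean(axis=0)
    centered = curves - mean_curve
    M = centered * sqrt_w  # T x G, rows are sqrt-weighted centered curves

    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(S**2)) / T
    basis = Vt[:K] / sqrt_w          # orthonormal under the quadrature
    scores = U[:, :K] * S[:K]        # equals quadrature inner products <f_t - mu, phi_k>
    eigenvalues = S[:K] ** 2 / T
    # zero-variance threshold relative to the curve magnitude (identical
    # curves differ from their mean only by rounding noise)
    tiny = (1e-9 * max(1.0, float(np.abs(curves).max()))) ** 2
    if total > tiny:
        var_exp = S[:K] ** 2 / np.sum(S**2)
    else:  # zero-variance curve set
        var_exp = np.zeros(K)
        scores = np.zeros_like(scores)
    _fix_signs(basis, scores, w)

    resid = centered - scores @ basis
    resid_var = np.mean(resid**2, axis=0)  # denominator T (population convention)

    return FPCABasis(
        grid=grid,
        mean_curve=mean_curve,
        basis=basis,
        scores=scores,
        var_explained=var_exp,
        resid_var_curve=resid_var,
        eigenvalues=eigenvalues,
        total_variance=total,
        years=np.asarray(curveset.years).copy(),
    )


def variance_explained(b: FPCABasis) -> np.ndarray:
    """Proportion of total centered-curve variance carried by each component."""
    return b.var_explained.copy()


def reconstruct(b: FPCABasis, scores_row: np.ndarray) -> np.ndarray:
    """Curve mu(x) + sum_k beta_k phi_k(x) for one score vector."""
    scores_row = np.asarray(scores_row, dtype=float)
    if scores_row.shape != (b.K,):
        raise ValueError(f"expected {b.K} scores, got shape {scores_row.shape}")
    return b.mean_curve + scores_row @ b.basis
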
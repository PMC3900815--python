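"""Penalized-spline smoothing of annual log mortality-age curves.

Each year's log rates over the age-group midpoints are modelled as a
smooth function of age observed with error.  The smooth function is a
cubic B-spline expansion on uniform knots spanning the midpoint range
(one knot per age group, extended beyond the boundary so the basis is
unclamped), with a second-difference penalty on the coefficients
(P-spline).  On uniform knots the second-difference penalty annihilates
exactly the linear functions, so an arbitrarily large penalty shrinks the
fit to the weighted least-squares line through the points.

The penalty can be fixed or selected per year by generalized
cross-validation (GCV) over a logarithmic grid, ties broken toward the
larger (smoother) penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

__all__ = [
    "SmoothCurveSet",
    "SmoothFit",
    "InsufficientDataError",
    "smooth_year",
    "smooth_surface",
    "make_grid",
]

DEGREE = 3
GCV_GRID = (1e-4, 1e4, 25)  # lambda in 10^-4 .. 10^4, 25 logarithmic steps


class InsufficientDataError(ValueError):
    """Fewer non-missing points than the smoother needs."""


def make_grid(midpoints: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Uniform age grid spanning [min(midpoints), max(midpoints)] inclusively."""
    lo, hi = float(midpoints[0]), float(midpoints[-1])
    n = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    if grid[-1] < hi - 1e-9:  # range not divisible by step: keep the endpoint
        grid = np.append(grid, hi)
    return grid


def spline_knots(midpoints: np.ndarray, degree: int = DEGREE) -> np.ndarray:
    """Uniform unclamped knot vector: one knot per age group over the
    midpoint range, extended ``degree`` knots beyond each boundary."""
    midpoints = np.asarray(midpoints, dtype=float)
    a, b = midpoints[0], midpoints[-1]
    n_inner = len(midpoints)
    h = (b - a) / (n_inner - 1)
    return a + h * np.arange(-degree, n_inner + degree)


def design_matrix(x: np.ndarray, knots: np.ndarray, degree: int = DEGREE) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    # nudge the right endpoint into the half-open support of the last basis
    xe = np.minimum(x, knots[-degree - 1] - 1e-9 * (knots[-1] - knots[0]))
    return BSpline.design_matrix(xe, knots, degree).toarray()


def _second_diff_penalty(n_coef: int) -> np.ndarray:
    D = np.diff(np.eye(n_coef), n=2, axis=0)
    return D.T @ D


@dataclass
class SmoothFit:
    """One year's penalized-spline fit."""

    curve: np.ndarray       # smooth log-rate on the grid
    obs_var: np.ndarray     # residual variance estimate, constant over the grid
    penalty: float
    edf: float              # effective degrees of freedom, trace of the hat matrix
    residuals: np.ndarray   # at the observed midpoints (nan where missing)
    coef: np.ndarray


def _pwls_solve(B, y, w, P, lam):
    """Penalized weighted least squares: (B'WB + lam P) c = B'Wy.

    The basis has more coefficients than observations, so lam = 0 is
    solved as the lam -> 0+ limit: among exact-fit solutions, the one
    with minimal second-difference penalty.
    """
    BW = B * w[:, None]
    BtB = BW.T @ B
    if lam == 0.0:
        lam = 1e-10 * np.trace(BtB) / max(np.trace(P), 1.0)
    M = BtB + lam * P
    coef = np.linalg.solve(M, BW.T @ y)
    # edf = tr(B (B'WB + lam P)^-1 B'W)
    edf = float(np.trace(np.linalg.solve(M, BW.T @ B)))
    return coef, edf


def smooth_year(
    log_y: np.ndarray,
    midpoints: np.ndarray,
    grid: np.ndarray,
    penalty: float | str = "auto",
    weights: np.ndarray | None = None,
    gcv_grid: tuple[float, float, int] = GCV_GRID,
) -> SmoothFit:
    """Fit one year's smooth log-mortality curve.

    Parameters
    ----------
    log_y
        Log rates over the age-group midpoints; ``nan`` marks missing.
    penalty
        Nonnegative penalty, or ``"auto"`` for per-year GCV selection.
    weights
        Optional observation weights (e.g. inverse variances when death
        counts are available); uniform by default.

    Returns
    -------
    SmoothFit
        Curve on the grid, residual variance (RSS over residual degrees
        of freedom, spread over the grid), penalty used and the effective
        degrees of freedom.
    """
    log_y = np.asarray(log_y, dtype=float)
    midpoints = np.asarray(midpoints, dtype=float)
    obs = ~np.isnan(log_y)
    n_obs = int(obs.sum())
    if n_obs < 4:
        raise InsufficientDataError(
            f"need >= 4 non-missing points to smooth, got {n_obs}"
        )
    knots = spline_knots(midpoints)
    B_obs = design_matrix(midpoints[obs], knots)
    B_grid = design_matrix(grid, knots)
    P = _second_diff_penalty(B_obs.shape[1])
    y = log_y[obs]
    w = np.ones(n_obs) if weights is None else np.asarray(weights, dtype=float)[obs]

    if penalty == "auto":
        lo, hi, steps = gcv_grid
        lambdas = np.logspace(np.log10(lo), np.log10(hi), int(steps))
        best = None
        for lam in lambdas:
            coef, edf = _pwls_solve(B_obs, y, w, P, lam)
            rss = float(np.sum(w * (y - B_obs @ coef) ** 2))
            denom = n_obs - edf
            gcv = np.inf if denom <= 0 else n_obs * rss / denom**2
            # ties (<=) resolve toward the larger, smoother penalty
            if best is None or gcv <= best[0]:
                best = (gcv, lam, coef, edf)
        _, lam, coef, edf = best
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValueError("penalty must be nonnegative")
        coef, edf = _pwls_solve(B_obs, y, w, P, lam)

    fitted = B_obs @ coef
    rss = float(np.sum(w * (y - fitted) ** 2))
    denom = max(n_obs - edf, 1e-8)
    sigma2 = rss / denom
    residuals = np.full_like(log_y, np.nan)
    residuals[obs] = y - fitted
    return SmoothFit(
        curve=B_grid @ coef,
        obs_var=np.full(len(grid), sigma2),
        penalty=lam,
        edf=edf,
        residuals=residuals,
        coef=coef,
    )


@dataclass
class SmoothCurveSet:
    """Smooth annual log-mortality curves on a shared fine age grid.

    ``obs_var`` is a single observational-variance curve over the grid,
    pooled across years: the per-age mean squared smoothing residual,
    regressed on age with the same smoother.  Pooling stabilises the
    estimate when the number of years is small.
    """

    years: np.ndarray
    grid: np.ndarray
    curves: np.ndarray      # T x G
    obs_var: np.ndarray     # G
    penalties: np.ndarray   # per-year penalty used
    edf: np.ndarray         # per-year effective degrees of freedom
    midpoints: np.ndarray   # original age-group midpoints

    @property
    def n_years(self) -> int:
        return len(self.years)


def smooth_surface(
    m,
    grid_step: float = 1.0,
    penalty: float | str = "auto",
    gcv_grid: tuple[float, float, int] = GCV_GRID,
) -> SmoothCurveSet:
    """Smooth every year of a log-rate matrix onto one shared age grid.

    Parameters
    ----------
    m : LogRateMatrix
        Log mortality rates over age-group midpoints, one row per year.
    """
    if m.n_years < 2:
        raise InsufficientDataError("need at least 2 years of data")
    grid = make_grid(m.age_midpoints, grid_step)
    T, G = m.n_years, len(grid)
    curves = np.empty((T, G))
    penalties = np.empty(T)
    edfs = np.empty(T)
    resid = np.empty((T, len(m.age_midpoints)))
    for t in range(T):
        try:
            fit = smooth_year(m.logrates[t], m.age_midpoints, grid, penalty, gcv_grid=gcv_grid)
        except InsufficientDataError as exc:
            raise InsufficientDataError(f"year {m.years[t]}: {exc}") from exc
        curves[t] = fit.curve
        penalties[t] = fit.penalty
        edfs[t] = fit.edf
        resid[t] = fit.residuals
        log.info("year %d: lambda=%.4g edf=%.2f", m.years[t], fit.penalty, fit.edf)

    # Pooled observational variance: mean squared residual per age,
    # smoothed over age with the same smoother, floored at zero.
    msr = np.nanmean(resid**2, axis=0)
    if np.isnan(msr).any():
        msr = np.where(np.isnan(msr), np.nanmean(msr), msr)
    var_fit = smooth_year(msr, m.age_midpoints, grid, penalty="auto", gcv_grid=gcv_grid)
    obs_var = np.clip(var_fit.curve, 0.0, None)

    return SmoothCurveSet(
        years=m.years.copy(),
        grid=grid,
        curves=curves,
        obs_var=obs_var,
        penalties=penalties,
        edf=edfs,
        midpoints=np.asarray(m.age_midpoints, dtype=float),
    )
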
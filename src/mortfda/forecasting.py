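"""Forecasting future mortality-age curves with prediction intervals.

Score forecasts from the per-component damped-trend models are combined
with the functional principal components basis:

    f_hat_{T+h}(x) = mu(x) + sum_k bhat_{T+h,k} phi_k(x)

The pointwise log-scale forecast variance decomposes into three stored
components: propagated score-forecast variance sum_k phi_k(x)^2 *
Var(bhat_{T+h,k}), the model-residual variance v(x), and the
observational variance sigma^2(x); the latter two are treated as constant
over the horizon.  Either of the last two can be toggled off (stored as
zeros), e.g. when the interval targets the future smooth curve rather
than a future noisy observation; the total always equals the sum of the
stored components.

Rate-scale intervals exponentiate the log-scale Gaussian bounds (quantile
mapping), and the rate-scale point forecast is exp of the log-scale mean
— the median of the implied lognormal, not its mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .ets import ETSDampedModel, forecast_ets
from .fpca import FPCABasis
from .smoothing import SmoothCurveSet

__all__ = ["CurveForecast", "forecast_surface", "evaluate_at_midpoints"]


@dataclass
class CurveForecast:
    """h-step-ahead mean curves with a pointwise variance decomposition."""

    grid: np.ndarray
    years: np.ndarray        # future calendar years, length h
    mean_log: np.ndarray     # h x G
    score_var: np.ndarray    # h x G
    model_var: np.ndarray    # h x G (zeros when toggled off)
    obs_var: np.ndarray      # h x G (zeros when toggled off)
    level: float
    midpoints: np.ndarray    # original age-group midpoints

    @property
    def var_log(self) -> np.ndarray:
        return self.score_var + self.model_var + self.obs_var

    @property
    def horizon(self) -> int:
        return len(self.years)

    def _bounds_log(self) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + self.level / 2.0)
        half = z * np.sqrt(self.var_log)
        return self.mean_log - half, self.mean_log + half

    @property
    def mean_rate(self) -> np.ndarray:
        return np.exp(self.mean_log)

    @property
    def lower_rate(self) -> np.ndarray:
        return np.exp(self._bounds_log()[0])

    @property
    def upper_rate(self) -> np.ndarray:
        return np.exp(self._bounds_log()[1])

    def age_group_view(self, midpoints: np.ndarray | None = None) -> dict:
        """Mean/lower/upper (rate and log scales) at the age-group midpoints."""
        return evaluate_at_midpoints(self, self.midpoints if midpoints is None else midpoints)


def forecast_surface(
    basis: FPCABasis,
    models: list[ETSDampedModel],
    curves: SmoothCurveSet,
    h: int,
    level: float = 0.80,
    include_model_var: bool = True,
    include_obs_var: bool = True,
) -> CurveForecast:
    """Forecast h future mortality-age curves with pointwise intervals.

    Parameters
    ----------
    basis
        Fitted functional principal components decomposition.
    models
        One fitted damped-trend model per basis function, in order.
    curves
        The smooth curve set the basis was fitted to (supplies the
        observational variance curve and the last calendar year).
    include_model_var, include_obs_var
        Whether the residual variance v(x) and observational variance
        sigma^2(x) enter the interval variance.  Excluded components are
        stored as zeros so the variance decomposition stays additive.
    """
    if len(models) != basis.K:
        raise ValueError(f"{len(models)} score models for K={basis.K} basis functions")
    if not (0.0 < level < 1.0):
        raise ValueError(f"interval level must be in (0, 1), got {level}")
    G = len(basis.grid)
    mean_log = np.tile(basis.mean_curve, (h, 1))
    score_var = np.zeros((h, G))
    for k, m in enumerate(models):
        sf = forecast_ets(m, h, level)
        mean_log += np.outer(sf.means, basis.basis[k])
        score_var += np.outer(sf.variances, basis.basis[k] ** 2)

    model_var = (
        np.tile(basis.resid_var_curve, (h, 1)) if include_model_var else np.zeros((h, G))
    )
    obs_var = np.tile(curves.obs_var, (h, 1)) if include_obs_var else np.zeros((h, G))
    years = curves.years[-1] + 1 + np.arange(h)
    return CurveForecast(
        grid=basis.grid.copy(),
        years=years,
        mean_log=mean_log,
        score_var=score_var,
        model_var=model_var,
        obs_var=obs_var,
        level=level,
        midpoints=np.asarray(curves.midpoints, dtype=float).copy(),
    )


def evaluate_at_midpoints(f: CurveForecast, midpoints: np.ndarray) -> dict:
    """Linear interpolation of the forecast surfaces at the given ages.

    Returns a dict with keys ``mean_log``, ``var_log``, ``mean_rate``,
    ``lower_rate``, ``upper_rate``, each an h x len(midpoints) array.
    """
    midpoints = np.asarray(midpoints, dtype=float)
    if midpoints.min() < f.grid[0] - 1e-9 or midpoints.max() > f.grid[-1] + 1e-9:
        raise ValueError(
            f"midpoints must lie within the grid range "
            f"[{f.grid[0]}, {f.grid[-1]}]"
        )

    def interp(mat):
        return np.vstack([np.interp(midpoints, f.grid, row) for row in mat])

    lower_log, upper_log = f._bounds_log()
    out = {
        "mean_log": interp(f.mean_log),
        "var_log": interp(f.var_log),
        "lower_log": interp(lower_log),
        "upper_log": interp(upper_log),
    }
    out["mean_rate"] = np.exp(out["mean_log"])
    out["lower_rate"] = np.exp(out["lower_log"])
    out["upper_rate"] = np.exp(out["upper_log"])
    return out
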
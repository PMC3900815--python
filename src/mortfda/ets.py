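"""Damped-trend exponential smoothing in innovations state-space form.

The model for one score series y_t is the additive-error, additive
damped-trend, non-seasonal exponential smoothing model:

    y_t = l_{t-1} + phi_d * b_{t-1} + eps_t,        eps_t ~ N(0, sigma2)
    l_t = l_{t-1} + phi_d * b_{t-1} + alpha * eps_t
    b_t = phi_d * b_{t-1} + beta * eps_t

with level smoothing alpha in (0, 1), trend smoothing beta in (0, alpha],
and damping phi_d in (0, 1].  Parameters and initial states (l0, b0) are
estimated jointly by maximizing the Gaussian innovations likelihood
(equivalently minimizing the one-step sum of squared innovations) with
bounded quasi-Newton iterations from a fixed list of starting points, so
the fit is deterministic.

Forecasts have closed forms: the mean at lead j is
l_T + (phi_d + ... + phi_d^j) b_T, and the variance at lead j is
sigma2 * (1 + sum_{i=1}^{j-1} c_i^2) with c_i = alpha + beta * (phi_d +
... + phi_d^i).  With phi_d < 1 the mean converges to the finite limit
l_T + b_T * phi_d / (1 - phi_d) as the lead grows, which is what keeps
long-horizon mortality projections from declining without bound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

log = logging.getLogger(__name__)

__all__ = ["ETSDampedModel", "ScoreForecast", "fit_ets_damped", "forecast_ets"]

ALPHA_BOUNDS = (1e-4, 0.9999)
PHI_BOUNDS = (0.8, 0.98)     # classical damping range
FALLBACK_PHI = 0.9           # used when the series is too short to estimate phi_d
MIN_T_FULL = 8

# deterministic multi-start grid: (alpha, beta/alpha ratio, phi position in bounds)
_STARTS = [
    (0.50, 0.50, 0.5),
    (0.20, 0.10, 0.5),
    (0.80, 0.10, 0.5),
    (0.50, 0.90, 0.9),
    (0.10, 0.50, 0.1),
]


@dataclass
class ETSDampedModel:
    alpha: float
    beta: float
    phi_d: float
    l0: float
    b0: float
    sigma2: float
    loglik: float
    level: np.ndarray   # fitted level states l_1..l_T
    trend: np.ndarray   # fitted trend states b_1..b_T

    @property
    def last_level(self) -> float:
        return float(self.level[-1])

    @property
    def last_trend(self) -> float:
        return float(self.trend[-1])

    def dump(self) -> str:
        """Flat key-value text for reproducibility audits.

        Includes the final filtered states ``l_T``/``b_T``, which are all
        the closed-form forecast needs, so a dumped model can be
        re-forecast without the original series.
        """
        keys = ("alpha", "beta", "phi_d", "l0", "b0", "sigma2", "loglik")
        lines = [f"{k} {getattr(self, k):.12g}" for k in keys]
        lines.append(f"l_T {self.last_level:.12g}")
        lines.append(f"b_T {self.last_trend:.12g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_dump(cls, text: str) -> "ETSDampedModel":
        vals = {}
        for line in text.strip().splitlines():
            k, v = line.split()
            vals[k] = float(v)
        lT = vals.pop("l_T", vals["l0"])
        bT = vals.pop("b_T", vals["b0"])
        return cls(level=np.array([lT]), trend=np.array([bT]), **vals)


@dataclass
class ScoreForecast:
    horizon: int
    means: np.ndarray
    variances: np.ndarray
    level: float          # nominal interval coverage
    lower: np.ndarray
    upper: np.ndarray


def _filter(y, alpha, beta, phi, l0, b0):
    """One-step innovations filter; returns innovations and state paths."""
    T = len(y)
    e = np.empty(T)
    lev = np.empty(T)
    tr = np.empty(T)
    l, b = l0, b0
    for t in range(T):
        mu = l + phi * b
        e[t] = y[t] - mu
        l = mu + alpha * e[t]
        b = phi * b + beta * e[t]
        lev[t] = l
        tr[t] = b
    return e, lev, tr


def _loglik_from_sse(sse: float, T: int) -> float:
    sigma2 = sse / T
    if sigma2 <= 0:
        return np.inf  # degenerate perfect fit
    return -0.5 * T * (np.log(2 * np.pi * sigma2) + 1.0)


def fit_ets_damped(
    series: np.ndarray,
    phi_bounds: tuple[float, float] = PHI_BOUNDS,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
) -> ETSDampedModel:
    """Maximum-likelihood fit of the damped-trend model to one series.

    Series shorter than 8 observations fall back to a fixed damping
    phi_d = 0.9 (only alpha, beta and the initial states are estimated).
    A constant series returns the degenerate exact fit (sigma2 = 0) with
    a warning.  Among converged starts the highest likelihood wins; exact
    likelihood ties resolve toward the smaller alpha.
    """
    y = np.asarray(series, dtype=float)
    T = len(y)
    if T < 2:
        raise ValueError("need at least 2 observations")

    if np.ptp(y) == 0.0:
        warnings.warn("constant series: degenerate ETS fit with sigma2 = 0", stacklevel=2)
        lev = np.full(T, y[0])
        return ETSDampedModel(
            alpha=alpha_bounds[0], beta=alpha_bounds[0] ** 2, phi_d=FALLBACK_PHI,
            l0=float(y[0]), b0=0.0, sigma2=0.0, loglik=np.inf,
            level=lev, trend=np.zeros(T),
        )

    fit_phi = T >= MIN_T_FULL
    if not fit_phi:
        warnings.warn(
            f"series length {T} < {MIN_T_FULL}: damping fixed at {FALLBACK_PHI}",
            stacklevel=2,
        )

    l0_init = float(y[0])
    b0_init = float(np.mean(np.diff(y[: min(T, 8)])))
    scale = max(float(np.std(y)), 1e-8)
    phi_lo, phi_hi = phi_bounds

    beta_lo = alpha_bounds[0]

    def unpack(theta):
        if fit_phi:
            alpha, ratio, phi, l0, b0 = theta
        else:
            alpha, ratio, l0, b0 = theta
            phi = FALLBACK_PHI
        # beta in [beta_lo, alpha] for any alpha in bounds
        return alpha, beta_lo + ratio * (alpha - beta_lo), phi, l0, b0

    def objective(theta):
        alpha, beta, phi, l0, b0 = unpack(theta)
        e, _, _ = _filter(y, alpha, beta, phi, l0, b0)
        sse = float(e @ e)
        return np.log(sse / T + 1e-300)

    bounds = [alpha_bounds, (0.0, 1.0)]
    if fit_phi:
        bounds.append((phi_lo, phi_hi))
    bounds += [(l0_init - 10 * scale, l0_init + 10 * scale),
               (b0_init - 10 * scale, b0_init + 10 * scale)]

    candidates = []
    for a0, r0, p0 in _STARTS:
        phi0 = phi_lo + p0 * (phi_hi - phi_lo)
        x0 = [a0, r0] + ([phi0] if fit_phi else []) + [l0_init, b0_init]
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        alpha, beta, phi, l0, b0 = unpack(res.x)
        e, _, _ = _filter(y, alpha, beta, phi, l0, b0)
        ll = _loglik_from_sse(float(e @ e), T)
        candidates.append((ll, alpha, (alpha, beta, phi, l0, b0)))

    # highest likelihood; ties toward the smaller alpha
    best_ll = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] >= best_ll - 1e-8 * max(abs(best_ll), 1.0)]
    _, _, params = min(tied, key=lambda c: c[1])
    alpha, beta, phi, l0, b0 = params
    e, lev, tr = _filter(y, alpha, beta, phi, l0, b0)
    sse = float(e @ e)
    return ETSDampedModel(
        alpha=alpha, beta=beta, phi_d=phi, l0=l0, b0=b0,
        sigma2=sse / T, loglik=_loglik_from_sse(sse, T),
        level=lev, trend=tr,
    )


def forecast_ets(m: ETSDampedModel, h: int, level: float = 0.80) -> ScoreForecast:
    """Closed-form h-step forecast means, variances and Gaussian intervals."""
    if h < 1:
        raise ValueError("horizon must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError(f"interval level must be in (0, 1), got {level}")
    phi = m.phi_d
    damp_sum = np.cumsum(phi ** np.arange(1, h + 1))   # phi + ... + phi^j
    means = m.last_level + damp_sum * m.last_trend
    c = m.alpha + m.beta * damp_sum                     # c_i, i = 1..h
    cum = np.concatenate(([0.0], np.cumsum(c[: h - 1] ** 2)))
    variances = m.sigma2 * (1.0 + cum)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variances)
    return ScoreForecast(
        horizon=h, means=means, variances=variances, level=level,
        lower=means - half, upper=means + half,
    )
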
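"""Out-of-sample forecast accuracy and basis-order selection.

The integrated squared forecast error (ISFE) between a forecast log-rate
curve and the realized smooth curve is the trapezoidal quadrature of the
squared difference over the age range, normalised by the range length, so
curves that differ by a constant delta give delta^2 (units: squared
log-rate).  The mean ISFE (MISE) averages over forecast horizons.

Order selection holds out the last H years, fits the full
smoothing-decomposition-forecasting pipeline on the training window for
each candidate basis order K, forecasts the holdout horizons, and selects
the K minimising the MISE against the holdout years' own smooth curves,
ties broken toward the smaller (more parsimonious) order.  An
expanding-window variant refits at every forecast origin inside the
holdout instead of forecasting once from the training end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ets import fit_ets_damped, forecast_ets
from .fpca import fit_fpca
from .smoothing import smooth_surface
from .surface import LogRateMatrix

log = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "isfe", "evaluate_orders"]


class GridAlignmentError(ValueError):
    """Curves to be compared live on different grids."""


def isfe(forecast_curve: np.ndarray, realized_curve: np.ndarray, grid: np.ndarray) -> float:
    """Normalised integrated squared forecast error of one curve pair."""
    forecast_curve = np.asarray(forecast_curve, dtype=float)
    realized_curve = np.asarray(realized_curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if forecast_curve.shape != grid.shape or realized_curve.shape != grid.shape:
        raise GridAlignmentError(
            f"curve shapes {forecast_curve.shape}/{realized_curve.shape} "
            f"do not match grid shape {grid.shape}"
        )
    diff2 = (forecast_curve - realized_curve) ** 2
    return float(np.trapezoid(diff2, grid) / (grid[-1] - grid[0]))


@dataclass
class EvaluationReport:
    candidate_orders: list[int]
    holdout_years: np.ndarray
    horizons: list[int]
    isfe_table: pd.DataFrame      # columns K, horizon, isfe
    mise_by_K: dict[int, float]
    selected_K: int
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"K": k, "mise": v, "selected": k == self.selected_K}
            for k, v in sorted(self.mise_by_K.items())
        ]
        return pd.DataFrame(rows)


def _forecast_mean_curves(train_curves, K, h):
    basis = fit_fpca(train_curves, K)
    mean_log = np.tile(basis.mean_curve, (h, 1))
    for k in range(K):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_ets_damped(basis.scores[:, k])
        sf = forecast_ets(m, h)
        mean_log += np.outer(sf.means, basis.basis[k])
    return mean_log


def evaluate_orders(
    m: LogRateMatrix,
    candidate_orders: list[int],
    holdout: int,
    horizons: list[int] | None = None,
    grid_step: float = 1.0,
    penalty: float | str = "auto",
    scheme: str = "single",
    adequacy_margin: float | None = 0.05,
) -> EvaluationReport:
    """Select the basis order by holdout mean integrated squared error.

    Parameters
    ----------
    m
        Full log-rate matrix (training + holdout years).
    candidate_orders
        Basis orders K to compare; infeasible orders are skipped with a
        warning and recorded in the report.
    holdout
        Number H of final years held out.
    horizons
        Forecast horizons (subset of 1..H) entering the MISE; all of
        1..H by default.
    scheme
        ``"single"`` forecasts horizons 1..H once from the training end;
        ``"expanding"`` refits at each origin inside the holdout and
        pools same-horizon errors.
    adequacy_margin
        Select the smallest K whose MISE is within this relative margin
        of the minimum (the "adequate fit" rule).  The default 0.05
        guards against chance over-selection: superfluous components
        carry near-zero scores, so their holdout MISE differs from the
        true order's only by noise and a plain argmin flips a coin among
        them.  Pass ``None`` for the strict argmin.
    """
    T = m.n_years
    H = int(holdout)
    if not (1 <= H < T - 1):
        raise ValueError(f"holdout {H} infeasible for T={T}")
    if horizons is None:
        horizons = list(range(1, H + 1))
    if any(h < 1 or h > H for h in horizons):
        raise ValueError(f"horizons {horizons} must lie in 1..{H}")
    candidates = sorted(set(int(k) for k in candidate_orders))
    T_train = T - H
    k_max = T_train - 1
    feasible = [k for k in candidates if 1 <= k <= k_max]
    skipped = [
        (k, f"K={k} infeasible: training window of {T_train} years allows K <= {k_max}")
        for k in candidates
        if k not in feasible
    ]
    for _, msg in skipped:
        warnings.warn(msg, stacklevel=2)
    if not feasible:
        raise ValueError(
            f"no feasible candidate order: training window of {T_train} years "
            f"allows K <= {k_max}"
        )

    full_curves = smooth_surface(m, grid_step=grid_step, penalty=penalty)
    grid = full_curves.grid
    realized = full_curves.curves[T_train:]  # holdout years' own smooth curves

    def subset(lo, hi):
        return LogRateMatrix(
            years=m.years[lo:hi],
            age_midpoints=m.age_midpoints,
            logrates=m.logrates[lo:hi],
        )

    rows = []
    train_curves_single = (
        smooth_surface(subset(0, T_train), grid_step=grid_step, penalty=penalty)
        if scheme == "single"
        else None
    )
    for K in feasible:
        if scheme == "single":
            mean_log = _forecast_mean_curves(train_curves_single, K, H)
            for h in horizons:
                rows.append({"K": K, "horizon": h, "isfe": isfe(mean_log[h - 1], realized[h - 1], grid)})
        elif scheme == "expanding":
            errs: dict[int, list[float]] = {h: [] for h in horizons}
            for origin in range(T_train, T):
                train_curves = smooth_surface(subset(0, origin), grid_step=grid_step, penalty=penalty)
                h_max = min(max(horizons), T - origin)
                mean_log = _forecast_mean_curves(train_curves, K, h_max)
                for h in horizons:
                    if origin + h <= T:
                        errs[h].append(
                            isfe(mean_log[h - 1], full_curves.curves[origin + h - 1], grid)
                        )
            for h in horizons:
                rows.append({"K": K, "horizon": h, "isfe": float(np.mean(errs[h]))})
        else:
            raise ValueError(f"unknown scheme {scheme!r}")

    table = pd.DataFrame(rows)
    mise = {int(k): float(g["isfe"].mean()) for k, g in table.groupby("K")}
    best = min(mise.values())
    if adequacy_margin is not None:
        selected = min(k for k, v in mise.items() if v <= best * (1 + adequacy_margin))
    else:  # argmin, ties toward smaller K
        selected = min(k for k, v in mise.items() if v <= best)
    log.info("order selection: MISE by K = %s, selected K=%d", mise, selected)
    return EvaluationReport(
        candidate_orders=candidates,
        holdout_years=m.years[T_train:].copy(),
        horizons=list(horizons),
        isfe_table=table,
        mise_by_K=mise,
        selected_K=int(selected),
        skipped=skipped,
    )
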
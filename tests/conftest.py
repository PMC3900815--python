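import numpy as np
import pytest

from mortfda.smoothing import SmoothCurveSet, make_grid
from mortfda.synthetic import GeneratorConfig, ScoreProcess, simulate_surface

MIDPOINTS = np.array([47.0, 52, 57, 62, 67, 72, 77, 82])


@pytest.fixture
def midpoints():
    return MIDPOINTS.copy()


@pytest.fixture
def grid():
    return make_grid(MIDPOINTS, 1.0)


@pytest.fixture
def default_surface():
    """One surface drawn from the default generator scenario."""
    return simulate_surface(GeneratorConfig(seed=42))


def curveset_from_matrix(curves, grid, years=None, obs_var=None):
    """Wrap a raw T x G matrix as a SmoothCurveSet for decomposition tests."""
    curves = np.asarray(curves, dtype=float)
    T = curves.shape[0]
    return SmoothCurveSet(
        years=np.arange(2000, 2000 + T) if years is None else np.asarray(years),
        grid=np.asarray(grid, dtype=float),
        curves=curves,
        obs_var=np.zeros(curves.shape[1]) if obs_var is None else obs_var,
        penalties=np.zeros(T),
        edf=np.zeros(T),
        midpoints=np.asarray(grid, dtype=float)[:: max(1, len(grid) // 8)],
    )


def rank3_config(seed: int) -> GeneratorConfig:
    """Three well-separated components with tiny observational noise.

    Separation must be operational, not just spectral.  Deterministic
    damped trends are all monotone, hence temporally collinear: three
    such paths span barely two effective sample dimensions and the third
    eigenvalue drowns in noise.  Quasi-independent persistent *level*
    processes (alpha near 1, negligible trend) with distinct innovation
    scales give genuinely separated sample eigenvalues, and a longer
    series lets each component's accumulated movement away from its
    training mean grow large against its forecast error, so omitting the
    component measurably worsens holdout forecast error — which is what
    the order-selection statistic can see.
    """
    return GeneratorConfig(
        n_years=120,
        score_processes=(
            ScoreProcess(alpha=0.95, beta=0.01, phi_d=0.9, l0=-1.5, b0=0.0, sigma=0.12),
            ScoreProcess(alpha=0.95, beta=0.01, phi_d=0.9, l0=0.5, b0=0.0, sigma=0.07),
            ScoreProcess(alpha=0.95, beta=0.01, phi_d=0.9, l0=0.0, b0=0.0, sigma=0.045),
        ),
        resid_sds=(),
        obs_sd=0.01,
        seed=seed,
    )
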
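# Methods

`mortfda` forecasts age-specific mortality by treating each calendar
year's log mortality–age profile as one functional observation, in the
functional-time-series tradition of demographic curve forecasting.
This note
records the model, the numerical choices, and the limits of what the
test suite demonstrates.

## Model

Observed rates y_t(x_i) (deaths per 100,000 person-years) at age-group
midpoints x_i, years t = 1..T, are modelled on the natural log scale as

    log y_t(x_i) = f_t(x) + sigma(x) eps_{t,i}

with f_t a smooth function of age.  The smooth curves are decomposed as

    f_t(x) = mu(x) + sum_{k=1}^K beta_{t,k} phi_k(x) + e_t(x)

where the phi_k are orthonormal eigenfunctions of the empirical
covariance operator of the centered curves, the score series beta_{.,k}
are zero-mean and mutually uncorrelated, and e_t(x) is the model
residual with pointwise variance v(x).  Each score series is forecast
independently with an additive-error, additive damped-trend,
non-seasonal exponential smoothing state-space model (level smoothing
alpha, trend smoothing beta <= alpha, damping phi_d), and forecast
curves are reassembled as mu + sum_k bhat_{T+h,k} phi_k with pointwise
log-scale variance

    Var(h, x) = sum_k phi_k(x)^2 Var(bhat_{T+h,k}) + v(x) + sigma^2(x).

Rate-scale intervals exponentiate the Gaussian log-scale bounds; the
rate-scale point forecast is exp of the log-scale mean, i.e. the median
of the implied lognormal.

## Smoothing

Cubic B-splines on uniform knots spanning the midpoint range, one knot
per age group, extended three knots beyond each boundary (unclamped), a
second-difference coefficient penalty, and penalized weighted least
squares.  On uniform knots the penalty annihilates exactly the linear
functions, so the infinite-penalty limit is the weighted least-squares
line; at zero penalty the solver returns the limit solution — the
exact-fit spline with minimal penalty — since the basis is richer than
the data.  The penalty is chosen per year by GCV over 25 logarithmic
steps in [1e-4, 1e4], ties toward the smoother fit.  Weights are
uniform because the input carries rates only; an inverse-variance
weight vector can be supplied when death counts are available.  The
observational variance sigma^2(x) is pooled across years: per-age mean
squared residuals, smoothed over age with the same smoother and floored
at zero.  Pooling stabilises the estimate at small T; it assumes
observational noise varies with age but not with time.

## Decomposition

All inner products use trapezoidal quadrature on the shared uniform age
grid (default step 1 year from the first to the last midpoint).  The
decomposition is the SVD of the centered, sqrt-weight-scaled curve
matrix, which keeps the basis exactly orthonormal and the scores
exactly the quadrature inner products.  Signs are fixed by making each
basis function integrate to a positive value (first nonzero element
positive in the degenerate case), so refits are bit-reproducible.  The
residual variance curve uses the population (denominator-T) convention.
Variance-explained proportions are ratios of squared singular values.

## Score forecasting

Parameters and initial states are estimated jointly by maximizing the
Gaussian innovations likelihood (equivalently minimizing one-step
squared innovations) with L-BFGS-B from five fixed starting points;
ties resolve to the higher likelihood, then the smaller alpha, so fits
are deterministic.  beta is parameterised as beta_lo + r (alpha -
beta_lo), r in [0, 1], honouring the classical constraint beta <=
alpha; damping is bounded in [0.8, 0.98] by default (configurable).
Series shorter than 8 observations fix phi_d = 0.9 and estimate only
alpha, beta and the initial states; constant series return the
degenerate exact fit with a warning.  Forecast means and variances use
the closed innovations-state-space forms; with phi_d < 1 the mean path
converges to l_T + b_T phi_d / (1 - phi_d), which is what keeps
long-horizon mortality projections from declining without bound.

A known limitation, measured in this package's own Monte-Carlo
experiments: the closed-form variance conditions on the estimated
parameters.  At T around 50 the damped-trend likelihood is nearly flat
in (beta, phi_d); the estimates are noisy (beta often collapses to its
bound) and intervals undercover at long horizons — empirical coverage
of nominal 80% intervals is about 89/67/61% at horizons 1/10/20 under
the default simulation scenario, about 75% averaged, whereas feeding
the true parameters to the same formulas gives 80–81% at every
horizon.  Honest long-horizon calibration at this sample size requires
integrating over parameter uncertainty (parametric bootstrap or a
Bayesian treatment), which v1 deliberately omits: intervals are
plug-in Gaussian.

## Interval variance components

The three variance components are stored separately so intervals can be
audited.  v(x) and sigma^2(x) are held constant over the forecast
horizon.  Either term can be toggled: when an interval targets the
future smooth curve (as in the simulation coverage experiments) the
observational term is excluded; when it targets a future noisy
observation it is included.  Excluded components are stored as zeros so
the decomposition always sums to the interval variance.

## Forecast accuracy and order selection

The integrated squared forecast error between a forecast and a realized
smooth log-rate curve is the trapezoidal integral of the squared
difference over age, normalised by the age-range length (so a constant
offset delta scores delta^2; units are squared log-rate).  Order
selection holds out the last H years, fits the full pipeline on the
training window for each candidate K, forecasts horizons 1..H, and
averages the per-horizon errors against the holdout years' own smooth
curves.  An expanding-window variant refits at every origin inside the
holdout.

Selection uses the "adequate fit" rule: the smallest K whose mean error
is within 5% of the minimum.  A strict argmin is inconsistent here
because superfluous components carry near-zero scores, so their holdout
error ties the true order's to within noise and the argmin picks among
ties arbitrarily; the margin restores parsimony.  The strict argmin
remains available (`adequacy_margin=None`).

Order selection can only see components whose scores *move* during the
holdout: the static part of any component is absorbed by the mean
curve, and deterministic damped trends are all monotone and hence
temporally collinear, so several trending components can occupy barely
two effective sample dimensions.  Recovery experiments therefore use
persistent level-driven score processes with distinct innovation
scales.

## Synthetic data

The generator draws from exactly the model above: a quadratic
(increasing, concave) mean log-rate curve over ages 45–84 calibrated to
roughly 60–250 deaths per 100,000; orthonormalised polynomial basis
functions; damped-trend score processes; two further small orthonormal
directions supplying the model residual e_t(x); Gaussian observational
noise (sd 0.05 on the log scale) at the eight five-year group
midpoints.  Defaults: T = 52 years, one dominant component with
ScoreProcess(alpha=0.5, beta=0.1, phi_d=0.92, l0=-1.5, b0=0.25,
sigma=0.2), residual sds (0.05, 0.03).  Score paths are simulated 25
years past the window so coverage and holdout experiments can compare
against the truth's own future curves.  One root seed feeds three
independent streams (scores, residual scores, observation noise), so
disabling one noise source leaves the others' draws unchanged.

What the generator does not emulate: birth-cohort structure, ICD coding
changes, population-denominator (count) noise that scales with deaths,
and any treatment- or screening-driven level shifts.  Passing tests
demonstrate internal statistical correctness under the assumed model,
not robustness to those features of real registry data.

## Numerical details and degenerate inputs

- Zero observed rates are treated as missing (log undefined); the
  smoother interpolates across them.  Smoothing a year requires at
  least four observed ages.
- Age midpoints are arithmetic: (lo + hi)/2, e.g. 47 for 45–49.
- The zero-variance curve-set threshold is relative to curve magnitude
  (identical curves differ from their mean only by rounding noise).
- Coverage counting adds an absolute slack of 1e-5 to the interval
  bounds: in noiseless configurations the intervals have zero width and
  the only forecast error is optimizer convergence (~1e-6); the slack
  is immaterial against any stochastic interval width.
- Forecast CSVs are written with 10 significant digits and round-trip
  through the bundled reader; runs stamp every output with a hash of
  the analytical configuration, and identical configurations produce
  byte-identical outputs.

## Problem sizes used by the checks

The calibration experiment uses 500 replicate surfaces (binomial Monte
Carlo error about 1.8 percentage points); oracle-equivalence checks use
20 random small curve sets and 200,000 simulated forecast paths; the
recovery experiments use 20 generator seeds each for the rank-1
(T = 52) and rank-3 (T = 120) scenarios.
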
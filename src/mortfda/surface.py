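"""Mortality-surface data model and CSV input/output.

A mortality surface is an age-group x calendar-year matrix of mortality
rates (deaths per 100,000 person-years), e.g. eight five-year age groups
45-49 ... 80-84 observed annually for half a century.  Each age group is
represented by its arithmetic midpoint, so the surface can be viewed as a
discretely observed set of annual mortality-age curves.

Zero rates are treated as missing: the analysis operates on the natural
log of the rate, for which a zero is undefined, and the smoother in
:mod:`mortfda.smoothing` interpolates across missing cells.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MortalitySurface",
    "LogRateMatrix",
    "SurfaceFormatError",
    "SurfaceValidationError",
    "read_surface",
    "log_transform",
    "write_forecast",
    "read_forecast",
]


class SurfaceFormatError(ValueError):
    """A CSV cell or header could not be parsed."""


class SurfaceValidationError(ValueError):
    """Parsed data violate a surface invariant (order, sign, contiguity)."""


_AGE_RANGE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")


def parse_age_label(token: str) -> tuple[int, int] | float:
    """Parse an age-group label.

    Accepts range labels such as ``"45-49"`` (hyphen or en/em dash),
    returning integer ``(low, high)`` bounds, or a bare numeric midpoint,
    returned as a float.  Anything else raises :class:`SurfaceFormatError`
    naming the offending token.
    """
    token = str(token).strip()
    m = _AGE_RANGE.match(token)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise SurfaceFormatError(f"age label {token!r}: upper bound below lower")
        return (lo, hi)
    try:
        return float(token)
    except ValueError:
        raise SurfaceFormatError(f"malformed age label {token!r}") from None


def _groups_from_midpoints(mids: np.ndarray) -> list[tuple[int, int]]:
    """Reconstruct integer group bounds from numeric midpoints.

    With uniformly spaced midpoints (spacing d) each group is assumed to
    span d consecutive integer ages centred on the midpoint; otherwise the
    group degenerates to a single age.
    """
    mids = np.asarray(mids, dtype=float)
    if len(mids) >= 2:
        steps = np.diff(mids)
        if np.allclose(steps, steps[0]) and steps[0] > 1:
            half = (steps[0] - 1.0) / 2.0
            return [(int(round(m - half)), int(round(m + half))) for m in mids]
    return [(int(round(m)), int(round(m))) for m in mids]


@dataclass
class MortalitySurface:
    """Observed age-group x year mortality-rate matrix.

    Parameters
    ----------
    age_groups
        Ordered ``(low, high)`` integer age bounds, one per group.
    years
        Consecutive calendar years, one per row of ``rates``.
    rates
        T x A matrix of rates per 100,000 person-years; ``nan`` marks a
        missing (or originally zero) cell.
    """

    age_groups: list[tuple[int, int]]
    years: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        self.age_groups = [(int(lo), int(hi)) for lo, hi in self.age_groups]
        T, A = self.rates.shape
        if len(self.years) != T or len(self.age_groups) != A:
            raise SurfaceValidationError(
                f"rates shape {self.rates.shape} inconsistent with "
                f"{len(self.years)} years / {len(self.age_groups)} age groups"
            )
        if T >= 2 and not np.all(np.diff(self.years) == 1):
            raise SurfaceValidationError("years must be consecutive calendar years")
        mids = self.age_midpoints
        if A >= 2 and not np.all(np.diff(mids) > 0):
            raise SurfaceValidationError("age midpoints must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.rates < 0):
                bad = np.argwhere(self.rates < 0)[0]
                raise SurfaceValidationError(
                    f"negative rate at year {self.years[bad[0]]}, "
                    f"age group {self.age_groups[bad[1]]}"
                )

    @property
    def age_midpoints(self) -> np.ndarray:
        """Arithmetic midpoints (lo + hi) / 2 of the age groups, in years."""
        return np.array([(lo + hi) / 2.0 for lo, hi in self.age_groups])

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.rates)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_ages(self) -> int:
        return len(self.age_groups)


@dataclass
class LogRateMatrix:
    """Natural log of the mortality rates, on the per-100,000 scale."""

    years: np.ndarray
    age_midpoints: np.ndarray
    logrates: np.ndarray

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.logrates)

    @property
    def n_years(self) -> int:
        return len(self.years)


def _zero_to_missing(rates: np.ndarray, years: np.ndarray) -> np.ndarray:
    rates = rates.astype(float)
    zero = rates == 0
    if np.any(zero):
        n = int(zero.sum())
        log.warning("%d zero rate(s) marked missing (log-rate undefined)", n)
        rates[zero] = np.nan
    return rates


def read_surface(path, dialect: str = "wide_age_rows") -> MortalitySurface:
    """Read a mortality surface from CSV.

    Dialects
    --------
    ``wide_age_rows``
        First column ``age_group`` (labels like ``45-49``), remaining
        headers integer years.
    ``wide_year_rows``
        First column ``year``, remaining headers age-group labels.
    ``long``
        Columns ``year, age_group, rate``, any row order.

    Rows and columns are normalised to increasing age and year.  Empty
    fields and ``NA`` are missing; a zero rate is marked missing with a
    warning.
    """
    if dialect not in ("wide_age_rows", "wide_year_rows", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, comment="#", na_values=["NA"], skipinitialspace=True)

    if dialect == "long":
        required = {"year", "age_group", "rate"}
        if not required.issubset(df.columns):
            raise SurfaceFormatError(
                f"long dialect requires columns {sorted(required)}, got {list(df.columns)}"
            )
        wide = df.pivot_table(
            index="age_group", columns="year", values="rate", aggfunc="first", dropna=False
        )
        labels = [parse_age_label(str(g)) for g in wide.index]
        years = np.array([int(y) for y in wide.columns])
        rates = wide.to_numpy(dtype=float).T  # T x A
    elif dialect == "wide_age_rows":
        labels = [parse_age_label(str(g)) for g in df.iloc[:, 0]]
        try:
            years = np.array([int(str(c).strip()) for c in df.columns[1:]])
        except ValueError as exc:
            raise SurfaceFormatError(f"year header not an integer: {exc}") from None
        rates = df.iloc[:, 1:].to_numpy(dtype=float).T
    else:  # wide_year_rows
        labels = [parse_age_label(str(c)) for c in df.columns[1:]]
        try:
            years = np.array([int(v) for v in df.iloc[:, 0]])
        except (ValueError, TypeError) as exc:
            raise SurfaceFormatError(f"year cell not an integer: {exc}") from None
        rates = df.iloc[:, 1:].to_numpy(dtype=float)

    if all(isinstance(lab, tuple) for lab in labels):
        groups = list(labels)
        mids = np.array([(lo + hi) / 2.0 for lo, hi in groups])
    else:
        mids = np.array([float(lab) if not isinstance(lab, tuple) else (lab[0] + lab[1]) / 2.0
                         for lab in labels])
        groups = _groups_from_midpoints(mids)

    age_order = np.argsort(mids)
    year_order = np.argsort(years)
    groups = [groups[i] for i in age_order]
    years = years[year_order]
    rates = rates[np.ix_(year_order, age_order)]
    rates = _zero_to_missing(rates, years)
    return MortalitySurface(age_groups=groups, years=years, rates=rates)


def log_transform(s: MortalitySurface) -> LogRateMatrix:
    """Natural log of the rates; missing cells propagate."""
    with np.errstate(invalid="ignore", divide="ignore"):
        logrates = np.log(s.rates)
    return LogRateMatrix(
        years=s.years.copy(),
        age_midpoints=s.age_midpoints,
        logrates=logrates,
    )


def write_surface(path, s: MortalitySurface) -> None:
    """Write a surface in the wide (age rows) dialect."""
    labels = [f"{lo}-{hi}" for lo, hi in s.age_groups]
    df = pd.DataFrame(s.rates.T, index=pd.Index(labels, name="age_group"),
                      columns=[str(y) for y in s.years])
    df.to_csv(path, float_format="%.10g")


def write_forecast(path, f) -> None:
    """Write a curve forecast as long CSV.

    Columns: ``year, age, point_rate, lower, upper, level``, one row per
    forecast year x age-group midpoint, rates on the deaths-per-100,000
    scale.  Values are written with 10 significant digits so the file
    round-trips through :func:`read_forecast`.
    """
    view = f.age_group_view()
    rows = []
    for i, year in enumerate(f.years):
        for j, age in enumerate(f.midpoints):
            rows.append(
                (int(year), float(age), view["mean_rate"][i, j],
                 view["lower_rate"][i, j], view["upper_rate"][i, j], f.level)
            )
    df = pd.DataFrame(rows, columns=["year", "age", "point_rate", "lower", "upper", "level"])
    df.to_csv(path, index=False, float_format="%.10g")


def read_forecast(path) -> pd.DataFrame:
    """Read back a forecast CSV written by :func:`write_forecast`."""
    df = pd.read_csv(path, comment="#")
    expected = ["year", "age", "point_rate", "lower", "upper", "level"]
    if list(df.columns) != expected:
        raise SurfaceFormatError(f"forecast CSV columns {list(df.columns)} != {expected}")
    return df
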
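import numpy as np
import pandas as pd
import pytest

from mortfda.surface import (
    MortalitySurface,
    SurfaceFormatError,
    SurfaceValidationError,
    log_transform,
    parse_age_label,
    read_forecast,
    read_surface,
    write_forecast,
    write_surface,
)

GROUPS = ["45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84"]


def _wide_csv(tmp_path, rates, years, groups=GROUPS):
    path = tmp_path / "wide.csv"
    df = pd.DataFrame(rates.T, index=pd.Index(groups, name="age_group"),
                      columns=[str(y) for y in years])
    df.to_csv(path)
    return path


@pytest.fixture
def rates52():
    rng = np.random.default_rng(0)
    return 100 * np.exp(rng.normal(0, 0.3, size=(52, 8)))


def test_wide_read_midpoints_and_shape(tmp_path, rates52):
    path = _wide_csv(tmp_path, rates52, range(1950, 2002))
    s = read_surface(path, "wide_age_rows")
    assert s.n_years == 52
    np.testing.assert_allclose(s.age_midpoints, [47, 52, 57, 62, 67, 72, 77, 82])
    np.testing.assert_allclose(s.rates, rates52)


def test_long_read_shuffled_equals_wide(tmp_path, rates52):
    wide = read_surface(_wide_csv(tmp_path, rates52, range(1950, 2002)), "wide_age_rows")
    rows = [
        {"year": 1950 + t, "age_group": GROUPS[a], "rate": rates52[t, a]}
        for t in range(52)
        for a in range(8)
    ]
    rng = np.random.default_rng(1)
    long_df = pd.DataFrame(rows).sample(frac=1.0, random_state=2)
    lp = tmp_path / "long.csv"
    long_df.to_csv(lp, index=False)
    s = read_surface(lp, "long")
    assert s.age_groups == wide.age_groups
    np.testing.assert_array_equal(s.years, wide.years)
    np.testing.assert_allclose(s.rates, wide.rates)


def test_wide_year_rows_dialect(tmp_path, rates52):
    path = tmp_path / "yr.csv"
    df = pd.DataFrame(rates52, columns=GROUPS)
    df.insert(0, "year", range(1950, 2002))
    df.to_csv(path, index=False)
    s = read_surface(path, "wide_year_rows")
    np.testing.assert_allclose(s.rates, rates52)
    np.testing.assert_allclose(s.age_midpoints, [47, 52, 57, 62, 67, 72, 77, 82])


def test_zero_rate_marked_missing(tmp_path, rates52):
    rates = rates52.copy()
    rates[3, 2] = 0.0
    s = read_surface(_wide_csv(tmp_path, rates, range(1950, 2002)), "wide_age_rows")
    assert s.missing_mask[3, 2]
    assert s.missing_mask.sum() == 1


def test_malformed_age_label_names_token():
    with pytest.raises(SurfaceFormatError, match="forty-five"):
        parse_age_label("forty-five to 49")


def test_numeric_midpoint_labels(tmp_path, rates52):
    path = tmp_path / "mid.csv"
    df = pd.DataFrame(rates52.T, index=pd.Index([47, 52, 57, 62, 67, 72, 77, 82],
                                                name="age_group"),
                      columns=[str(y) for y in range(1950, 2002)])
    df.to_csv(path)
    s = read_surface(path, "wide_age_rows")
    assert s.age_groups[0] == (45, 49)
    assert s.age_groups[-1] == (80, 84)


def test_non_contiguous_years_rejected(tmp_path, rates52):
    years = list(range(1950, 2001)) + [2005]
    path = _wide_csv(tmp_path, rates52, years)
    with pytest.raises(SurfaceValidationError, match="consecutive"):
        read_surface(path, "wide_age_rows")


def test_negative_rate_rejected(tmp_path, rates52):
    rates = rates52.copy()
    rates[0, 0] = -3.0
    path = _wide_csv(tmp_path, rates, range(1950, 2002))
    with pytest.raises(SurfaceValidationError, match="negative"):
        read_surface(path, "wide_age_rows")


def test_log_transform_values_and_missing():
    s = MortalitySurface(
        age_groups=[(45, 49), (50, 54), (55, 59), (60, 64)],
        years=[2000, 2001],
        rates=np.array([[20.0, 1.0, np.nan, 5.0], [2.0, 3.0, 4.0, np.nan]]),
    )
    m = log_transform(s)
    assert m.logrates[0, 0] == pytest.approx(2.9957, abs=5e-5)
    assert m.logrates[0, 1] == 0.0
    np.testing.assert_array_equal(m.missing_mask, s.missing_mask)
    # exp round-trips to the source rates
    np.testing.assert_allclose(np.exp(m.logrates[~m.missing_mask]),
                               s.rates[~s.missing_mask], rtol=1e-12)


def test_all_missing_column_propagates():
    rates = np.full((3, 4), 50.0)
    rates[:, 1] = np.nan
    s = MortalitySurface(
        age_groups=[(45, 49), (50, 54), (55, 59), (60, 64)],
        years=[2000, 2001, 2002], rates=rates,
    )
    m = log_transform(s)
    assert np.isnan(m.logrates[:, 1]).all()


def test_read_write_read_idempotent(tmp_path, rates52):
    p1 = _wide_csv(tmp_path, rates52, range(1950, 2002))
    s1 = read_surface(p1, "wide_age_rows")
    p2 = tmp_path / "rt.csv"
    write_surface(p2, s1)
    s2 = read_surface(p2, "wide_age_rows")
    assert s1.age_groups == s2.age_groups
    np.testing.assert_array_equal(s1.years, s2.years)
    np.testing.assert_allclose(s1.rates, s2.rates, rtol=1e-9)


def test_forecast_round_trip(tmp_path, default_surface):
    from mortfda import fit_fpca, fit_ets_damped, forecast_surface, smooth_surface

    surface, _ = default_surface
    curves = smooth_surface(log_transform(surface))
    basis = fit_fpca(curves, 1)
    fc = forecast_surface(basis, [fit_ets_damped(basis.scores[:, 0])], curves,
                          h=20, level=0.80)
    path = tmp_path / "fc.csv"
    write_forecast(path, fc)
    df = read_forecast(path)
    assert len(df) == 160  # 20 years x 8 age groups
    assert (df["level"] == 0.80).all()
    view = fc.age_group_view()
    got = df["point_rate"].to_numpy().reshape(20, 8)
    np.testing.assert_allclose(got, view["mean_rate"], rtol=1e-9)
    np.testing.assert_allclose(df["lower"].to_numpy().reshape(20, 8),
                               view["lower_rate"], rtol=1e-9)
    np.testing.assert_allclose(df["upper"].to_numpy().reshape(20, 8),
                               view["upper_rate"], rtol=1e-9)
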
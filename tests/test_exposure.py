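"""Seasonal windows, buffer means, tertiles and the binary contrast."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from greenbirth.exposure import (NoDataError, RasterStack, SeasonInstance,
                                 assign_exposure, buffer_mean,
                                 dichotomize_at_percentile, season_of_date,
                                 season_window, tertile_cutpoints)


def brute_force_buffer_mean(raster, x, y, radius_m, dates=None):
    """Exhaustive double loop over pixels x composites."""
    if dates is None:
        t_idx = range(len(raster.dates))
    else:
        t_idx = [k for k, d in enumerate(raster.dates) if d in set(dates)]
    home = raster.pixel_of(x, y)
    vals = []
    for i in range(raster.ny):
        for j in range(raster.nx):
            cx = raster.x0 + (j + 0.5) * raster.resolution
            cy = raster.y0 + (i + 0.5) * raster.resolution
            inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius_m ** 2 + 1e-6
            if inside or (i, j) == home:
                for t in t_idx:
                    v = raster.values[t, i, j]
                    if np.isfinite(v):
                        vals.append(v)
    return float(np.mean(vals))


@pytest.mark.parametrize("d,name,year", [
    (date(2009, 1, 15), "winter", 2009),
    (date(2009, 3, 1), "spring", 2009),
    (date(2009, 11, 30), "fall", 2009),
    (date(2009, 12, 1), "winter", 2010),   # December belongs to next winter
    (date(2009, 6, 10), "summer", 2009),
])
def test_season_of_date(d, name, year):
    s = season_of_date(d)
    assert (s.name, s.year) == (name, year)


def test_season_window_first_half_uses_three_prior_seasons():
    # 5 March is day 5 of a 92-day spring -> prior summer, fall, winter
    w = season_window(date(2009, 3, 5))
    assert [(s.name, s.year) for s in w] == [
        ("summer", 2008), ("fall", 2008), ("winter", 2009)]


def test_season_window_late_birth_includes_birth_season():
    # 20 May is day 81 of 92 -> fall, winter, spring of birth
    w = season_window(date(2009, 5, 20))
    assert [(s.name, s.year) for s in w] == [
        ("fall", 2008), ("winter", 2009), ("spring", 2009)]


def test_season_window_midpoint_day_goes_to_earlier_window():
    # day 46 of the 92-day spring is not "more than halfway"
    d = date(2009, 4, 15)
    s = season_of_date(d)
    assert (d - s.start).days + 1 == 46
    w = season_window(d)
    assert w[-1].name == "winter"


def test_winter_spans_december_through_february():
    w = SeasonInstance(2009, 0)
    assert w.start == date(2008, 12, 1)
    assert w.end == date(2009, 2, 28)


def test_buffer_mean_constant_raster(constant_raster):
    for r in (250.0, 600.0, 1250.0):
        assert buffer_mean(constant_raster, 1300.0, 1200.0, r) == pytest.approx(0.5)


def test_buffer_mean_plus_pattern_at_250m():
    # centre of a 3x3 grid: the 250 m buffer is the centre + 4 orthogonal
    # neighbours
    vals = np.arange(9, dtype=float).reshape(1, 3, 3) / 10.0
    r = RasterStack(vals, 0.0, 0.0, 250.0, [date(2008, 6, 1)])
    x = y = 1.5 * 250.0
    got = buffer_mean(r, x, y, 250.0)
    expected = np.mean([vals[0, 1, 1], vals[0, 0, 1], vals[0, 2, 1],
                        vals[0, 1, 0], vals[0, 1, 2]])
    assert got == pytest.approx(expected)
    assert got == pytest.approx(brute_force_buffer_mean(r, x, y, 250.0))


def test_buffer_1250m_pixel_count_matches_enumeration():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 1, size=(2, 15, 15))
    r = RasterStack(vals, 0.0, 0.0, 250.0, [date(2008, 5, 1), date(2008, 5, 17)])
    x = y = 7.5 * 250.0
    from greenbirth.exposure import _buffer_pixels
    rows, cols = _buffer_pixels(r, x, y, 1250.0)
    count = sum(
        1 for i in range(15) for j in range(15)
        if ((j + 0.5) * 250 - x) ** 2 + ((i + 0.5) * 250 - y) ** 2 <= 1250.0**2 + 1e-6
    )
    assert len(rows) == count <= 81


def test_buffer_mean_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(12):
        ny, nx = rng.integers(5, 20, size=2)
        n_dates = int(rng.integers(1, 5))
        vals = rng.uniform(-0.2, 0.9, size=(n_dates, ny, nx))
        vals[rng.random(vals.shape) < 0.05] = np.nan  # some missing cells
        dates = [date(2008, 1, 1) + pd.Timedelta(days=16 * k).to_pytimedelta()
                 for k in range(n_dates)]
        r = RasterStack(vals, 0.0, 0.0, 250.0, dates)
        x = rng.uniform(0, nx * 250.0 - 1)
        y = rng.uniform(0, ny * 250.0 - 1)
        radius = float(rng.choice([250.0, 600.0, 1250.0]))
        assert buffer_mean(r, x, y, radius) == pytest.approx(
            brute_force_buffer_mean(r, x, y, radius), abs=1e-12)


def test_buffer_mean_shift_identity():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0, 0.8, size=(3, 8, 8))
    dates = [date(2008, 4, 1), date(2008, 4, 17), date(2008, 5, 3)]
    r1 = RasterStack(vals, 0.0, 0.0, 250.0, dates)
    r2 = RasterStack(np.clip(vals + 0.1, -1, 1), 0.0, 0.0, 250.0, dates)
    m1 = buffer_mean(r1, 1000.0, 1000.0, 600.0)
    m2 = buffer_mean(r2, 1000.0, 1000.0, 600.0)
    assert m2 - m1 == pytest.approx(0.1, abs=1e-12)


def test_buffer_mean_all_missing_raises(constant_raster):
    constant_raster.values[:] = np.nan
    with pytest.raises(NoDataError):
        buffer_mean(constant_raster, 500.0, 500.0, 250.0)


def test_tertile_cutpoints_match_order_statistics():
    v = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    c1, c2 = tertile_cutpoints(v)
    assert c1 == pytest.approx(np.percentile(v, 100 / 3))
    assert c2 == pytest.approx(np.percentile(v, 200 / 3))


def test_assign_exposure_tertiles_partition_evenly(medium_frame):
    for _, grp in medium_frame.groupby("community_type"):
        sizes = grp["tertile"].value_counts()
        assert set(sizes.index) == {1, 2, 3}
        assert sizes.max() - sizes.min() <= 2
        # binary contrast is tertiles 2-3 vs 1
        assert (grp["exposed"] == (grp["tertile"] >= 2)).all()


def test_community_tertiles_differ_from_overall(medium_frame):
    # greener-within-city births still fall in the pooled bottom tertile
    city23 = medium_frame[(medium_frame["community_type"] == "city")
                          & (medium_frame["tertile"] >= 2)]
    assert (city23["tertile_overall"] == 1).mean() > 0.25
    town1 = medium_frame[(medium_frame["community_type"] == "township")
                         & (medium_frame["tertile"] == 1)]
    assert (town1["tertile_overall"] >= 2).mean() > 0.10


def test_max_statistic_equals_mean_on_constant_raster(constant_raster):
    cohort = pd.DataFrame({
        "birth_id": [0, 1], "community_type": ["city", "city"],
        "x": [1200.0, 1400.0], "y": [1100.0, 900.0],
        "birth_date": [date(2008, 5, 10), date(2008, 6, 2)],
    })
    mean_a = assign_exposure(cohort, constant_raster, statistic="mean",
                             extra_radii=())
    max_a = assign_exposure(cohort, constant_raster, statistic="max",
                            extra_radii=())
    assert np.allclose(mean_a["ndvi"], max_a["ndvi"])


def test_dichotomize_at_percentile():
    df = pd.DataFrame({"ndvi": np.arange(10) / 10.0,
                       "community_type": ["city"] * 10})
    exposed = dichotomize_at_percentile(df, 20.0)
    thr = np.percentile(df["ndvi"], 20.0)
    assert (exposed.to_numpy() == (df["ndvi"] >= thr).astype(int).to_numpy()).all()

    # all values tied: everyone at/above the threshold
    df2 = pd.DataFrame({"ndvi": [0.4] * 8, "community_type": ["city"] * 8})
    assert dichotomize_at_percentile(df2, 20.0).all()

    with pytest.raises(ValueError):
        dichotomize_at_percentile(df, 0.0)


def test_spearman_250_vs_1250_high_correlation(medium_frame):
    from scipy.stats import spearmanr
    rho = spearmanr(medium_frame["ndvi_mean_250"],
                    medium_frame["ndvi_mean_1250"]).statistic
    assert rho > 0.7


def test_raster_determinism(medium_config, medium_raster):
    from greenbirth.synthetic_data import simulate_raster
    again = simulate_raster(medium_config)
    assert np.array_equal(again.values, medium_raster.values)
    assert again.dates == medium_raster.dates
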
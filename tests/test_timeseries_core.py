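"""Calendar alignment, imputation, daily aggregation and increments."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendroflux.timeseries_core import (
    SLOTS_PER_DAY,
    DailyTreeSeries,
    HalfHourlyGirthSeries,
    PeriodWindow,
    TreeRecord,
    align_to_frame,
    compute_agr,
    daily_increment,
    daily_mean_girth,
    half_hour_grid,
    impute_short_gaps,
    iterate_window_days,
    neighbourhood_ba_d,
    scale_coefficient,
    unscale_coefficient,
    window_length_days,
)


def make_series(start: date, values: np.ndarray, band_id: str = "b1") -> HalfHourlyGirthSeries:
    idx = pd.date_range(pd.Timestamp(start), periods=len(values), freq="30min")
    return HalfHourlyGirthSeries(band_id=band_id, index=idx, girth=np.asarray(values, float))


# ---------------------------------------------------------------------- windows

def test_common_frame_has_1614_days():
    """The 01.03.2007-31.07.2011 frame spans 1614 days of 48 slots."""
    w = PeriodWindow(date(2007, 3, 1), date(2011, 7, 31))
    assert window_length_days(w) == 1614
    assert len(half_hour_grid(w)) == 1614 * SLOTS_PER_DAY


@pytest.mark.parametrize(
    "start, end, days",
    [
        (date(2007, 3, 17), date(2008, 9, 16), 550),   # wet period
        (date(2010, 3, 18), date(2010, 6, 23), 98),    # dry set A
        (date(2010, 2, 18), date(2010, 3, 7), 18),     # first dry spell
        (date(2020, 2, 28), date(2020, 3, 1), 3),      # leap day inside
        (date(2021, 5, 5), date(2021, 5, 5), 1),
    ],
)
def test_window_day_counts(start, end, days):
    assert window_length_days(PeriodWindow(start, end)) == days


def test_window_day_counts_match_brute_force_oracle():
    """Inclusive day counts agree with explicit date iteration, incl. leap years."""
    rng = np.random.default_rng(7)
    base = date(2004, 1, 1)
    for _ in range(300):
        a = base + timedelta(days=int(rng.integers(0, 3000)))
        b = a + timedelta(days=int(rng.integers(0, 900)))
        w = PeriodWindow(a, b)
        assert window_length_days(w) == sum(1 for _ in iterate_window_days(w))
        assert len(align_to_frame(make_series(a, [31.0] * 48), w)) == w.n_days * SLOTS_PER_DAY


def test_align_to_frame_preserves_values_and_marks_missing():
    w = PeriodWindow(date(2007, 3, 1), date(2007, 3, 3))
    s = make_series(date(2007, 3, 2), np.full(48, 31.5))
    out = align_to_frame(s, w)
    assert len(out) == 3 * SLOTS_PER_DAY
    assert np.isnan(out.girth[:48]).all() and np.isnan(out.girth[96:]).all()
    np.testing.assert_array_equal(out.girth[48:96], s.girth)


def test_align_to_frame_outside_data_is_all_missing():
    w = PeriodWindow(date(2010, 1, 1), date(2010, 1, 2))
    out = align_to_frame(make_series(date(2007, 3, 1), [31.0] * 48), w)
    assert np.isnan(out.girth).all()


def test_malformed_grid_rejected():
    idx = pd.date_range("2007-03-01", periods=48, freq="31min")
    with pytest.raises(ValueError, match="30-min grid"):
        HalfHourlyGirthSeries(band_id="b", index=idx, girth=np.full(48, 31.0))


# ------------------------------------------------------------------- imputation

@pytest.mark.parametrize(
    "values, expected",
    [
        ([1.0, np.nan, 2.0], [1.0, 1.5, 2.0]),
        ([1.0, np.nan, np.nan, 3.0], [1.0, 2.0, 2.0, 3.0]),
        ([1.0, np.nan, np.nan, np.nan, 3.0], [1.0, np.nan, np.nan, np.nan, 3.0]),
        ([np.nan, 1.0, 2.0], [np.nan, 1.0, 2.0]),  # edge gap stays
    ],
)
def test_impute_short_gaps_rules(values, expected):
    """Runs of one or two interior missing values take the bounding mean."""
    daily = DailyTreeSeries(band_id="b", dates=pd.date_range("2020-01-01", periods=len(values)),
                            gthm=np.array(values))
    out = impute_short_gaps(daily)
    np.testing.assert_array_equal(out.gthm, np.array(expected))
    filled = np.isnan(values) & ~np.isnan(out.gthm)
    assert out.imputed[filled].all()


@settings(max_examples=60, deadline=None)
@given(st.lists(st.one_of(st.floats(1.0, 100.0), st.none()), min_size=3, max_size=60))
def test_impute_idempotent_and_preserves_observed(values):
    arr = np.array([np.nan if v is None else v for v in values], dtype=float)
    daily = DailyTreeSeries(band_id="b", dates=pd.date_range("2020-01-01", periods=len(arr)),
                            gthm=arr)
    once = impute_short_gaps(daily)
    twice = impute_short_gaps(once)
    np.testing.assert_array_equal(once.gthm, twice.gthm)
    obs = ~np.isnan(arr)
    np.testing.assert_array_equal(once.gthm[obs], arr[obs])


# -------------------------------------------------------------------- daily agg

def test_daily_mean_constant_day():
    s = make_series(date(2007, 3, 1), np.full(48, 31.0))
    out = daily_mean_girth(s)
    assert out.gthm[0] == pytest.approx(31.0)
    assert out.complete[0]


def test_daily_mean_requires_all_48_slots():
    vals = np.full(48, 31.0)
    vals[10] = np.nan
    out = daily_mean_girth(make_series(date(2007, 3, 1), vals), require_complete=True)
    assert np.isnan(out.gthm[0]) and not out.complete[0]
    relaxed = daily_mean_girth(make_series(date(2007, 3, 1), vals), require_complete=False)
    assert relaxed.gthm[0] == pytest.approx(31.0)


def test_daily_mean_matches_direct_summation_oracle():
    ramp = np.linspace(30.0, 32.0, 48)
    out = daily_mean_girth(make_series(date(2007, 3, 1), ramp))
    assert out.gthm[0] == pytest.approx(ramp.sum() / 48.0, abs=1e-12)
    assert out.gthm[0] == pytest.approx((30.0 + 32.0) / 2.0, abs=1e-12)


# ------------------------------------------------------------------- increments

def test_daily_increment_formula_and_gaps():
    gthm = np.array([31.000, 31.002, np.nan, 31.010])
    daily = DailyTreeSeries(band_id="b", dates=pd.date_range("2020-01-01", periods=4), gthm=gthm)
    out = daily_increment(daily)
    assert out.gthi[0] == pytest.approx(2.0)
    assert np.isnan(out.gthi[1]) and np.isnan(out.gthi[2])  # across the gap
    assert np.isnan(out.gthi[3])  # last day has none


def test_increment_telescoping_identity(rng):
    gthm = 31.0 + np.cumsum(rng.normal(0, 0.002, 200))
    daily = daily_increment(
        DailyTreeSeries(band_id="b", dates=pd.date_range("2020-01-01", periods=200), gthm=gthm))
    total = np.nansum(daily.gthi) * 1e-3
    assert total == pytest.approx(gthm[-1] - gthm[0], abs=1e-9)


def test_agr_unit_conversion_and_gthi_proportionality(rng):
    dates = pd.date_range("2020-01-01", periods=366)
    gthm = 31.0 + 0.1 * np.arange(366) / 365.25  # +0.1 cm per year
    daily = daily_increment(DailyTreeSeries(band_id="b", dates=dates, gthm=gthm))
    agr = compute_agr(daily)
    assert agr == pytest.approx(1.0, rel=1e-6)
    # near-identity slope agr ~ 3.65 * mean(gthi)
    ratio = agr / np.nanmean(daily.gthi)
    assert ratio == pytest.approx(3.6525, rel=0.02)


def test_agr_zero_net_change():
    dates = pd.date_range("2020-01-01", periods=100)
    gthm = np.full(100, 31.0)
    daily = DailyTreeSeries(band_id="b", dates=dates, gthm=gthm)
    assert compute_agr(daily) == 0.0


# ------------------------------------------------------- scaling and neighbours

@pytest.mark.parametrize("coef, gbh, expected", [(1.0, 50.0, 1.0), (1.0, 100.0, 0.5),
                                                 (-2.0, 25.0, -4.0)])
def test_scale_coefficient(coef, gbh, expected):
    assert scale_coefficient(coef, gbh) == pytest.approx(expected)


@settings(max_examples=50, deadline=None)
@given(st.floats(-10, 10, allow_nan=False), st.floats(10, 200))
def test_scale_roundtrip(coef, gbh):
    assert unscale_coefficient(scale_coefficient(coef, gbh), gbh) == pytest.approx(coef, abs=1e-12)


def _tree(band, gbh, x, y):
    return TreeRecord(band_id=band, species_code="Mw", gbh=gbh, station=1, x=x, y=y)


def test_ba_d_simple_cases():
    focal = _tree("f", 50, 0.0, 0.0)
    assert neighbourhood_ba_d(focal, []) == 0.0
    # one neighbour of BA 100 cm^2 at 2 m: gbh = sqrt(100*4*pi)
    gbh = float(np.sqrt(100 * 4 * np.pi))
    nb = _tree("n", gbh, 2.0, 0.0)
    assert neighbourhood_ba_d(focal, [nb]) == pytest.approx(50.0)
    far = _tree("n2", gbh, 10.0, 0.0)
    small = _tree("n3", 9.0, 1.0, 0.0)
    assert neighbourhood_ba_d(focal, [far, small]) == 0.0


def test_ba_d_matches_exhaustive_oracle(rng):
    focal = _tree("f", 60, 50.0, 50.0)
    stand = [_tree(f"t{i}", float(rng.uniform(5, 150)),
                   float(rng.uniform(40, 60)), float(rng.uniform(40, 60)))
             for i in range(120)]
    expected = 0.0
    for t in stand:
        d = np.hypot(t.x - 50.0, t.y - 50.0)
        if 0 < d <= 5.0 and t.gbh >= 10.0:
            expected += t.gbh ** 2 / (4 * np.pi) / d
    assert neighbourhood_ba_d(focal, stand) == pytest.approx(expected, rel=1e-12)


def test_ba_d_zero_distance_rejected():
    focal = _tree("f", 50, 0.0, 0.0)
    with pytest.raises(ValueError, match="zero distance"):
        neighbourhood_ba_d(focal, [_tree("n", 50, 0.0, 0.0)])


def test_size_class_follows_overstorey_threshold():
    assert TreeRecord(band_id="a", species_code="Sf", gbh=97, station=1).scl == 2
    assert TreeRecord(band_id="b", species_code="Mw", gbh=31, station=1).scl == 1
    with pytest.raises(ValueError, match="inconsistent"):
        TreeRecord(band_id="c", species_code="Mw", gbh=31, station=1, scl=2)
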
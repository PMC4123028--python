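"""Design-matrix checks: station merging, lagged exposure, warm-season
restriction, spline bases (against a scipy natural-spline oracle) and the
assembled temporal design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline

import heatslope as hs
from heatslope.tempdesign import (
    DOW_LEVELS,
    HOLIDAY_CATEGORIES,
    design_columns,
    natural_spline_basis,
)


def _series(dates, values):
    return pd.DataFrame({"date": pd.to_datetime(dates), "tmax": values})


class TestCombineStations:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (30.0, 32.0, 31.0),
            (30.0, np.nan, 30.0),
            (np.nan, np.nan, np.nan),
        ],
    )
    def test_merge_rules(self, a, b, expected):
        out = hs.combine_stations(
            _series(["2007-01-01"], [a]), _series(["2007-01-01"], [b])
        )
        got = out["tmax"].iloc[0]
        assert (np.isnan(got) and np.isnan(expected)) or got == expected

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            hs.combine_stations(
                _series(["2007-01-01"], [30.0]), _series(["2007-01-02"], [30.0])
            )


class TestLaggedExposure:
    def test_lag_definition_and_identity(self):
        w = _series(["2007-01-01", "2007-01-02", "2007-01-03"], [30.0, 25.0, 20.0])
        lag1 = hs.lagged_exposure(w, lag=1)
        assert np.isnan(lag1["tmax1"].iloc[0])  # first date has no predecessor
        assert lag1["tmax1"].iloc[1] == 30.0
        lag0 = hs.lagged_exposure(w, lag=0)
        assert np.allclose(lag0["tmax1"], w["tmax"])
        with pytest.raises(ValueError):
            hs.lagged_exposure(w, lag=-1)


class TestWarmSeason:
    def test_membership_and_labels(self):
        out = hs.warm_season_subset(
            pd.date_range("2007-10-01", "2008-04-30", freq="D")
        )
        dates = set(out["date"])
        assert pd.Timestamp("2007-10-01") in dates
        assert pd.Timestamp("2008-04-01") not in dates
        assert (out["season_id"] == "2007-2008").all()
        # full Oct-Mar span: 31+30+31+31+29+31 days (2008 is a leap year)
        full = hs.warm_season_subset(pd.date_range("2007-10-01", "2008-03-31"))
        assert len(full) == 183

    def test_idempotence(self):
        once = hs.warm_season_subset(pd.date_range("2007-01-01", "2008-12-31"))
        twice = hs.warm_season_subset(once["date"])
        pd.testing.assert_series_equal(
            once["date"].reset_index(drop=True), twice["date"].reset_index(drop=True)
        )

    @given(st.integers(0, 3000))
    @settings(max_examples=50, deadline=None)
    def test_only_warm_months_survive(self, offset):
        d = pd.Timestamp("2005-01-01") + pd.Timedelta(days=offset)
        out = hs.warm_season_subset([d])
        assert (len(out) == 1) == (d.month in {10, 11, 12, 1, 2, 3})


class TestNaturalSpline:
    def test_matches_scipy_natural_spline_oracle(self):
        """Each basis column interpolated naturally through its knot values
        must reproduce the column everywhere inside the boundary knots."""
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 1, 400))
        knots = np.array([0.0, 0.2, 0.45, 0.7, 1.0])
        basis = natural_spline_basis(x, knots)
        at_knots = natural_spline_basis(knots, knots)
        for j in range(basis.shape[1]):
            oracle = CubicSpline(knots, at_knots[:, j], bc_type="natural")
            assert np.max(np.abs(oracle(x) - basis[:, j])) < 1e-8

    def test_linear_tails(self):
        """Natural splines are linear beyond the boundary knots."""
        knots = np.array([0.0, 0.5, 1.0])
        x = np.array([-2.0, -1.5, -1.0, 2.0, 2.5, 3.0])
        basis = natural_spline_basis(x, knots)
        for j in range(basis.shape[1]):
            left = np.diff(basis[:3, j]) / 0.5
            right = np.diff(basis[3:, j]) / 0.5
            assert np.allclose(left, left[0]) and np.allclose(right, right[0])


@pytest.fixture(scope="module")
def five_season_design():
    dates = pd.date_range("2007-01-01", "2011-12-31", freq="D")
    return hs.warm_season_subset(dates)


@pytest.fixture(scope="module")
def design():
    cal = hs.gen_holiday_calendar(range(2007, 2009))
    dates = pd.date_range("2007-01-01", "2008-12-31", freq="D")
    return hs.temporal_design(dates, cal)


class TestDoyBasis:
    def test_knot_counts_per_season(self, five_season_design):
        basis = hs.doy_spline_basis(five_season_design, interior_knots_per_season=5)
        seasons = sorted(five_season_design["season_id"].unique())
        # K interior knots + 2 boundary knots -> K+1 basis columns
        for i, sid in enumerate(seasons):
            cols = [c for c in basis.columns if c.startswith(f"doy_{sid}_s")]
            expected = 5 if i in (0, len(seasons) - 1) else 6
            assert len(cols) == expected
        lvl = [c for c in basis.columns if c.endswith("_lvl")]
        assert len(lvl) == len(seasons) - 1

    def test_blocks_orthogonal_across_seasons(self, five_season_design):
        basis = hs.doy_spline_basis(five_season_design)
        seasons = sorted(five_season_design["season_id"].unique())
        a = basis[[c for c in basis.columns if seasons[1] in c]].to_numpy()
        b = basis[[c for c in basis.columns if seasons[2] in c]].to_numpy()
        assert np.allclose(a.T @ b, 0.0)

    def test_constant_in_span(self, five_season_design):
        basis = hs.doy_spline_basis(five_season_design).to_numpy()
        X = np.column_stack([np.ones(len(basis)), basis])
        coef, *_ = np.linalg.lstsq(X, np.full(len(basis), 3.7), rcond=None)
        assert np.allclose(X @ coef, 3.7, atol=1e-8)

    def test_column_is_natural_spline_of_day_index(self, five_season_design):
        """Columns restricted to one season are natural cubic splines in the
        within-season day index (scipy interpolation oracle)."""
        basis = hs.doy_spline_basis(five_season_design)
        sid = sorted(five_season_design["season_id"].unique())[2]
        mask = (five_season_design["season_id"] == sid).to_numpy()
        days = (
            five_season_design.loc[mask, "date"]
            - five_season_design.loc[mask, "date"].min()
        ).dt.days.to_numpy(dtype=float)
        x = days / days.max()
        knots = np.quantile(x, np.linspace(0, 1, 7))  # 5 interior + 2 boundary
        col = basis.loc[mask, f"doy_{sid}_s3"].to_numpy()
        # knot values obtained by linear interpolation of the daily grid, so
        # the oracle carries O(h^3) interpolation error; the exact-knot case
        # is checked to 1e-8 in TestNaturalSpline
        at_knots = np.interp(knots, x, col)
        oracle = CubicSpline(knots, at_knots, bc_type="natural")
        assert np.max(np.abs(oracle(x) - col)) < 5e-5

    def test_short_season_rejected(self):
        tiny = hs.warm_season_subset(pd.date_range("2007-10-01", "2007-10-04"))
        with pytest.raises(ValueError):
            hs.doy_spline_basis(tiny, interior_knots_per_season=5)


class TestTemporalDesign:
    def test_reference_monday_non_holiday(self, design):
        row = design[design["date"] == pd.Timestamp("2007-11-05")]  # a Monday
        ind = row[[f"dow_{d}" for d in DOW_LEVELS] + [f"hols_{h}" for h in HOLIDAY_CATEGORIES]]
        assert (ind.to_numpy() == 0).all()

    def test_christmas_indicator(self, design):
        row = design[design["date"] == pd.Timestamp("2007-12-25")]
        hols = row[[f"hols_{h}" for h in HOLIDAY_CATEGORIES]].to_numpy().ravel()
        assert row["hols_christmas"].iloc[0] == 1.0
        assert hols.sum() == 1.0

    def test_column_count(self, design):
        doy_cols = [c for c in design.columns if c.startswith("doy_")]
        assert len(design_columns(design)) == 6 + 4 + len(doy_cols)

    def test_indicator_blocks_sum_at_most_one(self, design):
        dow = design[[f"dow_{d}" for d in DOW_LEVELS]].to_numpy().sum(axis=1)
        hol = design[[f"hols_{h}" for h in HOLIDAY_CATEGORIES]].to_numpy().sum(axis=1)
        assert ((dow <= 1) & (hol <= 1)).all()

    def test_uncovered_dates_rejected(self):
        cal = hs.gen_holiday_calendar([2007])
        with pytest.raises(ValueError):
            hs.temporal_design(pd.date_range("2007-10-01", "2008-03-31"), cal)

    def test_order_invariance(self):
        cal = hs.gen_holiday_calendar(range(2007, 2009))
        dates = pd.date_range("2007-06-01", "2008-06-30", freq="D")
        forward = hs.temporal_design(dates, cal)
        rng = np.random.default_rng(1)
        shuffled = pd.DatetimeIndex(rng.permutation(dates.to_numpy()))
        back = hs.temporal_design(shuffled, cal)
        pd.testing.assert_frame_equal(
            forward.sort_values("date").reset_index(drop=True),
            back.sort_values("date").reset_index(drop=True),
        )


class TestSpatialBasis:
    def test_shape_and_centring(self):
        areas = hs.gen_area_frame(158, seed=1)
        basis = hs.spatial_basis(areas, df_per_direction=2)
        ew = [c for c in basis.columns if c.startswith("ew_")]
        ns = [c for c in basis.columns if c.startswith("ns_")]
        assert len(ew) == 2 and len(ns) == 2
        assert np.allclose(basis[ew + ns].mean(), 0.0, atol=1e-12)

    def test_degenerate_coordinates_rejected(self):
        areas = hs.gen_area_frame(10, seed=0).assign(centroid_ns=0.5)
        with pytest.raises(ValueError):
            hs.spatial_basis(areas)

    def test_matches_natural_spline_oracle(self):
        areas = hs.gen_area_frame(60, seed=2)
        basis = hs.spatial_basis(areas, df_per_direction=2)
        x = areas["centroid_ew"].to_numpy()
        knots = np.quantile(x, [0.0, 0.5, 1.0])
        raw = natural_spline_basis(x, knots)
        raw = raw - raw.mean(axis=0)
        assert np.allclose(basis[["ew_1", "ew_2"]].to_numpy(), raw, atol=1e-10)
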
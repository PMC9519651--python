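"""Landscape, schedule and telemetry generators (ground-truth world)."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit
from shapely.geometry import box

from grazerange.covariates import Scaler
from grazerange.synthetic import (TrueModel, generate_landscape,
                                  generate_schedule, simulate_deer,
                                  simulate_use_series)


class TestGenerateLandscape:
    def test_grid_arithmetic(self):
        cov, ndvi = generate_landscape((0, 0, 2000, 2000), 20, seed=1)
        assert cov.values.shape == (100, 100) == ndvi.values.shape

    def test_seed_determinism(self):
        a, _ = generate_landscape((0, 0, 1000, 1000), 20, seed=5)
        b, _ = generate_landscape((0, 0, 1000, 1000), 20, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_value_ranges(self, landscape):
        cov, ndvi = landscape
        assert cov.values.min() >= 0 and cov.values.max() <= 100
        assert ndvi.values.min() >= -1 and ndvi.values.max() <= 1

    def test_smoothness_controls_autocorrelation(self):
        def lag1(r):
            v = r.values - r.values.mean()
            return float((v[:, :-1] * v[:, 1:]).sum()
                         / np.sqrt((v[:, :-1] ** 2).sum()
                                   * (v[:, 1:] ** 2).sum()))

        smooth, _ = generate_landscape((0, 0, 2000, 2000), 20, 3,
                                       smoothness=500)
        rough, _ = generate_landscape((0, 0, 2000, 2000), 20, 3,
                                      smoothness=20)
        assert lag1(smooth) > lag1(rough)

    def test_bad_extent_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape((0, 0, 1010, 1000), 20, 0)
        with pytest.raises(ValueError):
            generate_landscape((0, 0, 10, 10), 20, 0)
        with pytest.raises(ValueError):
            generate_landscape((0, 0, 1000, 1000), -5, 0)


class TestGenerateSchedule:
    sites = {"n": box(0, 900, 100, 1000), "s1": box(0, 0, 100, 100),
             "s2": box(200, 0, 300, 100)}

    def test_winter_year_single_25_day_december_interval(self):
        sched = generate_schedule(self.sites, [2016], seed=4)
        iv = sched.intervals
        assert len(iv) == 1
        assert iv["start"].iloc[0].month == 12
        assert (iv["end"].iloc[0] - iv["start"].iloc[0]).days + 1 == 25

    def test_summer_term_starts_in_june(self):
        sched = generate_schedule(self.sites, [2017], seed=4)
        assert sched.intervals["start"].min().month == 6

    def test_group_intervals_sorted_disjoint(self):
        sched = generate_schedule(self.sites, [2016, 2017, 2018], seed=2)
        sched.validate()  # raises on overlap
        for group in sched.groups():
            starts = sched.intervals_for(group)["start"]
            assert list(starts) == sorted(starts)

    def test_north_group_is_northernmost_site(self):
        sched = generate_schedule(self.sites, [2017], seed=0)
        assert sched.site_groups == {"n": "north", "s1": "south",
                                     "s2": "south"}

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule({}, [2017], seed=0)


@pytest.fixture(scope="module")
def deer_world(landscape):
    cover, ndvi = landscape
    sites = {"s1": box(800, 800, 1200, 1200)}
    sched = generate_schedule(sites, [2017], seed=1,
                              site_groups={"s1": "south"})
    scaling = Scaler(means={"cover": 50.0, "ndvi": 0.35, "dist_site": 400.0},
                     sds={"cover": 20.0, "ndvi": 0.2, "dist_site": 300.0})
    home = box(100, 100, 1900, 1900)
    return {"cover": cover, "ndvi": ndvi, "schedule": sched,
            "scaling": scaling, "home": home}


class TestSimulateDeer:
    def test_two_hour_cadence_and_schema(self, deer_world):
        w = deer_world
        tm = TrueModel({"dist": -0.5}, scaling=w["scaling"])
        df = simulate_deer(tm, w["home"], 50, w["schedule"], "female", 1,
                           cover=w["cover"], ndvi=w["ndvi"], group="south")
        assert len(df) == 50
        gaps = df["timestamp"].diff().dropna().dt.total_seconds().unique()
        assert list(gaps) == [7200.0]
        assert set(df.columns) >= {"animal_id", "timestamp", "x", "y", "sex",
                                   "quality_ok"}

    def test_null_model_uniform_over_home(self, deer_world):
        # all coefficients zero: locations uniform; 2-D chi-square GoF on a
        # 4x4 grid over the square home polygon
        w = deer_world
        tm = TrueModel({}, re_sd=0.0, scaling=w["scaling"])
        df = simulate_deer(tm, w["home"], 5000, w["schedule"], "female", 3,
                           cover=w["cover"], ndvi=w["ndvi"], group="south")
        hx = np.histogram2d(df["x"], df["y"], bins=4,
                            range=[[100, 1900], [100, 1900]])[0].ravel()
        p = stats.chisquare(hx).pvalue
        assert p > 0.01

    def test_negative_distance_coefficient_attracts(self, deer_world):
        w = deer_world
        from grazerange.covariates import distance_to_sites

        tm0 = TrueModel({}, re_sd=0.0, scaling=w["scaling"])
        tm1 = TrueModel({"dist": -1.0}, re_sd=0.0, scaling=w["scaling"])
        kw = dict(cover=w["cover"], ndvi=w["ndvi"], group="south")
        uni = simulate_deer(tm0, w["home"], 10_000, w["schedule"], "female",
                            7, **kw)
        att = simulate_deer(tm1, w["home"], 10_000, w["schedule"], "female",
                            7, **kw)
        sites = w["schedule"].site_polygons
        assert (distance_to_sites(att, sites).mean()
                < distance_to_sites(uni, sites).mean())

    def test_determinism(self, deer_world):
        w = deer_world
        tm = TrueModel({"dist": -0.5}, scaling=w["scaling"])
        kw = dict(cover=w["cover"], ndvi=w["ndvi"], group="south")
        a = simulate_deer(tm, w["home"], 40, w["schedule"], "male", 9, **kw)
        b = simulate_deer(tm, w["home"], 40, w["schedule"], "male", 9, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_home_outside_raster_rejected(self, deer_world):
        w = deer_world
        tm = TrueModel({}, scaling=w["scaling"])
        with pytest.raises(ValueError):
            simulate_deer(tm, box(5000, 5000, 6000, 6000), 10, w["schedule"],
                          "female", 1, cover=w["cover"], ndvi=w["ndvi"],
                          group="south")

    def test_bad_coefficient_names_rejected(self):
        with pytest.raises(ValueError):
            TrueModel({"dist:treatment[nonsense]": 1.0})
        with pytest.raises(ValueError):
            TrueModel({"elevation": 1.0})
        with pytest.raises(ValueError):
            TrueModel({"dist": np.inf})


class TestSimulateUseSeries:
    def _timestamps(self, n):
        # inside the early window of the toy summer term (21 days of 2-h
        # fixes, recycled: draws are independent Bernoullis per timestamp)
        base = pd.date_range("2017-06-10", periods=252, freq="2h")
        return pd.Series(np.resize(base.to_numpy(), n)).dt.tz_localize("UTC")

    def test_intercept_zero_frequency_half(self, toy_schedule):
        ts = self._timestamps(10_000)
        y = simulate_use_series({"(Intercept)": 0.0}, toy_schedule, ts, 1,
                                group="south")
        assert abs(y.mean() - 0.5) < 0.02

    def test_strongly_negative_intercept_rare_use(self, toy_schedule):
        ts = self._timestamps(100_000)
        y = simulate_use_series({"(Intercept)": -4.6966}, toy_schedule, ts, 2,
                                group="south")
        assert y.mean() == pytest.approx(expit(-4.6966), abs=0.003)

    def test_determinism(self, toy_schedule):
        ts = self._timestamps(500)
        a = simulate_use_series({"(Intercept)": -1.0, "tod[night]": 0.5},
                                toy_schedule, ts, 5, group="south")
        b = simulate_use_series({"(Intercept)": -1.0, "tod[night]": 0.5},
                                toy_schedule, ts, 5, group="south")
        np.testing.assert_array_equal(a, b)

    def test_uncovered_timestamp_rejected(self, toy_schedule):
        ts = pd.date_range("2015-03-01", periods=3, freq="2h", tz="UTC")
        with pytest.raises(ValueError, match="coverage"):
            simulate_use_series({"(Intercept)": 0.0}, toy_schedule, ts, 1,
                                group="south")

    def test_intercept_required(self, toy_schedule):
        with pytest.raises(ValueError, match="Intercept"):
            simulate_use_series({"tod[night]": 1.0}, toy_schedule,
                                self._timestamps(3), 1, group="south")
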
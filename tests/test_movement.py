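"""Telemetry QC, step velocities, seasons, MCP ranges, LVE extraction."""

import numpy as np
import pandas as pd
import pytest

import lichentrend as lt
from lichentrend import movement as mov
from lichentrend.errors import InsufficientDataError

from conftest import small_grid


def fixes(animal, times, lons, lats, herd="h", sex="cow"):
    return pd.DataFrame(
        {
            "animal_id": animal,
            "herd": herd,
            "sex": sex,
            "timestamp": pd.to_datetime(times, utc=True),
            "lon": lons,
            "lat": lats,
        }
    )


class TestHaversine:
    def test_one_degree_arc_at_equator(self):
        d = mov.haversine_m(0.0, 0.0, 1.0, 0.0)
        assert d == pytest.approx(111_195, rel=1e-4)

    def test_symmetry_and_zero(self):
        assert mov.haversine_m(10, 60, 10, 60) == 0.0
        assert mov.haversine_m(10, 60, 11, 61) == pytest.approx(
            mov.haversine_m(11, 61, 10, 60)
        )

    def test_agrees_with_projected_distance_near_center(self):
        """< 0.1% planar error for short steps near the projection centre."""
        proj = mov.LocalEquirect(65.0, -110.0)
        rng = np.random.default_rng(30)
        for _ in range(50):
            x1, y1, x2, y2 = rng.uniform(-2000, 2000, 4)
            if np.hypot(x2 - x1, y2 - y1) < 10:
                continue
            lon1, lat1 = proj.inverse(x1, y1)
            lon2, lat2 = proj.inverse(x2, y2)
            d_sphere = mov.haversine_m(lon1, lat1, lon2, lat2)
            d_plane = np.hypot(x2 - x1, y2 - y1)
            assert abs(d_sphere - d_plane) / d_plane < 1e-3


class TestStepVelocities:
    def test_two_fix_velocity(self):
        # 1000 m apart (due north), 5 h apart -> 200 m/h
        proj = mov.LocalEquirect(65.0, -110.0)
        lon1, lat1 = proj.inverse(0, 0)
        lon2, lat2 = proj.inverse(0, 1000)
        df = fixes("a", ["2008-01-01T00:00", "2008-01-01T05:00"], [lon1, lon2], [lat1, lat2])
        steps = mov.step_velocities(df)
        assert len(steps) == 1
        assert steps.velocity_mh.iloc[0] == pytest.approx(200.0, rel=1e-4)
        assert steps.dt_h.iloc[0] == pytest.approx(5.0)

    def test_identical_coordinates_zero_velocity(self):
        df = fixes("a", ["2008-01-01T00:00", "2008-01-01T08:00"], [-110, -110], [65, 65])
        assert mov.step_velocities(df).velocity_mh.iloc[0] == 0.0

    def test_gaps_beyond_max_dt_excluded(self):
        df = fixes(
            "a",
            ["2008-01-01T00:00", "2008-01-01T05:00", "2008-01-02T08:00"],
            [-110, -110.1, -110.2],
            [65, 65, 65],
        )
        steps = mov.step_velocities(df, max_dt_hours=8.0, dt_tolerance_hours=1.0)
        assert len(steps) == 1

    def test_velocity_invariant_to_track_reversal(self):
        rng = np.random.default_rng(31)
        times = pd.date_range("2008-01-01", periods=6, freq="5h", tz="UTC")
        lons = -110 + rng.normal(0, 0.01, 6).cumsum()
        lats = 65 + rng.normal(0, 0.01, 6).cumsum()
        fwd = mov.step_velocities(fixes("a", times, lons, lats))
        rev = mov.step_velocities(fixes("a", times, lons[::-1], lats[::-1]))
        np.testing.assert_allclose(
            np.sort(fwd.velocity_mh), np.sort(rev.velocity_mh), rtol=1e-12
        )


class TestQcFilter:
    @staticmethod
    def _animal(animal, n_days, per_day, start="2008-01-01"):
        times = []
        t0 = pd.Timestamp(start, tz="UTC")
        for d in range(n_days):
            for k in range(per_day):
                times.append(t0 + pd.Timedelta(days=d, hours=k * (24 // max(per_day, 1))))
        n = len(times)
        return fixes(animal, times, [-110.0] * n, [65.0] * n)

    def test_constructed_pass_fail_set(self):
        tele = pd.concat(
            [
                self._animal("pass_365x3", 365, 3),
                self._animal("pass_400x4", 400, 4),
                self._animal("fail_short", 200, 3),
                self._animal("fail_sparse", 365, 2),
                pd.concat(
                    [  # a 2-fix day breaks the 365-day streak in the middle
                        self._animal("fail_broken", 182, 3),
                        self._animal("fail_broken", 1, 2, start="2008-07-01"),
                        self._animal("fail_broken", 182, 3, start="2008-07-02"),
                    ]
                ),
            ],
            ignore_index=True,
        )
        out = mov.qc_filter(tele, min_fixes_per_day=3)
        assert sorted(out.animal_id.unique()) == ["pass_365x3", "pass_400x4"]

    def test_exactly_365_consecutive_days_retained(self):
        out = mov.qc_filter(self._animal("edge", 365, 3))
        assert out.animal_id.nunique() == 1
        out2 = mov.qc_filter(self._animal("edge", 364, 3))
        assert out2.empty

    def test_idempotent(self):
        tele = pd.concat(
            [self._animal("a", 370, 3), self._animal("b", 100, 3)], ignore_index=True
        )
        once = mov.qc_filter(tele)
        twice = mov.qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSeasons:
    def test_default_examples(self):
        cal = mov.SeasonCalendar()
        assert lt.assign_season("2008-07-15", cal) == "summer"
        assert lt.assign_season("2008-04-16", cal) == "spring"  # inclusive start
        assert lt.assign_season("2008-04-15", cal) == "winter"
        assert lt.assign_season("2008-12-01", cal) == "winter"

    def test_every_leap_year_day_covered_once(self):
        cal = mov.SeasonCalendar()
        days = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        seasons = [cal.assign(d) for d in days]
        assert len(seasons) == 366
        assert set(seasons) == {"spring", "summer", "fall", "winter"}

    def test_overlapping_calendar_rejected(self):
        with pytest.raises(ValueError):
            mov.SeasonCalendar(
                windows={
                    "spring": ((1, 1), (6, 30)),
                    "summer": ((6, 30), (12, 31)),
                }
            )


class TestMcp:
    proj = mov.LocalEquirect(65.0, -110.0)

    def _df_from_xy(self, xy):
        lon, lat = self.proj.inverse(xy[:, 0], xy[:, 1])
        times = pd.date_range("2008-01-01", periods=len(xy), freq="5h", tz="UTC")
        return fixes("a", times, lon, lat)

    def test_square_at_full_retention(self):
        xy = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], dtype=float)
        hr = mov.mcp_95(self._df_from_xy(xy), self.proj, retention=1.0)
        assert hr.polygon.area == pytest.approx(1e6, rel=1e-3)

    def test_distant_outliers_excluded_at_95(self):
        rng = np.random.default_rng(32)
        cluster = rng.normal(0, 100, (100, 2))
        outliers = np.array([[50000, 0], [0, 50000], [-50000, 0], [0, -50000], [40000, 40000]])
        hr = mov.mcp_95(self._df_from_xy(np.vstack([cluster, outliers])), self.proj)
        assert hr.polygon.area < 1e7  # outlier hull would be ~4e9 m²

    def test_area_monotone_in_retention(self):
        rng = np.random.default_rng(33)
        xy = rng.normal(0, 1000, (200, 2))
        df = self._df_from_xy(xy)
        areas = [
            mov.mcp_95(df, self.proj, retention=r).polygon.area
            for r in (0.5, 0.7, 0.9, 1.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(areas, areas[1:]))


class TestExtractLve:
    def test_constructed_lookups(self):
        grid = small_grid(4, 4, cell=100.0)
        proj = mov.LocalEquirect.from_crs_id(grid.crs_id)
        values = np.arange(16.0).reshape(4, 4)
        valid = np.ones((4, 4), bool)
        valid[3, 3] = False
        raster = lt.ScalarRaster(grid=grid, values=values, valid=valid)
        # cell centres of (0,0), (2,1), invalid (3,3), and one point outside
        xs = np.array([50.0, 150.0, 350.0, 5000.0])
        ys = np.array([350.0, 150.0, 50.0, 50.0])
        lon, lat = proj.inverse(xs, ys)
        steps = pd.DataFrame(
            {"lon": lon, "lat": lat, "year": [2000] * 4, "velocity_mh": 1.0}
        )
        out = mov.extract_lve_at_fixes(steps, {2000: raster}, proj)
        assert out.lve_at_start.iloc[0] == 0.0  # row 0, col 0
        assert out.lve_at_start.iloc[1] == values[2, 1]
        assert np.isnan(out.lve_at_start.iloc[2])  # invalid cell
        assert np.isnan(out.lve_at_start.iloc[3])  # outside extent

    def test_missing_year_gives_missing(self):
        grid = small_grid(2, 2, cell=100.0)
        proj = mov.LocalEquirect.from_crs_id(grid.crs_id)
        raster = lt.ScalarRaster(
            grid=grid, values=np.ones((2, 2)), valid=np.ones((2, 2), bool)
        )
        lon, lat = proj.inverse(np.array([50.0]), np.array([50.0]))
        steps = pd.DataFrame({"lon": lon, "lat": lat, "year": [1999], "velocity_mh": 1.0})
        out = mov.extract_lve_at_fixes(steps, {2000: raster}, proj)
        assert np.isnan(out.lve_at_start.iloc[0])


def test_local_equirect_round_trip():
    proj = mov.LocalEquirect(65.0, -110.0)
    rng = np.random.default_rng(34)
    x, y = rng.uniform(-2e4, 2e4, (2, 100))
    lon, lat = proj.inverse(x, y)
    x2, y2 = proj.forward(lon, lat)
    np.testing.assert_allclose(x2, x, atol=1e-6)
    np.testing.assert_allclose(y2, y, atol=1e-6)
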
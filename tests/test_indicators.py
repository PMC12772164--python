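"""Tests of indicator construction: daily series, anomaly chain, kernels, grids."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from shapely.geometry import LineString, Polygon

import fleetsentinel.indicators as ind
from fleetsentinel.geometry import EARTH_RADIUS_KM

from conftest import make_pings

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.195


def series(values, start="2020-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx, dtype=float)


def linked_pings(rows):
    df = make_pings(rows)
    if "allocated_pounds" not in df.columns:
        df["allocated_pounds"] = 1.0
    else:
        df["allocated_pounds"] = df["allocated_pounds"].fillna(1.0)
    return df


class TestDailyCentroid:
    def test_weighted_mean_latitude(self):
        df = linked_pings([
            {"timestamp": "2020-08-01 06:00", "lat": 40.0, "allocated_pounds": 1.0},
            {"timestamp": "2020-08-01 07:00", "lat": 46.0, "allocated_pounds": 2.0},
        ])
        assert ind.daily_effort_centroid(df).iloc[0] == pytest.approx(44.0)

    def test_equal_weights_give_midpoint(self):
        df = linked_pings([
            {"timestamp": "2020-08-01 06:00", "lat": 40.0},
            {"timestamp": "2020-08-01 07:00", "lat": 46.0},
        ])
        assert ind.daily_effort_centroid(df).iloc[0] == pytest.approx(43.0)

    def test_single_ping_and_zero_weight_day(self):
        df = linked_pings([
            {"timestamp": "2020-08-01 06:00", "lat": 41.5},
            {"timestamp": "2020-08-02 06:00", "lat": 45.0, "allocated_pounds": 0.0},
        ])
        s = ind.daily_effort_centroid(df)
        assert s.iloc[0] == pytest.approx(41.5)
        assert np.isnan(s.iloc[1])

    def test_centroid_within_daily_bounding_box(self):
        rng = np.random.default_rng(0)
        rows = []
        for d in range(5):
            for _ in range(20):
                rows.append({
                    "timestamp": pd.Timestamp("2020-08-01") + pd.Timedelta(days=d, hours=1),
                    "lat": float(rng.uniform(39, 48)),
                    "allocated_pounds": float(rng.uniform(0.1, 5.0)),
                })
        df = linked_pings(rows)
        s = ind.daily_effort_centroid(df)
        g = df.groupby(df["timestamp"].dt.normalize())["lat"]
        assert ((s >= g.min()) & (s <= g.max())).all()


class TestDistanceToShore:
    coast = LineString([(-124.0, 40.0), (-124.0, 48.0)])

    def offshore(self, km, lat=44.0):
        return -124.0 - km / (KM_PER_DEG * np.cos(np.radians(lat)))

    def test_weighted_mean_distance(self):
        df = linked_pings([
            {"timestamp": "2020-08-01 06:00", "lon": self.offshore(10.0), "allocated_pounds": 1.0},
            {"timestamp": "2020-08-01 07:00", "lon": self.offshore(40.0), "allocated_pounds": 3.0},
        ])
        s = ind.daily_distance_to_shore(df, self.coast)
        assert s.iloc[0] == pytest.approx(32.5, rel=5e-3)

    def test_ping_on_coastline_is_zero(self):
        df = linked_pings([{"timestamp": "2020-08-01 06:00", "lon": -124.0}])
        assert ind.daily_distance_to_shore(df, self.coast).iloc[0] == pytest.approx(0.0, abs=0.05)

    def test_equal_weights_midpoint(self):
        df = linked_pings([
            {"timestamp": "2020-08-01 06:00", "lon": self.offshore(10.0)},
            {"timestamp": "2020-08-01 07:00", "lon": self.offshore(40.0)},
        ])
        assert ind.daily_distance_to_shore(df, self.coast).iloc[0] == pytest.approx(25.0, rel=5e-3)

    def test_empty_coastline_rejected(self):
        df = linked_pings([{"timestamp": "2020-08-01 06:00"}])
        with pytest.raises(ValueError):
            ind.daily_distance_to_shore(df, LineString())


class TestDailyCpue:
    def test_pounds_per_minute(self):
        df = linked_pings([
            {"timestamp": "2020-08-01 06:00", "time_forward": 60.0, "allocated_pounds": 600.0},
            {"timestamp": "2020-08-01 07:00", "time_forward": 40.0, "allocated_pounds": 400.0},
        ])
        assert ind.daily_cpue(df).iloc[0] == pytest.approx(10.0)

    def test_zero_pounds_is_zero_not_missing(self):
        df = linked_pings([{"timestamp": "2020-08-01 06:00", "time_forward": 100.0,
                            "allocated_pounds": 0.0}])
        assert ind.daily_cpue(df).iloc[0] == 0.0

    def test_negative_input_rejected(self):
        df = linked_pings([{"timestamp": "2020-08-01 06:00", "allocated_pounds": -1.0}])
        with pytest.raises(ValueError):
            ind.daily_cpue(df)


class TestAnomalyChain:
    def test_self_climatology_gives_zero(self):
        s = series(np.tile(np.arange(30.0), 12))
        clim = ind.monthly_climatology(s)
        anom = ind.anomalize(s)
        months = s.index.month
        assert np.allclose(anom + pd.Series(months, index=s.index).map(clim), s)

    def test_two_july_years(self):
        idx = pd.DatetimeIndex(["2020-07-15", "2021-07-15"])
        s = pd.Series([14.0, 16.0], index=idx)
        anom = ind.anomalize(s)
        assert list(anom) == [-1.0, 1.0]

    def test_constant_shift_invariance(self):
        s = series(np.random.default_rng(1).normal(0, 1, 400))
        a0 = ind.anomalize(s)
        a1 = ind.anomalize(s + 17.3)
        assert np.allclose(a0, a1)

    def test_monthly_zero_mean_invariant(self):
        rng = np.random.default_rng(2)
        s = series(np.cumsum(rng.normal(0, 1, 4 * 365)), start="2016-01-01")
        anom = ind.anomalize(s)
        monthly = anom.groupby(anom.index.month).mean()
        assert (monthly.abs() < 1e-9).all()

    def test_smooth_constant(self):
        s = series(np.full(120, 3.3))
        assert np.allclose(ind.smooth(s).dropna(), 3.3)

    def test_smooth_impulse(self):
        v = np.zeros(120)
        v[50] = 30.0
        sm = ind.smooth(series(v))
        assert np.allclose(sm.iloc[50:80], 1.0)
        assert np.allclose(sm.iloc[80:], 0.0)

    def test_smooth_linear_ramp(self):
        s = series(np.arange(200.0))
        sm = ind.smooth(s)
        t = np.arange(200.0)
        assert np.allclose(sm.iloc[29:], t[29:] - 14.5)

    def test_smooth_coverage_threshold(self):
        v = np.full(120, 1.0)
        s = series(v)
        s.iloc[40:60] = np.nan  # 20-day hole
        sm = ind.smooth(s)
        # at day 59 only 10 of the last 30 days exist -> below 15-day coverage
        assert np.isnan(sm.iloc[59])
        assert sm.iloc[100] == pytest.approx(1.0)

    def test_smooth_white_noise_variance_reduction(self):
        rng = np.random.default_rng(3)
        s = series(rng.normal(0, 1, 4000))
        sm = ind.smooth(s).dropna()
        ratio = sm.var() / s.var()
        assert 0.02 < ratio < 0.05  # ~1/30

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            ind.smooth(series([1.0, 2.0]), window=0)

    def test_restrict_season_membership(self):
        idx = pd.DatetimeIndex(["2015-06-30", "2015-07-01", "2015-10-31", "2015-11-01"])
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        out = ind.restrict_season(s)
        assert list(out) == [2.0, 3.0]

    def test_season_2015_has_123_days(self):
        s = series(np.ones(365), start="2015-01-01")
        assert len(ind.restrict_season(s)) == 123

    def test_processing_order_is_smooth_then_restrict(self):
        """Restricting before smoothing changes season-edge values: early-July
        windows must see June data."""
        idx = pd.date_range("2019-01-01", "2020-12-31", freq="D")
        v = np.where(idx.month == 6, 100.0, 0.0)
        s = pd.Series(v, index=idx)
        correct = ind.restrict_season(ind.smooth(s))
        wrong = ind.smooth(ind.restrict_season(s))
        july = correct[(correct.index.month == 7) & (correct.index.day <= 10)]
        july_wrong = wrong.reindex(july.index)
        assert (july > 0).all()  # June spill-over visible
        assert not np.allclose(july, july_wrong, equal_nan=True)


class TestEffortKernel:
    @staticmethod
    def cloud(n=4000, seed=0):
        rng = np.random.default_rng(seed)
        lat = rng.normal(44.0, 1.0, n)
        lon = rng.normal(-127.0, 0.7, n)
        return pd.DataFrame({"lat": lat, "lon": lon,
                             "time_forward": rng.uniform(30, 90, n)})

    grid_lats = np.arange(38.125, 49.0, 0.25)
    grid_lons = np.arange(-130.875, -124.0, 0.25)

    def test_mass_captured_matches_percentile(self):
        df = self.cloud()
        mask = ind.effort_kernel_mask(df, self.grid_lats, self.grid_lons, percentile=0.75)
        ilat = np.clip(np.searchsorted(self.grid_lats - 0.125, df["lat"]) - 1, 0, len(self.grid_lats) - 1)
        ilon = np.clip(np.searchsorted(self.grid_lons - 0.125, df["lon"]) - 1, 0, len(self.grid_lons) - 1)
        inside = mask.values[ilat, ilon]
        frac = df.loc[inside, "time_forward"].sum() / df["time_forward"].sum()
        assert frac == pytest.approx(0.75, abs=0.05)

    def test_level_sets_nest(self):
        df = self.cloud(seed=1)
        m75 = ind.effort_kernel_mask(df, self.grid_lats, self.grid_lons, percentile=0.75)
        m90 = ind.effort_kernel_mask(df, self.grid_lats, self.grid_lons, percentile=0.90)
        assert bool((m90.values | ~m75.values).all())

    def test_full_percentile_covers_everything(self):
        df = self.cloud(seed=2)
        m = ind.effort_kernel_mask(df, self.grid_lats, self.grid_lons, percentile=1.0)
        assert bool(m.all())  # Gaussian density positive on every cell

    def test_too_few_pings_rejected(self):
        with pytest.raises(ValueError):
            ind.effort_kernel_mask(self.cloud(n=10), self.grid_lats, self.grid_lons)


def toy_field(values, lats, lons, days=1):
    t = pd.date_range("2020-07-01", periods=days, freq="D")
    return xr.DataArray(
        np.broadcast_to(np.asarray(values, dtype=float), (days, len(lats), len(lons))).copy(),
        coords={"time": t, "lat": list(lats), "lon": list(lons)},
        dims=("time", "lat", "lon"),
    )


class TestSstaSeries:
    def test_uniform_field_zero_anomaly(self):
        field = toy_field(np.full((3, 2), 15.0), [40, 41, 42], [-126, -125], days=90)
        mask = xr.ones_like(field.isel(time=0), dtype=bool)
        s = ind.ssta_series(field, mask, min_coverage=1)
        assert np.allclose(s.dropna(), 0.0)

    def test_single_cell_mask_reproduces_cell(self):
        rng = np.random.default_rng(4)
        field = toy_field(np.zeros((2, 2)), [40, 41], [-126, -125], days=60)
        field.values += rng.normal(0, 1, field.shape)
        mask = xr.zeros_like(field.isel(time=0), dtype=bool)
        mask[0, 0] = True
        s = ind.masked_mean_series(field, mask)
        assert np.allclose(s.values, field.values[:, 0, 0])

    def test_empty_mask_rejected(self):
        field = toy_field(np.zeros((2, 2)), [40, 41], [-126, -125])
        mask = xr.zeros_like(field.isel(time=0), dtype=bool)
        with pytest.raises(ValueError):
            ind.masked_mean_series(field, mask)


class TestHabitatIndicators:
    eez = Polygon([(-127, 39), (-124, 39), (-124, 44), (-127, 44)])
    coast = LineString([(-124.0, 38.0), (-124.0, 49.0)])

    def hotspot_field(self):
        lats = [40.0, 41.0, 42.0]
        lons = [-126.0, -125.0]
        field = toy_field(np.full((3, 2), 0.1), lats, lons, days=2)
        field.values[0, 1, 0] = 0.9  # day 0: hotspot at lat 41
        field.values[1, 2, 0] = 0.9  # day 1: hotspot at lat 42
        return field

    def test_hotspot_centroid_and_one_degree_move(self):
        out = ind.habitat_indicators(self.hotspot_field(), self.eez, self.coast)
        y = out["y"]
        assert y.iloc[0] == pytest.approx(41.0)
        assert y.iloc[1] - y.iloc[0] == pytest.approx(1.0)

    def test_uniform_field_has_empty_core(self):
        field = toy_field(np.full((3, 2), 0.5), [40, 41, 42], [-126, -125], days=1)
        out = ind.habitat_indicators(field, self.eez, self.coast)
        assert np.isnan(out["y"].iloc[0])

    def test_eez_mask_excludes_outside_cells(self):
        # hotspot outside the EEZ must not drive the centroid
        field = toy_field(np.full((3, 2), 0.1), [40.0, 41.0, 46.0], [-126.0, -125.0], days=1)
        field.values[0, 2, 0] = 0.9  # lat 46 is outside eez (cap 44)
        field.values[0, 1, 1] = 0.5
        out = ind.habitat_indicators(field, self.eez, self.coast)
        assert out["y"].iloc[0] == pytest.approx(41.0)

    def test_no_overlap_rejected(self):
        field = toy_field(np.full((2, 2), 0.5), [40, 41], [-126, -125])
        far = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        with pytest.raises(ValueError):
            ind.habitat_indicators(field, far, self.coast)


class TestGridEffort:
    def test_suppression_boundary(self):
        rows = []
        for i, vessel in enumerate(["A", "B", "C"]):   # 3 vessels -> suppressed
            rows.append({"timestamp": "2020-08-01 06:00", "vessel_id": vessel,
                         "lat": 44.01, "lon": -126.01, "time_forward": 60.0})
        for i, vessel in enumerate(["A", "B", "C", "D"]):  # 4 vessels -> kept
            rows.append({"timestamp": "2020-08-01 06:00", "vessel_id": vessel,
                         "lat": 45.01, "lon": -126.01, "time_forward": 60.0})
        df = make_pings(rows)
        ds = ind.grid_effort(df)
        hours = ds["hours"].to_series().dropna()
        assert len(hours) == 1
        assert hours.iloc[0] == pytest.approx(4.0)
        assert ds.attrs["suppressed_share"] == pytest.approx(3.0 / 7.0)

    def test_unsuppressed_hours_conserved(self, small_linked):
        ds = ind.grid_effort(small_linked, min_vessels=1)
        total = float(ds["hours"].sum())
        assert total == pytest.approx(small_linked["time_forward"].sum() / 60.0, rel=1e-9)


class TestAnnualCpue:
    def test_constant_years_zero_anomaly(self):
        idx = pd.date_range("2018-01-01", "2020-12-31", freq="D")
        s = pd.Series(10.0, index=idx)
        out = ind.annual_cpue(s)
        assert np.allclose(out["cpue"], 10.0)
        assert np.allclose(out["anomaly"], 0.0)

    def test_poor_year_shows_negative_anomaly(self):
        idx = pd.date_range("2018-01-01", "2021-12-31", freq="D")
        s = pd.Series(10.0, index=idx)
        s[s.index.year == 2021] = 5.0
        out = ind.annual_cpue(s)
        assert out.loc[2021, "anomaly"] == pytest.approx(5.0 - np.mean([10, 10, 10, 5]))
        assert out.loc[2021, "anomaly"] < 0
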
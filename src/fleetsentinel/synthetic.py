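"""Synthetic scenario generator for the sentinel-fleet analysis.

Emulates the study system: a U.S. West Coast-like albacore troll fleet
tracked by hourly VMS pings, shoreside landings receipts, daily gridded
SST and tuna habitat-suitability fields, and daily economic driver series
(fuel price, weather-alert area, ex-vessel price).  Heatwave years carry a
warm SST anomaly during the July-October fishing season and a northward /
inshore shift of the habitat blob; the fleet follows habitat with a
configurable mixing weight, so every downstream stage (linkage filters,
indicator construction, SEDI skill, driver regression) can be tested
against known ground truth.

Everything is deterministic given ``ScenarioConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import LineString, Polygon

# Spatial domain: a Pacific Northwest-like box with a straight synthetic
# coastline along its eastern edge.
LON_MIN, LON_MAX = -131.0, -124.0
LAT_MIN, LAT_MAX = 38.0, 49.0
COAST_LON = -124.0
KM_PER_DEG_LAT = 111.32

SEASON_MONTHS = (7, 8, 9, 10)


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth parameters of a synthetic scenario.

    Defaults mirror the study system: a 15-year record (2010-2024) with the
    2014-2016 marine-heatwave years, ~hourly pings, a ~1.5 degC seasonal warm
    anomaly, a 1.5 degree northward habitat shift in heatwave years, a fleet
    that follows habitat with weight 0.8, and a baseline catch rate of
    7.8 lbs of albacore per fishing minute that drops to ~54% of baseline
    in heatwave seasons.
    """

    years: tuple[int, int] = (2010, 2024)
    n_vessels: int = 25
    ping_interval: float = 60.0          # minutes, nominal
    heatwave_years: tuple[int, ...] = (2014, 2015, 2016)
    ssta_amplitude: float = 1.5          # degC added during heatwave fishing seasons
    habitat_shift_lat: float = 1.5       # degrees northward in heatwave years
    habitat_shift_shore: float = 30.0    # km inshore (toward the coast) in heatwave years
    effort_tracking: float = 0.8         # fraction of trips placed on habitat vs uniform
    cpue_base: float = 7.8               # lbs of albacore per fishing minute
    cpue_heatwave_factor: float = 0.54   # multiplier on cpue_base in heatwave years
    grid_resolution: float = 0.25        # degrees
    seed: int = 0

    # Fleet behaviour / data-quality knobs (not part of the headline truth,
    # but they exercise every linkage filter).
    trips_per_season: float = 6.0
    mean_trip_days: float = 7.0
    gap_fraction: float = 0.05           # fraction of pings starting a >121-min signal break
    flag_fraction: float = 0.02          # fraction of pings carrying the GIS quality flag
    fail_90_fraction: float = 0.15       # fraction of receipts below the 90% albacore rule
    fishing_speed: tuple[float, float] = (2.0, 0.7)   # knots, mean/sd (clipped < 3.5)
    transit_speed: tuple[float, float] = (8.0, 1.0)   # knots, mean/sd
    driver_betas: Mapping[str, float] = field(default_factory=dict)
    driver_gap_fraction: float = 0.03
    driver_lat_scale: float = 1.0        # degrees of ground shift per unit driver z-score

    def validate(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("years: end before start")
        if any(y < y0 or y > y1 for y in self.heatwave_years):
            raise ValueError("heatwave_years: must be a subset of years")
        if not (0.0 <= self.effort_tracking <= 1.0):
            raise ValueError("effort_tracking: must lie in [0, 1]")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution: must be positive")
        if self.n_vessels < 1:
            raise ValueError("n_vessels: must be at least 1")
        if self.ping_interval <= 0:
            raise ValueError("ping_interval: must be positive")
        if not (0.0 < self.cpue_heatwave_factor <= 1.0):
            raise ValueError("cpue_heatwave_factor: must lie in (0, 1]")
        for name in ("gap_fraction", "flag_fraction", "fail_90_fraction", "driver_gap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}: must lie in [0, 1]")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ScenarioBundle:
    """Everything one scenario emits, plus the truth that generated it."""

    pings: pd.DataFrame
    receipts: pd.DataFrame
    sst: xr.DataArray
    habitat: xr.Dataset
    drivers: pd.DataFrame
    coastline: LineString
    eez: Polygon
    truth: ScenarioConfig
    trips: pd.DataFrame


def _seedseqs(config: ScenarioConfig) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(config.seed).spawn(3)


def _dates(config: ScenarioConfig) -> pd.DatetimeIndex:
    y0, y1 = config.years
    return pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")


def heatwave_weight(dates: pd.DatetimeIndex, heatwave_years: Sequence[int]) -> np.ndarray:
    """Heatwave forcing weight per day: 1 during Jul-Oct of heatwave years,
    linear shoulders over June and November, 0 elsewhere.

    The shoulders keep the 30-day right-aligned smoother from seeing a hard
    step at the season edge while leaving the in-season mean forcing exactly
    equal to the configured amplitude.
    """
    w = np.zeros(len(dates))
    in_hw = np.isin(dates.year, list(heatwave_years))
    month = dates.month.values
    day = dates.day.values
    w[in_hw & np.isin(month, SEASON_MONTHS)] = 1.0
    june = in_hw & (month == 6)
    w[june] = day[june] / 30.0
    nov = in_hw & (month == 11)
    w[nov] = 1.0 - day[nov] / 30.0
    return w


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with innovation sd ``sd``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sd, n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def default_coastline() -> LineString:
    return LineString([(COAST_LON, LAT_MIN), (COAST_LON, LAT_MAX)])


def default_eez() -> Polygon:
    return Polygon(
        [
            (COAST_LON, LAT_MIN + 0.5),
            (-130.0, LAT_MIN + 0.5),
            (-130.0, LAT_MAX - 0.5),
            (COAST_LON, LAT_MAX - 0.5),
        ]
    )


def _habitat_centers(config: ScenarioConfig, dates: pd.DatetimeIndex, rng: np.random.Generator,
                     base_lat: float) -> tuple[np.ndarray, np.ndarray]:
    """Daily (lat, lon) centre of one species' suitability blob."""
    doy = dates.dayofyear.values
    w = heatwave_weight(dates, config.heatwave_years)
    seasonal = 1.0 * np.cos(2.0 * np.pi * (doy - 250) / 365.25)
    jitter_lat = _ar1(rng, len(dates), 0.8, 0.10)
    jitter_lon = _ar1(rng, len(dates), 0.8, 0.08)
    shift_lon = config.habitat_shift_shore / (KM_PER_DEG_LAT * np.cos(np.radians(base_lat)))
    lat_c = base_lat + seasonal + config.habitat_shift_lat * w + jitter_lat
    lon_c = -126.5 + shift_lon * w + jitter_lon   # eastward = inshore
    return lat_c, lon_c


def _gen_fields(config: ScenarioConfig, dates: pd.DatetimeIndex,
                rng: np.random.Generator) -> tuple[xr.DataArray, xr.Dataset, dict]:
    res = config.grid_resolution
    lats = np.arange(LAT_MIN + res / 2.0, LAT_MAX, res)
    lons = np.arange(LON_MIN + res / 2.0, LON_MAX, res)
    doy = dates.dayofyear.values
    w = heatwave_weight(dates, config.heatwave_years)

    # SST: seasonal cycle + meridional gradient + heatwave anomaly + AR(1) noise
    base_t = 12.0 + 5.0 * np.cos(2.0 * np.pi * (doy - 235) / 365.25)
    noise_t = _ar1(rng, len(dates), 0.8, 0.15)
    sst = (
        base_t[:, None, None]
        + (-0.4 * (lats - 43.0))[None, :, None]
        + (config.ssta_amplitude * w + noise_t)[:, None, None]
        + rng.normal(0.0, 0.2, (len(dates), len(lats), len(lons)))
    ).astype(np.float32)
    sst_da = xr.DataArray(
        sst,
        coords={"time": dates, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name="sst",
        attrs={"units": "degC", "long_name": "sea surface temperature"},
    )

    # Habitat suitability: Gaussian blob per species whose centre migrates
    # seasonally and shifts north/inshore in heatwave years.
    centers = {}
    hab_vars = {}
    for species, base_lat in (("albacore", 42.5), ("bluefin", 41.0)):
        lat_c, lon_c = _habitat_centers(config, dates, rng, base_lat)
        centers[species] = (lat_c, lon_c)
        sig_lat, sig_lon = 1.5, 1.2
        suit = np.exp(
            -(
                (lats[None, :, None] - lat_c[:, None, None]) ** 2 / (2 * sig_lat**2)
                + (lons[None, None, :] - lon_c[:, None, None]) ** 2 / (2 * sig_lon**2)
            )
        )
        suit = suit * (1.0 + rng.normal(0.0, 0.05, suit.shape))
        hab_vars[species] = xr.DataArray(
            np.clip(suit, 0.0, 1.0).astype(np.float32),
            coords={"time": dates, "lat": lats, "lon": lons},
            dims=("time", "lat", "lon"),
            attrs={"long_name": f"{species} habitat suitability", "units": "1"},
        )
    habitat = xr.Dataset(hab_vars)
    return sst_da, habitat, centers


def gen_drivers(config: ScenarioConfig) -> pd.DataFrame:
    """Daily economic/weather driver series with AR(1) persistence and gaps.

    Columns: ``fuel_price`` (USD/gallon), ``alert_area`` (km^2 of coastal
    waters under weather alerts), ``price_per_pound`` (USD).  A configurable
    fraction of days is set missing to exercise gap interpolation.
    """
    config.validate()
    rng = np.random.default_rng(_seedseqs(config)[1])
    dates = _dates(config)
    n = len(dates)
    fuel = 3.5 + _ar1(rng, n, 0.97, 0.03)
    alerts = np.clip(5000.0 + _ar1(rng, n, 0.90, 600.0), 0.0, None)
    price = np.clip(2.5 + _ar1(rng, n, 0.95, 0.04), 0.2, None)
    df = pd.DataFrame(
        {"fuel_price": fuel, "alert_area": alerts, "price_per_pound": price},
        index=dates,
    )
    df.index.name = "date"
    if config.driver_gap_fraction > 0:
        gap = rng.random(n) < config.driver_gap_fraction
        df.loc[gap, :] = np.nan
    return df


def _driver_effect(config: ScenarioConfig, drivers: pd.DataFrame) -> pd.Series:
    """Latitude offset (degrees) of fishing grounds implied by driver_betas."""
    if not config.driver_betas:
        return pd.Series(0.0, index=drivers.index)
    effect = pd.Series(0.0, index=drivers.index)
    for name, beta in config.driver_betas.items():
        if name not in drivers.columns:
            raise ValueError(f"driver_betas: unknown driver '{name}'")
        x = drivers[name].interpolate(limit_direction="both")
        z = (x - x.mean()) / x.std(ddof=1)
        effect = effect + beta * z
    return config.driver_lat_scale * effect


def _simulate_fleet(config: ScenarioConfig, dates: pd.DatetimeIndex,
                    centers: dict, drivers: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate trips: port departure -> transit -> fishing -> return, one
    receipt per trip, pings at ~ping_interval with injected gaps and flags."""
    y0, y1 = config.years
    alb_lat, alb_lon = centers["albacore"]
    date_pos = pd.Series(np.arange(len(dates)), index=dates)
    lat_offset = _driver_effect(config, drivers).values

    vessels = [f"V{i:03d}" for i in range(config.n_vessels)]
    port_lats = rng.uniform(40.0, 47.0, config.n_vessels)

    ping_frames: list[pd.DataFrame] = []
    receipt_rows: list[dict] = []
    trip_rows: list[dict] = []
    ticket_counter = 0

    fish_mu, fish_sd = config.fishing_speed
    trans_mu, trans_sd = config.transit_speed

    for vi, vessel in enumerate(vessels):
        port_lat = port_lats[vi]
        vessel_pings: list[pd.DataFrame] = []
        for year in range(y0, y1 + 1):
            heat = year in config.heatwave_years
            rate = config.cpue_base * (config.cpue_heatwave_factor if heat else 1.0)
            n_trips = 1 + rng.poisson(max(config.trips_per_season - 1.0, 0.0))
            starts = np.sort(rng.uniform(0.0, 1.0, n_trips))
            window0 = pd.Timestamp(f"{year}-06-15")
            window_days = (pd.Timestamp(f"{year}-10-25") - window0).days
            t_cursor = window0
            for s in starts:
                depart = window0 + pd.Timedelta(days=float(s * window_days)) + pd.Timedelta(
                    hours=float(rng.uniform(5, 9))
                )
                if depart <= t_cursor:
                    depart = t_cursor + pd.Timedelta(hours=float(rng.uniform(12, 36)))
                duration = float(np.clip(rng.gamma(4.0, config.mean_trip_days / 4.0), 2.0, 14.0))
                ret = depart + pd.Timedelta(days=duration)
                if ret > pd.Timestamp(f"{year}-11-28"):
                    break
                t_cursor = ret + pd.Timedelta(hours=float(rng.uniform(18, 60)))

                # fishing ground: follow habitat with weight effort_tracking
                mid_day = depart + (ret - depart) / 2
                di = int(date_pos.get(mid_day.normalize(), len(dates) - 1))
                if rng.random() < config.effort_tracking:
                    g_lat = alb_lat[di] + lat_offset[di] + rng.normal(0.0, 0.5)
                    g_lon = alb_lon[di] + rng.normal(0.0, 0.4)
                else:
                    g_lat = rng.uniform(LAT_MIN + 1.0, LAT_MAX - 0.5)
                    g_lon = rng.uniform(LON_MIN + 1.0, COAST_LON - 0.5)
                g_lat = float(np.clip(g_lat, LAT_MIN + 0.5, LAT_MAX - 0.5))
                g_lon = float(np.clip(g_lon, LON_MIN + 0.5, COAST_LON - 0.3))

                # ping skeleton
                total_min = (ret - depart).total_seconds() / 60.0
                n_pings = max(int(total_min / config.ping_interval), 8)
                incr = np.maximum(rng.normal(config.ping_interval, config.ping_interval * 0.05, n_pings), 1.0)
                t_min = np.concatenate([[0.0], np.cumsum(incr)])
                t_min = t_min[t_min < total_min]
                n = len(t_min)
                n_transit = max(int(round(0.12 * n)), 2)
                phase = np.full(n, "fishing", dtype=object)
                phase[:n_transit] = "transit"
                phase[-n_transit:] = "transit"
                phase[0] = "depart"

                frac_out = np.linspace(0.0, 1.0, n_transit)
                lat = np.empty(n)
                lon = np.empty(n)
                lat[:n_transit] = port_lat + frac_out * (g_lat - port_lat)
                lon[:n_transit] = COAST_LON + frac_out * (g_lon - COAST_LON)
                lat[-n_transit:] = g_lat + frac_out * (port_lat - g_lat)
                lon[-n_transit:] = g_lon + frac_out * (COAST_LON - g_lon)
                n_fish = n - 2 * n_transit
                if n_fish > 0:
                    lat[n_transit:n - n_transit] = g_lat + rng.normal(0.0, 0.15, n_fish)
                    lon[n_transit:n - n_transit] = g_lon + rng.normal(0.0, 0.12, n_fish)
                lat = np.clip(lat, LAT_MIN + 0.01, LAT_MAX - 0.01)
                lon = np.clip(lon, LON_MIN + 0.01, COAST_LON - 0.01)

                speed = np.where(
                    phase == "fishing",
                    np.clip(np.abs(rng.normal(fish_mu, fish_sd, n)), 0.05, 3.5),
                    np.clip(rng.normal(trans_mu, trans_sd, n), 5.0, 12.0),
                )
                speed[0] = 1.0

                # signal breaks: drop short runs of pings so the preceding
                # ping's time-forward exceeds the 121-min cut
                keep = np.ones(n, dtype=bool)
                gap_starts = np.flatnonzero(rng.random(n) < config.gap_fraction / 2.5)
                for g in gap_starts:
                    keep[g + 1 : g + 1 + int(rng.integers(2, 4))] = False
                keep[0] = True

                times = depart + pd.to_timedelta(t_min, unit="m")
                trip_id = f"{vessel}-{year}-{len(trip_rows)}"
                df = pd.DataFrame(
                    {
                        "timestamp": times[keep],
                        "vessel_id": vessel,
                        "lat": lat[keep],
                        "lon": lon[keep],
                        "event_type": np.where(phase[keep] == "depart", "departing_port", "at_sea"),
                        "speed": speed[keep],
                        "phase": phase[keep],
                        "trip_id": trip_id,
                    }
                )
                vessel_pings.append(df)

                # in-port pings after return
                port_times = ret + pd.to_timedelta(np.arange(2, 26, 6), unit="h")
                vessel_pings.append(
                    pd.DataFrame(
                        {
                            "timestamp": port_times,
                            "vessel_id": vessel,
                            "lat": port_lat,
                            "lon": COAST_LON - 0.005,
                            "event_type": "in_port",
                            "speed": 0.0,
                            "phase": "port",
                            "trip_id": trip_id,
                        }
                    )
                )

                ticket_counter += 1
                trip_rows.append(
                    {
                        "trip_id": trip_id,
                        "vessel_id": vessel,
                        "year": year,
                        "depart": depart,
                        "ret": ret,
                        "ground_lat": g_lat,
                        "ground_lon": g_lon,
                        "rate": rate,
                        "ticket_id": f"T{ticket_counter:06d}",
                    }
                )

        if not vessel_pings:
            continue
        vdf = pd.concat(vessel_pings, ignore_index=True).sort_values("timestamp", kind="stable")
        tf = vdf["timestamp"].diff().shift(-1).dt.total_seconds() / 60.0
        vdf["time_forward"] = tf.fillna(config.ping_interval).clip(lower=0.0)
        ping_frames.append(vdf)

    pings = pd.concat(ping_frames, ignore_index=True)
    pings["gis_flag"] = rng.random(len(pings)) < config.flag_fraction
    pings = pings[
        ["timestamp", "vessel_id", "lat", "lon", "event_type", "time_forward", "speed",
         "gis_flag", "phase", "trip_id"]
    ]

    trips = pd.DataFrame(trip_rows)

    # Receipts: pounds = rate x sum of time-forward over the trip's pings that
    # survive every fishing filter (at-sea, unflagged, gap <= 121, speed < 3.74).
    fishing_ok = (
        (pings["event_type"] == "at_sea")
        & ~pings["gis_flag"]
        & (pings["time_forward"] <= 121.0)
        & (pings["speed"] < 3.74)
        & (pings["phase"] == "fishing")
    )
    fish_min = pings.loc[fishing_ok].groupby("trip_id")["time_forward"].sum()
    price_series = drivers["price_per_pound"].interpolate(limit_direction="both")
    for row in trips.itertuples():
        minutes = float(fish_min.get(row.trip_id, 0.0))
        alb = row.rate * minutes
        price = float(price_series.get(row.ret.normalize(), 2.5))
        receipt_rows.append(
            {
                "timestamp": row.ret,
                "vessel_id": row.vessel_id,
                "ticket_id": row.ticket_id,
                "species": "albacore",
                "pounds": alb,
                "price_per_pound": price,
            }
        )
        if rng.random() < config.fail_90_fraction:
            frac_other = rng.uniform(0.12, 0.5)
        else:
            frac_other = rng.uniform(0.0, 0.08)
        other = alb * frac_other / (1.0 - frac_other) if frac_other > 0 else 0.0
        if other > 0:
            receipt_rows.append(
                {
                    "timestamp": row.ret,
                    "vessel_id": row.vessel_id,
                    "ticket_id": row.ticket_id,
                    "species": "other",
                    "pounds": other,
                    "price_per_pound": round(price * 0.6, 2),
                }
            )
    receipts = pd.DataFrame(receipt_rows)
    return pings, receipts, trips


def gen_scenario(config: ScenarioConfig | None = None, **overrides) -> ScenarioBundle:
    """Generate a full scenario bundle from a config (or keyword overrides)."""
    if config is None:
        config = ScenarioConfig(**overrides)
    elif overrides:
        config = config.replace(**overrides)
    config.validate()
    ss = _seedseqs(config)
    dates = _dates(config)

    rng_fields = np.random.default_rng(ss[0])
    sst, habitat, centers = _gen_fields(config, dates, rng_fields)

    drivers = gen_drivers(config)

    rng_fleet = np.random.default_rng(ss[2])
    pings, receipts, trips = _simulate_fleet(config, dates, centers, drivers, rng_fleet)

    return ScenarioBundle(
        pings=pings,
        receipts=receipts,
        sst=sst,
        habitat=habitat,
        drivers=drivers,
        coastline=default_coastline(),
        eez=default_eez(),
        truth=config,
        trips=trips,
    )


def gen_regression_case(
    n_days: int = 400,
    betas: Mapping[str, float] | None = None,
    noise_sd: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Standardized predictors plus a response with known standardized effects.

    The response is ``sum_i beta_i * z_i + N(0, noise_sd)`` over iid standard
    normal predictors, giving an exact ground truth for regression-recovery
    tests of the driver-attribution stage.
    """
    if betas is None:
        betas = {"habitat_y": 0.4, "ssta": 0.0, "fuel_price": 0.0,
                 "alert_area": 0.0, "price_per_pound": 0.0}
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2015-01-01", periods=n_days, freq="D")
    X = {name: rng.normal(0.0, 1.0, n_days) for name in betas}
    y = sum(b * X[name] for name, b in betas.items()) + rng.normal(0.0, noise_sd, n_days)
    df = pd.DataFrame({**X, "response": y}, index=dates)
    df.index.name = "date"
    return df, dict(betas)
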
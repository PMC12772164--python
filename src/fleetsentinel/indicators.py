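"""Daily and annual indicator time-series for fleet and habitat.

Three fleet series summarise the linked VMS-landings data — the
pounds-weighted latitudinal (Y) centroid, the pounds-weighted mean distance
to shore, and catch per unit effort (CPUE, pounds per minute) — alongside a
sea-surface-temperature anomaly (SSTa) averaged over the fleet's
kernel-density effort footprint and habitat-suitability centroids masked to
the EEZ and thresholded to core habitat.  Every daily series runs through
one processing chain, in this order: raw values, anomalies relative to a
monthly climatology, a 30-day right-aligned rolling mean, and restriction
to the July-October fishing season.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from scipy import stats
from shapely.geometry import LineString, Polygon

from fleetsentinel.geometry import distance_to_coast_km

logger = logging.getLogger(__name__)

SEASON_MONTHS = (7, 8, 9, 10)


def quantile_nearest(values: np.ndarray, p: float) -> float:
    """Nearest-rank (inverse empirical CDF) percentile; one definition package-wide."""
    return float(np.quantile(np.asarray(values), p, method="inverted_cdf"))


# ---------------------------------------------------------------------------
# fleet series (raw)
# ---------------------------------------------------------------------------

def _daily_weighted_mean(linked: pd.DataFrame, value_col: str, weight_col: str) -> pd.Series:
    df = linked[[value_col, weight_col]].copy()
    df["day"] = linked["timestamp"].dt.normalize()
    df["wv"] = df[value_col] * df[weight_col]
    g = df.groupby("day")[["wv", weight_col]].sum()
    w = g[weight_col]
    out = g["wv"].where(w > 0) / w.where(w > 0)
    if (w <= 0).any():
        logger.info("%d day(s) with zero weight -> missing", int((w <= 0).sum()))
    out.index.name = "date"
    return out


def daily_effort_centroid(linked: pd.DataFrame, weight_col: str = "allocated_pounds") -> pd.Series:
    """Per day, the latitude of the pounds-weighted mean fleet position."""
    s = _daily_weighted_mean(linked, "lat", weight_col)
    s.name = "vms_y"
    return s


def daily_distance_to_shore(
    linked: pd.DataFrame,
    coastline: LineString,
    weight_col: str = "allocated_pounds",
) -> pd.Series:
    """Per day, the pounds-weighted mean great-circle distance (km) to the coastline."""
    if coastline is None or coastline.is_empty:
        raise ValueError("coastline geometry required")
    df = linked.copy()
    df["shore_km"] = distance_to_coast_km(df["lat"].to_numpy(), df["lon"].to_numpy(), coastline)
    s = _daily_weighted_mean(df, "shore_km", weight_col)
    s.name = "vms_shore"
    return s


def daily_cpue(linked: pd.DataFrame) -> pd.Series:
    """Per day, summed allocated pounds divided by summed time-forward minutes."""
    if (linked["allocated_pounds"] < 0).any() or (linked["time_forward"] < 0).any():
        raise ValueError("negative pounds or minutes in linked pings")
    df = linked[["allocated_pounds", "time_forward"]].copy()
    df["day"] = linked["timestamp"].dt.normalize()
    g = df.groupby("day").sum()
    s = g["allocated_pounds"].where(g["time_forward"] > 0) / g["time_forward"].where(g["time_forward"] > 0)
    s.index.name = "date"
    s.name = "vms_cpue"
    return s


# ---------------------------------------------------------------------------
# anomaly chain
# ---------------------------------------------------------------------------

def monthly_climatology(series: pd.Series, period: tuple[int, int] | None = None) -> pd.Series:
    """Per-calendar-month mean over the climatology period (default: full record)."""
    s = series.dropna()
    if period is not None:
        s = s[(s.index.year >= period[0]) & (s.index.year <= period[1])]
    return s.groupby(s.index.month).mean()


def anomalize(series: pd.Series, climatology_period: tuple[int, int] | None = None) -> pd.Series:
    """Daily anomaly relative to the monthly climatology.

    Months absent from the climatology yield missing anomalies (logged).
    """
    clim = monthly_climatology(series, climatology_period)
    base = pd.Series(series.index.month, index=series.index).map(clim)
    missing_months = set(range(1, 13)) - set(clim.index)
    if missing_months and series.index.month.isin(missing_months).any():
        logger.warning("no climatology for month(s) %s; anomalies there are missing",
                       sorted(missing_months))
    out = series - base
    out.name = series.name
    return out


def smooth(series: pd.Series, window: int = 30, min_coverage: int | None = None) -> pd.Series:
    """Right-aligned rolling mean over ``window`` days on a regular daily axis.

    The value at day t averages the available values in [t-window+1, t] and
    is emitted only when at least ``min_coverage`` of those days are present
    (default: half the window).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_coverage is None:
        min_coverage = max(window // 2, 1)
    full = series.reindex(pd.date_range(series.index.min(), series.index.max(), freq="D"))
    out = full.rolling(window, min_periods=min_coverage).mean()
    out.index.name = "date"
    out.name = series.name
    return out


def restrict_season(series: pd.Series, months: tuple[int, ...] = SEASON_MONTHS) -> pd.Series:
    """Keep only days whose calendar month is in the fishing season."""
    return series[series.index.month.isin(months)]


def process_series(
    raw: pd.Series,
    climatology_period: tuple[int, int] | None = None,
    window: int = 30,
    min_coverage: int | None = None,
    months: tuple[int, ...] = SEASON_MONTHS,
) -> pd.Series:
    """raw -> anomalize -> smooth -> restrict_season (fixed order)."""
    return restrict_season(
        smooth(anomalize(raw, climatology_period), window, min_coverage), months
    )


# ---------------------------------------------------------------------------
# effort kernel and environmental series
# ---------------------------------------------------------------------------

def effort_kernel_mask(
    pings: pd.DataFrame,
    grid_lats: np.ndarray,
    grid_lons: np.ndarray,
    percentile: float = 0.75,
    weight_col: str = "time_forward",
    max_points: int = 20000,
    subsample_seed: int = 0,
) -> xr.DataArray:
    """Boolean mask of grid cells inside the fleet's effort-kernel level set.

    A weighted Gaussian KDE with a full anisotropic bandwidth matrix
    (weighted data covariance scaled by Scott's factor) is evaluated at the
    cell centres; densities are normalized to sum to one, ranked descending,
    and cells are kept while the cumulative probability of use stays at or
    below ``percentile``.  Large ping sets are subsampled (deterministically)
    before the KDE for speed.
    """
    df = pings.dropna(subset=["lat", "lon", weight_col])
    if len(df) < 30:
        raise ValueError("need at least 30 weighted pings for a kernel estimate")
    if len(df) > max_points:
        rng = np.random.default_rng(subsample_seed)
        df = df.iloc[rng.choice(len(df), max_points, replace=False)]
    xy = np.vstack([df["lon"].to_numpy(), df["lat"].to_numpy()])
    w = df[weight_col].to_numpy(dtype=float)
    try:
        kde = stats.gaussian_kde(xy, weights=w)
    except np.linalg.LinAlgError:
        logger.warning("degenerate ping cloud; applying bandwidth floor jitter")
        rng = np.random.default_rng(subsample_seed)
        kde = stats.gaussian_kde(xy + rng.normal(0.0, 1e-4, xy.shape), weights=w)
    glon, glat = np.meshgrid(np.asarray(grid_lons), np.asarray(grid_lats))
    dens = kde(np.vstack([glon.ravel(), glat.ravel()]))
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel density is zero everywhere on the grid")
    dens = dens / total
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order])
    keep_sorted = (cum <= percentile + 1e-12) & (dens[order] > 0)
    mask_flat = np.zeros(dens.size, dtype=bool)
    mask_flat[order[keep_sorted]] = True
    return xr.DataArray(
        mask_flat.reshape(glat.shape),
        coords={"lat": np.asarray(grid_lats), "lon": np.asarray(grid_lons)},
        dims=("lat", "lon"),
        name="effort_kernel",
        attrs={"percentile": percentile},
    )


def masked_mean_series(field: xr.DataArray, mask: xr.DataArray) -> pd.Series:
    """Daily area-mean of a gridded field over the masked cells."""
    if not bool(mask.any()):
        raise ValueError("mask selects no cells")
    s = field.where(mask).mean(("lat", "lon")).to_series()
    s.index = pd.DatetimeIndex(s.index).normalize()
    s.index.name = "date"
    return s


def ssta_series(
    sst: xr.DataArray,
    mask: xr.DataArray,
    climatology_period: tuple[int, int] | None = None,
    window: int = 30,
    min_coverage: int | None = None,
) -> pd.Series:
    """SST anomaly within the effort kernel: mask -> area mean -> anomalize -> smooth."""
    s = masked_mean_series(sst, mask)
    out = smooth(anomalize(s, climatology_period), window, min_coverage)
    out.name = "ssta"
    return out


def habitat_indicators(
    suitability: xr.DataArray,
    eez: Polygon,
    coastline: LineString,
    core_percentile: float = 0.75,
    per_day: bool = True,
) -> dict[str, pd.Series]:
    """Raw daily core-habitat centroid latitude and mean distance to shore.

    Suitability is masked to the EEZ; core habitat each day is the set of
    cells whose value strictly exceeds that day's nearest-rank
    ``core_percentile`` threshold (or one pooled threshold if
    ``per_day=False``); the surviving cells are summarised by their
    suitability-weighted mean latitude and suitability-weighted mean
    distance to the coastline.  Days with an empty core are missing.
    """
    lats = suitability["lat"].values
    lons = suitability["lon"].values
    glon, glat = np.meshgrid(lons, lats)
    in_eez = shapely.contains_xy(eez, glon.ravel(), glat.ravel()).reshape(glat.shape)
    if not in_eez.any():
        raise ValueError("EEZ polygon does not overlap the grid")
    shore_km = distance_to_coast_km(glat, glon, coastline)

    v = suitability.values.astype(float)
    v = np.where(in_eez[None, :, :], v, np.nan)
    flat = v.reshape(v.shape[0], -1)
    if per_day:
        thr = np.nanquantile(flat, core_percentile, axis=1, method="inverted_cdf")
    else:
        thr_val = quantile_nearest(flat[np.isfinite(flat)], core_percentile)
        thr = np.full(flat.shape[0], thr_val)
    w = np.where(flat > thr[:, None], flat, 0.0)
    w = np.where(np.isfinite(w), w, 0.0)
    wsum = w.sum(axis=1)
    empty = wsum <= 0
    if empty.any():
        logger.info("%d day(s) with empty core habitat -> missing", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(empty, np.nan, (w * glat.ravel()[None, :]).sum(axis=1) / wsum)
        shore = np.where(empty, np.nan, (w * shore_km.ravel()[None, :]).sum(axis=1) / wsum)
    idx = pd.DatetimeIndex(suitability["time"].values).normalize()
    idx.name = "date"
    return {
        "y": pd.Series(y, index=idx, name="habitat_y"),
        "shore": pd.Series(shore, index=idx, name="habitat_shore"),
    }


# ---------------------------------------------------------------------------
# effort grid and annual CPUE
# ---------------------------------------------------------------------------

def grid_effort(
    linked: pd.DataFrame,
    resolution: float = 0.1,
    min_vessels: int = 4,
) -> xr.Dataset:
    """Effort hours per grid cell with confidentiality suppression.

    Sums time-forward (as hours) per ``resolution``-degree cell; cells with
    fewer than ``min_vessels`` distinct vessels are suppressed (set missing).
    The fraction of effort hours suppressed is reported in the attrs.
    """
    df = linked.copy()
    df["cell_lat"] = np.floor(df["lat"] / resolution) * resolution
    df["cell_lon"] = np.floor(df["lon"] / resolution) * resolution
    g = df.groupby(["cell_lat", "cell_lon"]).agg(
        hours=("time_forward", lambda x: x.sum() / 60.0),
        n_vessels=("vessel_id", "nunique"),
    )
    total = g["hours"].sum()
    suppressed = g["n_vessels"] < min_vessels
    share = float(g.loc[suppressed, "hours"].sum() / total) if total > 0 else 0.0
    g.loc[suppressed, "hours"] = np.nan
    ds = xr.Dataset.from_dataframe(g)
    ds = ds.rename({"cell_lat": "lat", "cell_lon": "lon"})
    ds.attrs.update({"resolution_deg": resolution, "min_vessels": min_vessels,
                     "suppressed_share": share})
    return ds


def annual_cpue(cpue_raw: pd.Series, months: tuple[int, ...] = SEASON_MONTHS) -> pd.DataFrame:
    """Annual fishing-season CPUE means and their anomalies across years.

    The anomaly baseline is the across-year mean of the annual season means,
    so a year at half the others' catch rate shows up as a large negative
    anomaly the October it becomes computable.
    """
    season = restrict_season(cpue_raw.dropna(), months)
    if season.empty:
        return pd.DataFrame(columns=["cpue", "anomaly"])
    means = season.groupby(season.index.year).mean()
    out = pd.DataFrame({"cpue": means})
    out["anomaly"] = out["cpue"] - out["cpue"].mean()
    out.index.name = "year"
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_indicators(
    linked: pd.DataFrame,
    sst: xr.DataArray | None = None,
    habitat: xr.Dataset | None = None,
    coastline: LineString | None = None,
    eez: Polygon | None = None,
    drivers: pd.DataFrame | None = None,
    climatology_period: tuple[int, int] | None = None,
    window: int = 30,
    min_coverage: int | None = None,
    months: tuple[int, ...] = SEASON_MONTHS,
    kernel_percentile: float = 0.75,
    core_percentile: float = 0.75,
    compute: list[str] | None = None,
) -> dict[str, pd.Series]:
    """Build the processed (anomaly, smoothed, season-restricted) indicator set.

    Returns a dict keyed by indicator name: ``vms_y``, ``vms_shore``,
    ``vms_cpue``, ``ssta``, ``habitat_y:<species>``, ``habitat_shore:<species>``
    and, when driver series are supplied, ``fuel_price``/``alert_area``/
    ``price_per_pound``.  ``compute`` restricts the set (prefix match), e.g.
    ``["vms_y", "habitat_y"]``.
    """
    def wanted(name: str) -> bool:
        return compute is None or any(name == c or name.startswith(c + ":") or name.startswith(c)
                                      for c in compute)

    chain = dict(climatology_period=climatology_period, window=window,
                 min_coverage=min_coverage, months=months)
    out: dict[str, pd.Series] = {}
    if wanted("vms_y"):
        out["vms_y"] = process_series(daily_effort_centroid(linked), **chain)
    if wanted("vms_shore") and coastline is not None:
        out["vms_shore"] = process_series(daily_distance_to_shore(linked, coastline), **chain)
    if wanted("vms_cpue"):
        out["vms_cpue"] = process_series(daily_cpue(linked), **chain)
    if wanted("ssta") and sst is not None:
        mask = effort_kernel_mask(linked, sst["lat"].values, sst["lon"].values,
                                  percentile=kernel_percentile)
        out["ssta"] = restrict_season(
            ssta_series(sst, mask, climatology_period, window, min_coverage), months
        )
    if habitat is not None and eez is not None and coastline is not None:
        for species in habitat.data_vars:
            y_name, s_name = f"habitat_y:{species}", f"habitat_shore:{species}"
            if not (wanted(y_name) or wanted(s_name)):
                continue
            raw = habitat_indicators(habitat[species], eez, coastline, core_percentile)
            if wanted(y_name):
                out[y_name] = process_series(raw["y"], **chain).rename(y_name)
            if wanted(s_name):
                out[s_name] = process_series(raw["shore"], **chain).rename(s_name)
    if drivers is not None:
        for col in drivers.columns:
            if wanted(col):
                filled = drivers[col].interpolate(limit_area="inside")
                out[col] = process_series(filled, **chain).rename(col)
    return out


def tidy_indicators(series_map: dict[str, pd.Series]) -> pd.DataFrame:
    """Long-format table (name, date, value, is_anomaly, smoothed) of processed series."""
    frames = []
    for name, s in series_map.items():
        frames.append(pd.DataFrame({
            "name": name,
            "date": s.index,
            "value": s.values,
            "is_anomaly": True,
            "smoothed": True,
        }))
    return pd.concat(frames, ignore_index=True)
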
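"""Read/write scenario bundles in portable text and NetCDF formats.

Pings/receipts/drivers go to CSV with fixed headers, gridded fields to
CF-style NetCDF (dimensions time, lat, lon; written with the NetCDF3
backend for portability), and coastline/EEZ geometry to GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import xarray as xr
from shapely.geometry import LineString, Polygon, mapping, shape

from fleetsentinel.synthetic import ScenarioBundle

PING_COLUMNS = ["timestamp", "vessel_id", "lat", "lon", "event_type",
                "time_forward", "speed", "gis_flag"]
RECEIPT_COLUMNS = ["timestamp", "vessel_id", "ticket_id", "species", "pounds",
                   "price_per_pound"]


def write_geojson(geom, path: Path | str) -> None:
    feature = {"type": "Feature", "properties": {}, "geometry": mapping(geom)}
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}))


def read_geojson(path: Path | str):
    data = json.loads(Path(path).read_text())
    return shape(data["features"][0]["geometry"])


def write_bundle(bundle: ScenarioBundle, out_dir: Path | str, truth: bool = False) -> dict[str, Path]:
    """Write a scenario bundle to a directory; returns the paths written.

    ``truth=True`` additionally keeps the generator's ground-truth columns
    (phase, trip_id) in pings.csv and writes trips.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    ping_cols = PING_COLUMNS + (["phase", "trip_id"] if truth else [])
    paths["pings"] = out / "pings.csv"
    bundle.pings[ping_cols].to_csv(paths["pings"], index=False)
    paths["receipts"] = out / "receipts.csv"
    bundle.receipts[RECEIPT_COLUMNS].to_csv(paths["receipts"], index=False)
    paths["drivers"] = out / "drivers.csv"
    bundle.drivers.to_csv(paths["drivers"])
    paths["sst"] = out / "sst.nc"
    bundle.sst.to_dataset(name="sst").to_netcdf(paths["sst"], engine="scipy")
    paths["habitat"] = out / "habitat.nc"
    bundle.habitat.to_netcdf(paths["habitat"], engine="scipy")
    paths["coastline"] = out / "coastline.geojson"
    write_geojson(bundle.coastline, paths["coastline"])
    paths["eez"] = out / "eez.geojson"
    write_geojson(bundle.eez, paths["eez"])
    if truth:
        paths["trips"] = out / "trips.csv"
        bundle.trips.to_csv(paths["trips"], index=False)
    return paths


def load_pings(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["gis_flag"] = df["gis_flag"].astype(bool)
    return df


def load_receipts(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def load_drivers(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    return df


def load_field(path: Path | str) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    return ds.load()


def load_coastline(path: Path | str) -> LineString:
    return read_geojson(path)


def load_eez(path: Path | str) -> Polygon:
    return read_geojson(path)
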
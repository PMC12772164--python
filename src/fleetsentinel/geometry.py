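"""Great-circle geometry helpers: haversine distances and distance to a coastline.

All coordinates are geographic degrees (WGS84-like sphere); distances are
kilometres on a sphere of authalic radius 6371.0088 km.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in degrees.

    Inputs broadcast against each other like numpy arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def densify_polyline(line: LineString, spacing_km: float = 1.0) -> np.ndarray:
    """Return (n, 2) array of (lon, lat) vertices with great-circle spacing <= spacing_km.

    Interpolation is linear in lon/lat space, which is adequate at the
    ~1 km spacing used for shore-distance lookups.
    """
    coords = np.asarray(line.coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("coastline must have at least 2 vertices")
    pts = [coords[0]]
    for (lon0, lat0), (lon1, lat1) in zip(coords[:-1], coords[1:]):
        seg_km = float(haversine_km(lat0, lon0, lat1, lon1))
        n = max(int(np.ceil(seg_km / spacing_km)), 1)
        frac = np.linspace(0.0, 1.0, n + 1)[1:]
        pts.append(np.column_stack([lon0 + frac * (lon1 - lon0), lat0 + frac * (lat1 - lat0)]))
    return np.vstack([np.atleast_2d(p) for p in pts])


def distance_to_coast_km(
    lats: np.ndarray,
    lons: np.ndarray,
    coastline: LineString,
    spacing_km: float = 1.0,
    chunk: int = 4096,
) -> np.ndarray:
    """Great-circle distance (km) from each point to the nearest coastline vertex.

    The polyline is densified to <= spacing_km vertex spacing first, so the
    vertex-nearest distance differs from the true point-to-segment distance
    by at most ~spacing_km/2.
    """
    if coastline is None or coastline.is_empty:
        raise ValueError("coastline geometry is empty")
    verts = densify_polyline(coastline, spacing_km)
    vlat = verts[:, 1]
    vlon = verts[:, 0]
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    out = np.empty(lats.shape, dtype=float)
    flat_lat = lats.ravel()
    flat_lon = lons.ravel()
    flat_out = out.ravel()
    for i in range(0, flat_lat.size, chunk):
        sl = slice(i, i + chunk)
        d = haversine_km(flat_lat[sl, None], flat_lon[sl, None], vlat[None, :], vlon[None, :])
        flat_out[sl] = d.min(axis=1)
    return out
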
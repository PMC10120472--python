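"""Great-circle geometry helpers.

All distances in this package are great-circle (haversine) distances on a
spherical Earth; at the 100 m attribution scale and city (~10 km) travel
scale the projection choice is immaterial, and haversine keeps results
bit-reproducible across platforms.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def offset_to_lonlat(center_lon: float, center_lat: float, dx_km, dy_km):
    """Convert local east/north offsets in km to lon/lat degrees.

    Small-offset equirectangular approximation around the city center; the
    synthetic city spans a few tens of km, where the error is negligible.
    """
    dx_km = np.asarray(dx_km, dtype=float)
    dy_km = np.asarray(dy_km, dtype=float)
    km_per_deg_lat = np.pi * EARTH_RADIUS_KM / 180.0
    km_per_deg_lon = km_per_deg_lat * np.cos(np.radians(center_lat))
    return center_lon + dx_km / km_per_deg_lon, center_lat + dy_km / km_per_deg_lat
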
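"""Great-circle geometry helpers.

All spatial covariances and kriging distances in this package use
haversine great-circle distance in kilometres on WGS84 longitude/latitude
degrees; no projected coordinate system is assumed.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Inputs broadcast; returns an array of the broadcast shape.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats, lons2=None, lats2=None):
    """Full distance matrix (km) between two point sets (or one set with itself)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons2 is None:
        lons2, lats2 = lons, lats
    lons2 = np.asarray(lons2, dtype=float)
    lats2 = np.asarray(lats2, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons2[None, :], lats2[None, :])
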
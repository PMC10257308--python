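"""GeoJSON export of tracks and clustered bottom-phase centroids."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .deadreckon import GeoTrack


def track_to_geojson(track: GeoTrack, config: RunConfig | None = None,
                     decimate: int = 1) -> dict:
    """A LineString Feature of the georeferenced track (lon, lat order)."""
    lat = track.lat[::decimate]
    lon = track.lon[::decimate]
    coords = [[round(float(x), 6), round(float(y), 6)] for x, y in zip(lon, lat)]
    props: dict = {"n_points": int(track.t.size),
                   "total_distance_m": round(track.total_distance_m(), 1)}
    if config is not None:
        props["config"] = config.to_dict()
    return {
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": props,
        }],
    }


def clusters_to_geojson(centroids: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Point Features of bottom-phase centroids with dive_id/cluster/bottom_time."""
    features = []
    for _, row in centroids.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [round(float(row["lon"]), 6), round(float(row["lat"]), 6)],
            },
            "properties": {
                "dive_id": int(row["dive_id"]),
                "cluster": int(row["cluster"]) if not np.isnan(row["cluster"]) else None,
                "bottom_time": round(float(row["bottom_time"]), 1),
            },
        })
    out = {"type": "FeatureCollection", "features": features}
    if config is not None:
        out["properties"] = {"config": config.to_dict()}
    return out
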
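"""Spatial aggregation of park users over park polygons.

Photographs with WGS84 lon/lat are assigned to park polygons (boundary
points count as inside; a photo inside overlapping polygons goes to the
smallest-area one).  Per park, the tourist-minus-local unique-user count
difference ("skew"; positive = tourist-dominated) and the mean user-axis
scores are computed, the latter only for parks with at least three
unique users.  Planar point-in-polygon at city scale; no geodesic
correction (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point, shape

from .exceptions import GeometryError

__all__ = ["ParkSummary", "load_parks", "assign_parks", "park_user_summary",
           "summaries_to_geojson"]

_KM_PER_DEG = 111.32  # at the equator; scaled by cos(lat) in longitude


@dataclass
class ParkSummary:
    park_id: object
    n_users: int
    n_tourists: int
    n_locals: int
    skew: int                    # n_tourists - n_locals
    mean_axis: dict | None       # axis name -> mean score, None if < min_users
    area_km2: float
    small: bool                  # area below 0.1 km^2


def load_parks(collection: dict) -> pd.DataFrame:
    """Parse a GeoJSON FeatureCollection of park polygons.

    Returns a frame with park_id, shapely geometry and planar area in
    km^2 (equirectangular approximation at the polygon's latitude).
    """
    rows = []
    for i, feature in enumerate(collection.get("features", [])):
        props = feature.get("properties", {})
        park_id = props.get("park_id", f"feature{i}")
        try:
            geom = shape(feature["geometry"])
        except Exception as exc:
            raise GeometryError(f"feature {park_id!r}: {exc}") from exc
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(f"feature {park_id!r} is not a polygon")
        if not geom.is_valid:
            raise GeometryError(f"feature {park_id!r} has an invalid ring")
        lat = geom.centroid.y
        area_km2 = geom.area * _KM_PER_DEG ** 2 * float(np.cos(np.radians(lat)))
        rows.append({"park_id": park_id, "geometry": geom,
                     "area_km2": area_km2})
    return pd.DataFrame(rows)


def assign_parks(photos: pd.DataFrame, parks: pd.DataFrame | dict) -> pd.Series:
    """Map photo_id -> park_id by point-in-polygon (NaN when outside all).

    Boundary points count as inside.  A point covered by several
    polygons is assigned to the smallest-area polygon.
    """
    if isinstance(parks, dict):
        parks = load_parks(parks)
    has_pos = photos["lon"].notna() & photos["lat"].notna()
    pts = photos.loc[has_pos]
    geoms = list(parks["geometry"])
    tree = STRtree(geoms)
    points = [Point(lon, lat) for lon, lat in zip(pts["lon"], pts["lat"])]
    result = pd.Series(np.nan, index=photos["photo_id"], dtype=object,
                       name="park_id")
    if points:
        pairs = tree.query(points, predicate="intersects")
        areas = parks["area_km2"].to_numpy()
        ids = parks["park_id"].to_numpy()
        best: dict[int, int] = {}
        for pi, gi in pairs.T:
            if pi not in best or areas[gi] < areas[best[pi]]:
                best[pi] = gi
        pid = pts["photo_id"].to_numpy()
        for pi, gi in best.items():
            result[pid[pi]] = ids[gi]
    return result


def park_user_summary(photos: pd.DataFrame, users: pd.DataFrame,
                      parks: pd.DataFrame | dict,
                      axes: pd.DataFrame | None = None,
                      min_users: int = 3,
                      small_area_km2: float = 0.1) -> list[ParkSummary]:
    """Per-park user-group summaries.

    ``photos`` needs photo_id/user_id/park_id (already assigned);
    ``users`` needs user_id and status; ``axes`` (optional) holds one
    score column per user axis, indexed by user_id.  A user visiting a
    park several times counts once in that park; mean axis scores are
    reported only for parks with >= ``min_users`` unique users.
    """
    if isinstance(parks, dict):
        parks = load_parks(parks)
    mapped = photos[photos["park_id"].notna()]
    status = users.set_index("user_id")["status"]
    summaries = []
    visits = mapped.drop_duplicates(["park_id", "user_id"])
    by_park = visits.groupby("park_id")["user_id"].agg(list)
    for row in parks.itertuples(index=False):
        uids = by_park.get(row.park_id, [])
        st = status.reindex(uids)
        n_tourists = int((st == "tourist").sum())
        n_locals = int((st == "local").sum())
        mean_axis = None
        if len(uids) >= min_users and axes is not None:
            sub = axes.reindex(uids).dropna(how="all")
            if len(sub):
                mean_axis = {c: float(sub[c].mean()) for c in axes.columns}
        summaries.append(ParkSummary(
            park_id=row.park_id, n_users=len(uids),
            n_tourists=n_tourists, n_locals=n_locals,
            skew=n_tourists - n_locals, mean_axis=mean_axis,
            area_km2=float(row.area_km2),
            small=bool(row.area_km2 < small_area_km2)))
    return summaries


def summaries_to_geojson(summaries: list[ParkSummary],
                         parks: pd.DataFrame | dict) -> dict:
    """FeatureCollection carrying the summary properties per park."""
    if isinstance(parks, dict):
        parks = load_parks(parks)
    geom_by_id = dict(zip(parks["park_id"], parks["geometry"]))
    features = []
    for s in summaries:
        geom = geom_by_id[s.park_id]
        props = {
            "park_id": s.park_id, "n_users": s.n_users,
            "n_tourists": s.n_tourists, "n_locals": s.n_locals,
            "skew": s.skew, "skew_sign_convention": "positive=tourist",
            "area_km2": s.area_km2, "small": s.small,
        }
        if s.mean_axis is not None:
            for k, v in s.mean_axis.items():
                props[f"mean_{k}"] = v
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": geom.__geo_interface__,
        })
    return {"type": "FeatureCollection", "features": features}
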
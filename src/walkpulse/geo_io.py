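"""Reading/writing external formats and spatial indexing; no analysis logic.

Formats
-------
* ping streams: delimited text with columns ``user_id, timestamp_utc,
  lat, lon, accuracy_m`` (ISO-8601 UTC timestamps, WGS84 degrees);
* geographic layers: GeoJSON (RFC 7946) — roads as LineStrings with a
  ``highway`` class property, parks as Polygons, POIs as Points with a
  ``category`` property, census tracts as Polygons with ``tract_id`` and
  ``msa_id``;
* tract attribute tables and all tabular outputs: CSV.

Column schemas are documented in ``docs/schemas.md``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely import STRtree
from shapely.geometry import LineString, Point, Polygon, mapping, shape

from .geodesy import LocalProjector, haversine_m

logger = logging.getLogger("walkpulse")


class FormatError(ValueError):
    """Raised when an input file does not match its documented schema."""


#: Road classes considered pedestrian-eligible: secondary/tertiary roads,
#: residential and living streets, pedestrian ways, footways, tracks and
#: paths.  Highways, motorways and trunks are excluded — slow traffic on
#: them would otherwise masquerade as walking.
PEDESTRIAN_CLASSES = frozenset({
    "secondary", "tertiary", "residential", "living_street",
    "pedestrian", "footway", "track", "path",
})

PING_COLUMNS = ["user_id", "timestamp_utc", "lat", "lon", "accuracy_m"]

TRACT_ATTRIBUTE_COLUMNS = [
    "tract_id", "msa_id", "median_income", "frac_black",
    "frac_public_transit", "frac_over64", "park_access",
    "obesity_prev", "population",
]

#: covariates entering the tract-level walking model, in canonical order
MODEL_COVARIATES = [
    "median_income", "frac_black", "frac_public_transit",
    "frac_over64", "park_access", "obesity_prev",
]


# ---------------------------------------------------------------------------
# GeoWorld


@dataclass
class GeoWorld:
    """Pedestrian network, parks and POIs with lazy spatial indexes.

    Geometries are stored in WGS84 (lon/lat); index queries run in a
    local equirectangular plane centred on ``projector`` and are
    refined with great-circle distances where the result is metric.
    """

    pedestrian: pd.DataFrame   # segment_id, highway, geometry (LineString)
    excluded: pd.DataFrame     # same schema
    parks: pd.DataFrame        # park_id, geometry (Polygon)
    pois: pd.DataFrame         # poi_id, category, lat, lon
    projector: LocalProjector
    tracts: Optional[pd.DataFrame] = None  # tract_id, msa_id, geometry
    _ped_planar: Optional[np.ndarray] = field(default=None, repr=False)
    _ped_tree: Optional[STRtree] = field(default=None, repr=False)
    _park_planar: Optional[np.ndarray] = field(default=None, repr=False)
    _park_tree: Optional[STRtree] = field(default=None, repr=False)
    _poi_xy: Optional[np.ndarray] = field(default=None, repr=False)
    _poi_tree: Optional[STRtree] = field(default=None, repr=False)
    _tract_tree: Optional[STRtree] = field(default=None, repr=False)
    _tract_planar: Optional[np.ndarray] = field(default=None, repr=False)

    # -- planar projection helpers ------------------------------------

    def _project_geoms(self, geoms: Sequence) -> np.ndarray:
        proj = self.projector

        def f(coords):
            x, y = proj.to_xy(coords[:, 1], coords[:, 0])
            return np.column_stack([x, y])

        return np.array([shapely.transform(g, f) for g in geoms], dtype=object)

    def _points_planar(self, lat, lon) -> np.ndarray:
        x, y = self.projector.to_xy(lat, lon)
        return shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))

    # -- pedestrian segments ------------------------------------------

    def _ensure_ped_index(self) -> bool:
        if self._ped_tree is None and len(self.pedestrian):
            self._ped_planar = self._project_geoms(self.pedestrian["geometry"])
            self._ped_tree = STRtree(self._ped_planar)
        return self._ped_tree is not None

    def dist_to_pedestrian_m(self, lat, lon) -> np.ndarray:
        """Planar distance (m) from each point to the nearest pedestrian
        segment (point-to-nearest-point-on-segment); +inf if no segments."""
        pts = self._points_planar(lat, lon)
        if not self._ensure_ped_index():
            return np.full(len(pts), np.inf)
        idx = self._ped_tree.nearest(pts)
        return shapely.distance(pts, self._ped_planar[idx])

    # -- parks ---------------------------------------------------------

    def _ensure_park_index(self) -> bool:
        if self._park_tree is None and len(self.parks):
            self._park_planar = self._project_geoms(self.parks["geometry"])
            self._park_tree = STRtree(self._park_planar)
        return self._park_tree is not None

    def in_park(self, lat, lon) -> np.ndarray:
        """Boolean mask: point lies inside (or on the edge of) a park."""
        pts = self._points_planar(lat, lon)
        out = np.zeros(len(pts), dtype=bool)
        if not self._ensure_park_index():
            return out
        pt_idx, _ = self._park_tree.query(pts, predicate="intersects")
        out[np.unique(pt_idx)] = True
        return out

    # -- POIs ----------------------------------------------------------

    def _ensure_poi_index(self) -> bool:
        if self._poi_tree is None and len(self.pois):
            x, y = self.projector.to_xy(self.pois["lat"].to_numpy(),
                                        self.pois["lon"].to_numpy())
            self._poi_xy = shapely.points(np.column_stack([x, y]))
            self._poi_tree = STRtree(self._poi_xy)
        return self._poi_tree is not None

    def pois_within(self, lat: float, lon: float, radius_m: float) -> pd.DataFrame:
        """POIs within ``radius_m`` great-circle meters of a point, with a
        ``dist_m`` column; empty frame if none."""
        if not self._ensure_poi_index():
            return self.pois.assign(dist_m=pd.Series(dtype=float)).iloc[0:0]
        pt = self._points_planar(lat, lon)[0]
        # planar shortlist with slack, then exact geodesic refinement
        cand = self._poi_tree.query(pt.buffer(radius_m * 1.5))
        if len(cand) == 0:
            return self.pois.assign(dist_m=pd.Series(dtype=float)).iloc[0:0]
        sub = self.pois.iloc[np.sort(cand)]
        d = haversine_m(lat, lon, sub["lat"].to_numpy(), sub["lon"].to_numpy())
        sub = sub.assign(dist_m=d)
        return sub[sub["dist_m"] <= radius_m]

    # -- tracts ----------------------------------------------------------

    def _ensure_tract_index(self) -> bool:
        if self._tract_tree is None and self.tracts is not None and len(self.tracts):
            self._tract_planar = self._project_geoms(self.tracts["geometry"])
            self._tract_tree = STRtree(self._tract_planar)
        return self._tract_tree is not None

    def tract_of(self, lat, lon) -> np.ndarray:
        """tract_id per point, or None where no tract covers it."""
        pts = self._points_planar(lat, lon)
        out = np.full(len(pts), None, dtype=object)
        if not self._ensure_tract_index():
            return out
        pt_idx, tr_idx = self._tract_tree.query(pts, predicate="intersects")
        if len(pt_idx) == 0:
            return out
        ids = self.tracts["tract_id"].to_numpy()
        # a point on a shared tract edge matches both; keep the smallest id
        order = np.lexsort((ids[tr_idx], pt_idx))
        p_sorted = pt_idx[order]
        id_sorted = ids[tr_idx][order]
        first = np.concatenate([[True], p_sorted[1:] != p_sorted[:-1]])
        out[p_sorted[first]] = id_sorted[first]
        return out


# ---------------------------------------------------------------------------
# Ping streams


def read_pings(path, drop_accuracy_worse_than: Optional[float] = None) -> pd.DataFrame:
    """Read a delimited ping stream into a per-user time-sorted frame.

    Rows with unparseable timestamps/coordinates or out-of-range lat/lon
    are dropped (count logged); duplicate ``(user_id, timestamp)`` rows
    keep the first occurrence.  ``drop_accuracy_worse_than`` removes rows
    whose reported horizontal accuracy exceeds the given meters (the
    default keeps everything — no accuracy filter is applied).
    """
    df = pd.read_csv(path, dtype={"user_id": str})
    for col in ("user_id", "timestamp_utc", "lat", "lon"):
        if col not in df.columns:
            raise FormatError(f"ping file {path} is missing required column {col!r}")
    if "accuracy_m" not in df.columns:
        df["accuracy_m"] = np.nan

    n0 = len(df)
    t = pd.to_datetime(df["timestamp_utc"], errors="coerce", utc=True)
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    acc = pd.to_numeric(df["accuracy_m"], errors="coerce")
    ok = (t.notna() & lat.notna() & lon.notna()
          & lat.between(-90, 90) & lon.between(-180, 180))
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("read_pings: dropped %d malformed row(s) of %d", dropped, n0)

    out = pd.DataFrame({
        "user_id": df["user_id"][ok],
        "t": t[ok],
        "lat": lat[ok],
        "lon": lon[ok],
        "accuracy_m": acc[ok],
    })
    if drop_accuracy_worse_than is not None:
        bad = out["accuracy_m"] > drop_accuracy_worse_than
        if bad.any():
            logger.warning("read_pings: accuracy filter removed %d row(s)",
                           int(bad.sum()))
        out = out[~bad]
    out = (out.sort_values(["user_id", "t"], kind="mergesort")
              .drop_duplicates(subset=["user_id", "t"], keep="first")
              .reset_index(drop=True))
    return out


def write_pings(pings: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "user_id": pings["user_id"],
        "timestamp_utc": pings["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "lat": pings["lat"].round(7),
        "lon": pings["lon"].round(7),
        "accuracy_m": pings["accuracy_m"],
    })
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON layers


def _read_geojson(path, expected: Iterable[str]):
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    geoms, props = [], []
    for i, feat in enumerate(gj.get("features", [])):
        try:
            g = shape(feat["geometry"])
        except Exception as exc:
            raise FormatError(f"{path}: invalid geometry at feature {i}: {exc}")
        if not g.is_valid:
            raise FormatError(f"{path}: invalid geometry at feature {i}")
        if g.geom_type not in expected:
            raise FormatError(
                f"{path}: feature {i} has type {g.geom_type}, expected {expected}")
        geoms.append(g)
        props.append(feat.get("properties") or {})
    return geoms, props


def _write_geojson(path, geoms, props) -> None:
    feats = [{"type": "Feature", "geometry": mapping(g), "properties": p}
             for g, p in zip(geoms, props)]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def load_world(roads_path, parks_path, pois_path,
               pedestrian_classes: frozenset = PEDESTRIAN_CLASSES,
               tracts_path=None,
               origin: Optional[tuple] = None) -> GeoWorld:
    """Load GeoJSON layers and partition roads into pedestrian/excluded.

    ``origin`` fixes the local projection centre (lat, lon); by default
    it is the centroid of the road layer's bounding box.
    """
    road_geoms, road_props = _read_geojson(roads_path, {"LineString"})
    park_geoms, park_props = _read_geojson(parks_path, {"Polygon"})
    poi_geoms, poi_props = _read_geojson(pois_path, {"Point"})

    roads = pd.DataFrame({
        "segment_id": [p.get("segment_id", f"seg_{i}") for i, p in enumerate(road_props)],
        "highway": [p.get("highway", "") for p in road_props],
        "geometry": road_geoms,
    })
    is_ped = roads["highway"].isin(pedestrian_classes)
    parks = pd.DataFrame({
        "park_id": [p.get("park_id", f"park_{i}") for i, p in enumerate(park_props)],
        "geometry": park_geoms,
    })
    pois = pd.DataFrame({
        "poi_id": [p.get("poi_id", f"poi_{i}") for i, p in enumerate(poi_props)],
        "category": [p.get("category", "") for p in poi_props],
        "lat": [g.y for g in poi_geoms],
        "lon": [g.x for g in poi_geoms],
    })

    tracts = None
    if tracts_path is not None:
        tr_geoms, tr_props = _read_geojson(tracts_path, {"Polygon"})
        tracts = pd.DataFrame({
            "tract_id": [p.get("tract_id", f"tract_{i}") for i, p in enumerate(tr_props)],
            "msa_id": [p.get("msa_id", "msa_0") for p in tr_props],
            "geometry": tr_geoms,
        })

    if origin is None:
        if len(road_geoms):
            minx, miny, maxx, maxy = shapely.total_bounds(np.array(road_geoms, dtype=object))
            origin = ((miny + maxy) / 2.0, (minx + maxx) / 2.0)
        else:
            origin = (0.0, 0.0)

    return GeoWorld(
        pedestrian=roads[is_ped].reset_index(drop=True),
        excluded=roads[~is_ped].reset_index(drop=True),
        parks=parks, pois=pois, tracts=tracts,
        projector=LocalProjector(*origin),
    )


def write_world(world: GeoWorld, roads_path, parks_path, pois_path,
                tracts_path=None) -> None:
    roads = pd.concat([world.pedestrian, world.excluded], ignore_index=True)
    _write_geojson(
        roads_path, roads["geometry"],
        [{"segment_id": s, "highway": h}
         for s, h in zip(roads["segment_id"], roads["highway"])])
    _write_geojson(parks_path, world.parks["geometry"],
                   [{"park_id": p} for p in world.parks["park_id"]])
    _write_geojson(
        pois_path,
        [Point(lon, lat) for lat, lon in zip(world.pois["lat"], world.pois["lon"])],
        [{"poi_id": p, "category": c}
         for p, c in zip(world.pois["poi_id"], world.pois["category"])])
    if tracts_path is not None and world.tracts is not None:
        _write_geojson(
            tracts_path, world.tracts["geometry"],
            [{"tract_id": t, "msa_id": m}
             for t, m in zip(world.tracts["tract_id"], world.tracts["msa_id"])])


# ---------------------------------------------------------------------------
# Tract attribute tables


def read_tract_attributes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str, "msa_id": str})
    for col in TRACT_ATTRIBUTE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"tract table {path} is missing column {col!r}")
    if df["tract_id"].duplicated().any():
        raise FormatError("tract_id values must be unique")
    for col in ("frac_black", "frac_public_transit", "frac_over64", "obesity_prev"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise FormatError(f"{col} must lie in [0, 1]")
    if (df["population"] < 0).any():
        raise FormatError("population must be non-negative")
    return df


def write_tract_attributes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in TRACT_ATTRIBUTE_COLUMNS
                                          if c in df.columns])
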
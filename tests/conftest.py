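"""Shared fixtures: hand-built ping streams and minimal geo worlds.

Streams are laid out along the equator so a longitude offset of
``m / R`` radians is ``m`` meters of great-circle distance to float
precision, letting tests plant exact pair distances and speeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

import walkpulse as wp
from walkpulse.geodesy import EARTH_RADIUS_M, LocalProjector
from walkpulse.geo_io import GeoWorld


def lon_deg(meters: float, lat: float = 0.0) -> float:
    """Longitude offset (deg) spanning ``meters`` at the given latitude."""
    return float(np.degrees(meters / (EARTH_RADIUS_M * np.cos(np.radians(lat)))))


T0 = pd.Timestamp("2020-02-20 12:00:00", tz="UTC")


def make_stream(dists, dts, user: str = "u1", t0: pd.Timestamp = T0,
                lat: float = 0.0) -> pd.DataFrame:
    """Ping frame with planted consecutive gap distances (m) and gap
    times (s); eastward along a parallel."""
    lons = np.concatenate([[0.0], np.cumsum([lon_deg(d, lat) for d in dists])])
    ts = [t0]
    for dt in dts:
        ts.append(ts[-1] + pd.Timedelta(seconds=float(dt)))
    return pd.DataFrame({"user_id": user, "t": ts,
                         "lat": lat, "lon": lons,
                         "accuracy_m": np.nan})


def make_world(pois=(), ped_lines=(), parks=(), origin=(0.0, 0.0),
               tracts=None) -> GeoWorld:
    """Minimal GeoWorld from literal lon/lat coordinates.

    ``pois``: (lat, lon, category) triples; ``ped_lines``: coordinate
    lists [(lon, lat), ...]; ``parks``: polygon shells.
    """
    pois_df = pd.DataFrame({
        "poi_id": [f"poi_{i:05d}" for i in range(len(pois))],
        "category": [p[2] for p in pois],
        "lat": [p[0] for p in pois],
        "lon": [p[1] for p in pois],
    })
    ped = pd.DataFrame({
        "segment_id": [f"seg_{i}" for i in range(len(ped_lines))],
        "highway": ["footway"] * len(ped_lines),
        "geometry": [LineString(c) for c in ped_lines],
    })
    parks_df = pd.DataFrame({
        "park_id": [f"park_{i}" for i in range(len(parks))],
        "geometry": [Polygon(c) for c in parks],
    })
    return GeoWorld(pedestrian=ped,
                    excluded=ped.iloc[0:0].copy(),
                    parks=parks_df, pois=pois_df, tracts=tracts,
                    projector=LocalProjector(*origin))


@pytest.fixture(scope="session")
def tiny_world():
    """Small but fully featured synthetic world (deterministic)."""
    cfg = wp.WorldConfig(n_tracts=9, n_msas=3, grid_extent_m=2000.0,
                         road_spacing_m=200.0, n_pois=120,
                         park_fraction=0.06, seed=5)
    world, skeleton = wp.build_world(cfg)
    return cfg, world, skeleton


@pytest.fixture(scope="session")
def small_sim(tiny_world):
    """Short trace simulation over the tiny world with ground truth."""
    _, world, _ = tiny_world
    beh = wp.BehaviorConfig(n_users=12, n_days=20, intervention_day=10,
                            seed=6)
    pings, truth = wp.simulate_traces(world, beh)
    return world, beh, pings, truth
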
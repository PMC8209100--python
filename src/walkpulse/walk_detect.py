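"""Walking-bout detection from anonymized GPS ping streams.

A walk bout is a maximal run of consecutive pings whose pairwise speeds
do not exceed a walking-speed ceiling (default 2 m/s, boundary
inclusive) and whose time gaps stay below a maximum (default 180 s).
Candidate bouts shorter than 50 m are discarded as GPS noise, and bouts
must lie in pedestrian-eligible areas: every ping within 20 m of a
pedestrian-class road segment, or inside a park polygon.  Speeds use
great-circle distance; a zero time gap yields infinite speed (never
walkable).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .config import DetectConfig
from .geodesy import haversine_m
from .geo_io import GeoWorld

logger = logging.getLogger("walkpulse")

BOUT_COLUMNS = ["bout_id", "user_id", "start_t", "end_t", "n_pings",
                "distance_m", "duration_min", "start_idx", "end_idx",
                "end_lat", "end_lon", "purpose", "destination_category"]


def _as_sorted(pings: pd.DataFrame) -> pd.DataFrame:
    t = pings["t"]
    grp_t = t.groupby(pings["user_id"].to_numpy(), sort=False)
    if not grp_t.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("pings must be time-sorted within each user")
    return pings


def pairwise_speeds(pings: pd.DataFrame) -> pd.DataFrame:
    """Per-consecutive-pair gap distance (m), gap time (s) and speed (m/s)
    for a single-user, time-sorted ping frame.

    Pairs with a zero time gap get speed +inf.
    """
    if len(pings) < 2:
        raise ValueError("need at least 2 pings")
    if pings["user_id"].nunique() > 1:
        raise ValueError("pairwise_speeds operates on a single user")
    _as_sorted(pings)
    lat = pings["lat"].to_numpy(dtype=float)
    lon = pings["lon"].to_numpy(dtype=float)
    ts = pings["t"].astype("int64").to_numpy() / 1e9
    dist = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt = np.diff(ts)
    with np.errstate(divide="ignore"):
        speed = np.where(dt > 0, dist / np.where(dt > 0, dt, 1.0), np.inf)
    speed = np.where((dt == 0), np.inf, speed)
    return pd.DataFrame({"gap_distance_m": dist, "gap_seconds": dt,
                         "speed_mps": speed})


def _walkable_pairs(pings: pd.DataFrame, config: DetectConfig) -> np.ndarray:
    """Boolean per consecutive row pair (global frame, sorted by
    user then time): pair is same-user, slow enough and close enough in
    time to sit inside one walk bout."""
    lat = pings["lat"].to_numpy(dtype=float)
    lon = pings["lon"].to_numpy(dtype=float)
    ts = pings["t"].astype("int64").to_numpy() / 1e9
    uid = pings["user_id"].to_numpy()
    dist = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt = np.diff(ts)
    same = uid[:-1] == uid[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt > 0, dist / np.where(dt > 0, dt, 1.0), np.inf)
    return (same & (dt > 0) & (dt <= config.max_ping_gap_s)
            & (speed <= config.speed_threshold_mps))


def segment_bouts(pings: pd.DataFrame,
                  config: Optional[DetectConfig] = None) -> pd.DataFrame:
    """Extract candidate bouts: maximal runs of walkable consecutive
    pairs, keeping runs with at least ``min_pings_per_bout`` pings.

    ``pings`` must be sorted by (user_id, t); bouts reference the frame
    by positional row range [start_idx, end_idx] inclusive.
    """
    config = config or DetectConfig()
    pings = _as_sorted(pings).reset_index(drop=True)
    n = len(pings)
    if n < 2:
        return pd.DataFrame(columns=BOUT_COLUMNS)
    ok = _walkable_pairs(pings, config)
    # maximal runs of True in `ok`
    padded = np.concatenate([[False], ok, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # one past last True pair
    rows = []
    lat = pings["lat"].to_numpy(dtype=float)
    lon = pings["lon"].to_numpy(dtype=float)
    ts = pings["t"]
    for k, (a, b) in enumerate(zip(starts, ends)):
        i0, i1 = int(a), int(b)  # pings i0 .. i1 inclusive
        n_pings = i1 - i0 + 1
        if n_pings < config.min_pings_per_bout:
            continue
        dist = float(haversine_m(lat[i0:i1], lon[i0:i1],
                                 lat[i0 + 1:i1 + 1], lon[i0 + 1:i1 + 1]).sum())
        dur_min = (ts.iloc[i1] - ts.iloc[i0]).total_seconds() / 60.0
        rows.append((None, pings["user_id"].iloc[i0], ts.iloc[i0], ts.iloc[i1],
                     n_pings, dist, dur_min, i0, i1,
                     lat[i1], lon[i1], pd.NA, pd.NA))
    out = pd.DataFrame(rows, columns=BOUT_COLUMNS)
    out["bout_id"] = [f"bout_{i:06d}" for i in range(len(out))]
    return out


def filter_min_distance(bouts: pd.DataFrame,
                        config: Optional[DetectConfig] = None) -> pd.DataFrame:
    """Discard bouts of distance strictly less than the minimum (50 m
    default); the boundary value is kept."""
    config = config or DetectConfig()
    if len(bouts) == 0:
        return bouts
    return bouts[bouts["distance_m"] >= config.min_bout_distance_m] \
        .reset_index(drop=True)


def pedestrian_mask(bouts: pd.DataFrame, pings: pd.DataFrame,
                    world: GeoWorld,
                    config: Optional[DetectConfig] = None) -> np.ndarray:
    """Vectorized pedestrian-area test for each bout.

    A ping qualifies if it is within ``pedestrian_buffer_m`` of a
    pedestrian segment or inside a park; a bout qualifies if all its
    pings do (or a configured fraction, under the 'fraction' rule).
    """
    config = config or DetectConfig()
    if len(bouts) == 0:
        return np.zeros(0, dtype=bool)
    if len(world.pedestrian) == 0 and len(world.parks) == 0:
        logger.warning("pedestrian-area test: world has no pedestrian "
                       "segments or parks; all bouts fail")
        return np.zeros(len(bouts), dtype=bool)
    b0 = bouts["start_idx"].to_numpy(dtype=np.int64)
    b1 = bouts["end_idx"].to_numpy(dtype=np.int64)
    idx = np.concatenate([np.arange(a, b + 1) for a, b in zip(b0, b1)])
    owner = np.repeat(np.arange(len(bouts)), b1 - b0 + 1)
    lat = pings["lat"].to_numpy(dtype=float)[idx]
    lon = pings["lon"].to_numpy(dtype=float)[idx]
    near_ped = world.dist_to_pedestrian_m(lat, lon) <= config.pedestrian_buffer_m
    ok = near_ped | world.in_park(lat, lon)
    if config.pedestrian_rule == "all":
        good = np.ones(len(bouts), dtype=bool)
        np.logical_and.at(good, owner, ok)
        return good
    frac = np.bincount(owner, weights=ok.astype(float), minlength=len(bouts)) \
        / np.bincount(owner, minlength=len(bouts))
    return frac >= config.pedestrian_min_fraction


def in_pedestrian_area(bout: pd.Series, pings: pd.DataFrame, world: GeoWorld,
                       config: Optional[DetectConfig] = None) -> bool:
    """Single-bout pedestrian-area test (see :func:`pedestrian_mask`)."""
    return bool(pedestrian_mask(bout.to_frame().T.reset_index(drop=True),
                                pings, world, config)[0])


def detect_walks(pings: pd.DataFrame, world: GeoWorld,
                 config: Optional[DetectConfig] = None,
                 timezone: str = "UTC") -> pd.DataFrame:
    """Full detection: segment, apply the minimum-distance filter, keep
    bouts in pedestrian areas; adds the local calendar date of the bout
    start.  Purpose is left unset (classification is a separate step).
    """
    config = config or DetectConfig()
    pings = (pings.sort_values(["user_id", "t"], kind="mergesort")
                  .reset_index(drop=True))
    bouts = segment_bouts(pings, config)
    bouts = filter_min_distance(bouts, config)
    if len(bouts):
        bouts = bouts[pedestrian_mask(bouts, pings, world, config)] \
            .reset_index(drop=True)
    bouts["date"] = (bouts["start_t"].dt.tz_convert(timezone).dt.date
                     if len(bouts) else pd.Series(dtype=object))
    return bouts
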
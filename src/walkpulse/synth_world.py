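"""Synthetic toy world and GPS-trace generator with known ground truth.

The generator emulates the statistical structure the walking analysis
assumes: a grid street network (most classes pedestrian-eligible, a few
motorways), parks, categorized POIs, census tracts tiling the extent and
assigned round-robin to metropolitan areas; user traces mixing walking,
driving and stationary periods with realistic speeds and isotropic GPS
jitter; POI-anchored utilitarian destinations; and a pre/post behavioral
shock that differentially suppresses utilitarian walking.

Planted trips are constructed to be recoverable by the detection and
classification rules: walk speeds stay strictly below 2 m/s and drive
speeds strictly above it even after jitter; utilitarian walks are
shorter than 750 m and end exactly at a non-outdoors POI; leisure walks
are long (>= 1 km planted) and end away from any POI.  Stationary
periods emit sparse jittered pings at the home location (idle devices
report infrequently), which the detector must reject.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import norm
from shapely.geometry import LineString, Polygon

from .config import BehaviorConfig, ConfigurationError, WorldConfig
from .geodesy import LocalProjector
from .geo_io import GeoWorld, MODEL_COVARIATES, TRACT_ATTRIBUTE_COLUMNS

#: planted per-SD effects (m/day) and reference intercept used as the
#: default ground truth for the tract-attribute simulator
DEFAULT_BETA: Dict[str, float] = {
    "median_income": -29.205,
    "frac_black": 2.745,
    "frac_public_transit": 54.170,
    "frac_over64": -0.331,
    "park_access": 15.691,
    "obesity_prev": -20.703,
}
DEFAULT_INTERCEPT: float = 315.572

_PED_CLASS_CYCLE = ["residential", "secondary", "tertiary", "footway",
                    "living_street", "path"]

#: mild default correlation among tract covariates (|r| <= 0.5)
DEFAULT_COVARIATE_CORR = np.array([
    #  inc    blk    trn    o64    prk    obe
    [1.00, -0.35, -0.10,  0.10,  0.30, -0.45],
    [-0.35, 1.00,  0.30, -0.10, -0.15,  0.35],
    [-0.10, 0.30,  1.00, -0.15,  0.10,  0.05],
    [0.10, -0.10, -0.15,  1.00,  0.05,  0.10],
    [0.30, -0.15,  0.10,  0.05,  1.00, -0.25],
    [-0.45, 0.35,  0.05,  0.10, -0.25,  1.00],
])


# ---------------------------------------------------------------------------
# World construction


def build_world(config: WorldConfig) -> Tuple[GeoWorld, pd.DataFrame]:
    """Build the toy geography; deterministic given ``config.seed``.

    Returns the :class:`GeoWorld` (roads, parks, POIs, tract polygons)
    and a tract skeleton table (``tract_id``, ``msa_id``).
    """
    rng = np.random.default_rng(config.seed)
    proj = LocalProjector(config.origin_lat, config.origin_lon)
    E = config.grid_extent_m
    s = config.road_spacing_m
    n_lines = int(np.floor(E / s)) + 1

    def to_line(coords_xy):
        xy = np.asarray(coords_xy, dtype=float)
        lat, lon = proj.to_latlon(xy[:, 0], xy[:, 1])
        return LineString(np.column_stack([lon, lat]))

    # pedestrian grid: vertical and horizontal lines, classes cycling
    seg_rows = []
    k = 0
    for i in range(n_lines):
        x = i * s
        seg_rows.append(("v", to_line([(x, 0.0), (x, E)])))
        k += 1
    for j in range(n_lines):
        y = j * s
        seg_rows.append(("h", to_line([(0.0, y), (E, y)])))
    ped = pd.DataFrame({
        "segment_id": [f"seg_{i:04d}" for i in range(len(seg_rows))],
        "highway": [_PED_CLASS_CYCLE[i % len(_PED_CLASS_CYCLE)]
                    for i in range(len(seg_rows))],
        "geometry": [g for _, g in seg_rows],
    })

    # motorways offset half a spacing from the grid (never pedestrian)
    mot_rows = []
    for i in range(0, n_lines - 1, max(1, config.highway_every)):
        x = (i + 0.5) * s
        mot_rows.append(to_line([(x, 0.0), (x, E)]))
    excluded = pd.DataFrame({
        "segment_id": [f"mot_{i:04d}" for i in range(len(mot_rows))],
        "highway": ["motorway"] * len(mot_rows),
        "geometry": mot_rows,
    })

    # parks: squares centred in grid cells, ~park_fraction of total area
    n_cells = n_lines - 1
    park_side = 0.7 * s
    park_geoms = []
    if config.park_fraction > 0 and n_cells >= 1:
        n_parks = max(1, int(round(config.park_fraction * E * E
                                   / (park_side ** 2))))
        n_parks = min(n_parks, n_cells * n_cells)
        cells = rng.choice(n_cells * n_cells, size=n_parks, replace=False)
        for c in np.sort(cells):
            ci, cj = divmod(int(c), n_cells)
            cx, cy = (ci + 0.5) * s, (cj + 0.5) * s
            h = park_side / 2.0
            xy = [(cx - h, cy - h), (cx + h, cy - h),
                  (cx + h, cy + h), (cx - h, cy + h), (cx - h, cy - h)]
            lat, lon = proj.to_latlon(np.array([p[0] for p in xy]),
                                      np.array([p[1] for p in xy]))
            park_geoms.append(Polygon(np.column_stack([lon, lat])))
    parks = pd.DataFrame({
        "park_id": [f"park_{i:03d}" for i in range(len(park_geoms))],
        "geometry": park_geoms,
    })

    # POIs on pedestrian segments, categories from the configured mix
    cats = sorted(config.poi_category_weights)
    probs = np.array([config.poi_category_weights[c] for c in cats])
    poi_lat, poi_lon, poi_cat = [], [], []
    if config.n_pois > 0:
        line_idx = rng.integers(0, len(seg_rows), size=config.n_pois)
        offs = rng.uniform(0.0, E, size=config.n_pois)
        chosen = rng.choice(len(cats), size=config.n_pois, p=probs)
        for li, off, ci in zip(line_idx, offs, chosen):
            orient, _ = seg_rows[li]
            if orient == "v":
                xy = (li * s, off)
            else:
                xy = (off, (li - n_lines) * s)
            lat, lon = proj.to_latlon(xy[0], xy[1])
            poi_lat.append(float(lat))
            poi_lon.append(float(lon))
            poi_cat.append(cats[ci])
    pois = pd.DataFrame({
        "poi_id": [f"poi_{i:05d}" for i in range(len(poi_cat))],
        "category": poi_cat, "lat": poi_lat, "lon": poi_lon,
    })

    # tracts tile the extent in rows of near-equal cell counts
    tracts = _tile_tracts(config, proj)

    world = GeoWorld(pedestrian=ped, excluded=excluded, parks=parks,
                     pois=pois, tracts=tracts, projector=proj)
    return world, tracts[["tract_id", "msa_id"]].copy()


def _tile_tracts(config: WorldConfig, proj: LocalProjector) -> pd.DataFrame:
    n = config.n_tracts
    E = config.grid_extent_m
    n_rows = max(1, int(round(np.sqrt(n))))
    base, extra = divmod(n, n_rows)
    rows = [base + (1 if r < extra else 0) for r in range(n_rows)]
    geoms, ids, msas = [], [], []
    t = 0
    y0 = 0.0
    dy = E / n_rows
    for r, ncols in enumerate(rows):
        if ncols == 0:
            continue
        dx = E / ncols
        for c in range(ncols):
            x0 = c * dx
            xy = [(x0, y0), (x0 + dx, y0), (x0 + dx, y0 + dy),
                  (x0, y0 + dy), (x0, y0)]
            lat, lon = proj.to_latlon(np.array([p[0] for p in xy]),
                                      np.array([p[1] for p in xy]))
            geoms.append(Polygon(np.column_stack([lon, lat])))
            ids.append(f"tract_{t:04d}")
            msas.append(f"msa_{t % config.n_msas:02d}")
            t += 1
        y0 += dy
    return pd.DataFrame({"tract_id": ids, "msa_id": msas, "geometry": geoms})


# ---------------------------------------------------------------------------
# Pedestrian graph (for routing planted walks)


def pedestrian_graph(world: GeoWorld) -> nx.Graph:
    """Node/edge graph of the pedestrian network in local planar meters.

    Nodes are segment intersections and endpoints (rounded to 1 um);
    edges connect consecutive nodes along each segment with a ``length``
    attribute.
    """
    proj = world.projector
    lines = []
    for g in world.pedestrian["geometry"]:
        xy = np.asarray(g.coords)
        x, y = proj.to_xy(xy[:, 1], xy[:, 0])
        lines.append(LineString(np.column_stack([x, y])))
    tree = shapely.STRtree(np.array(lines, dtype=object))
    G = nx.Graph()
    for i, line in enumerate(lines):
        cuts = {0.0, line.length}
        for j in tree.query(line, predicate="intersects"):
            if j == i:
                continue
            inter = line.intersection(lines[j])
            pts = []
            if inter.geom_type == "Point":
                pts = [inter]
            elif inter.geom_type == "MultiPoint":
                pts = list(inter.geoms)
            for p in pts:
                cuts.add(line.project(p))
        locs = sorted(cuts)
        nodes = [line.interpolate(d) for d in locs]
        keys = [(round(p.x, 6), round(p.y, 6)) for p in nodes]
        for a, b, da, db in zip(keys[:-1], keys[1:], locs[:-1], locs[1:]):
            if db - da > 1e-9 and a != b:
                G.add_edge(a, b, length=db - da)
    return G


def _lattice_path(G: nx.Graph, start_key, target_len: float,
                  rng: np.random.Generator,
                  head: Optional[Sequence[Tuple[float, float]]] = None
                  ) -> np.ndarray:
    """Random non-backtracking walk over ``G`` from ``start_key`` until
    the polyline reaches ``target_len`` (last leg trimmed); returns the
    path reversed so it *ends* at ``start_key``/``head``.

    ``head`` optionally prepends fixed points (e.g. a mid-edge POI
    location) before the walk starts.
    """
    pts = list(head) if head else []
    pts.append(start_key)
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        total += float(np.hypot(b[0] - a[0], b[1] - a[1]))
    cur, prev = start_key, None
    while total < target_len:
        nbrs = [n for n in G.neighbors(cur) if n != prev]
        if not nbrs:
            nbrs = list(G.neighbors(cur))
            if not nbrs:
                break
        nxt = nbrs[rng.integers(0, len(nbrs))]
        step = G.edges[cur, nxt]["length"]
        if total + step > target_len:
            frac = (target_len - total) / step
            end = (cur[0] + frac * (nxt[0] - cur[0]),
                   cur[1] + frac * (nxt[1] - cur[1]))
            pts.append(end)
            total = target_len
            break
        pts.append(nxt)
        total += step
        prev, cur = cur, nxt
    return np.asarray(pts[::-1], dtype=float)


# ---------------------------------------------------------------------------
# Ping emission


def emit_pings(path_xy: np.ndarray, speed_mps: float, t0_s: int,
               interval_s: float, noise_sd_m: float,
               rng: np.random.Generator, projector: LocalProjector
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample pings along a planar polyline at constant speed.

    Pings are emitted every ``interval_s`` from the path start and always
    include the final path point, with isotropic Gaussian position noise.
    Returns (epoch seconds, lat, lon).
    """
    path_xy = np.asarray(path_xy, dtype=float)
    seg = np.diff(path_xy, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    T = total / speed_mps
    # regular cadence, but the last ping lands exactly on the path end:
    # the final gap spans [interval, 2*interval), never a sliver whose
    # positional noise would dominate the measured speed
    offs = np.arange(0.0, T, interval_s)
    if len(offs) >= 2:
        offs[-1] = T
    else:
        offs = np.array([0.0, T])
    d = np.minimum(offs * speed_mps, total)
    x = np.interp(d, cum, path_xy[:, 0])
    y = np.interp(d, cum, path_xy[:, 1])
    if noise_sd_m > 0:
        x = x + rng.normal(0.0, noise_sd_m, size=x.shape)
        y = y + rng.normal(0.0, noise_sd_m, size=y.shape)
    t = t0_s + np.round(offs).astype(np.int64)
    lat, lon = projector.to_latlon(x, y)
    return t, lat, lon


# ---------------------------------------------------------------------------
# Trace simulation


def _local_to_epoch(naive: pd.DatetimeIndex, tz: str) -> np.ndarray:
    loc = naive.tz_localize(tz, nonexistent="shift_forward",
                            ambiguous=np.ones(len(naive), dtype=bool))
    return (loc.tz_convert("UTC").asi8 // 10 ** 9).astype(np.int64)


def simulate_traces(world: GeoWorld, behavior: BehaviorConfig
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate user GPS traces over the toy world.

    Returns ``(pings, truth)``: pings with columns
    ``user_id, t, lat, lon, accuracy_m`` (UTC, per-user time-sorted) and
    a ground-truth segment table with one row per planted trip or
    stationary night (``segment_id, user_id, kind, t_start, t_end,
    planted_length_m, dest_category, day_index, home_tract``).
    """
    if len(world.pedestrian) == 0:
        raise ConfigurationError("world has no pedestrian segments")
    rng = np.random.default_rng(behavior.seed)
    proj = world.projector
    tz = behavior.timezone
    cols_p = ["user_id", "t", "lat", "lon", "accuracy_m"]
    cols_t = ["segment_id", "user_id", "kind", "t_start", "t_end",
              "planted_length_m", "dest_category", "day_index", "home_tract"]
    if behavior.n_users == 0:
        return (pd.DataFrame(columns=cols_p),
                pd.DataFrame(columns=cols_t))

    G = pedestrian_graph(world)
    nodes = np.array(list(G.nodes), dtype=float)
    node_keys = list(G.nodes)
    node_tree = cKDTree(nodes)

    # POI bookkeeping: host node and leisure-endpoint clearance
    pois = world.pois
    if len(pois):
        px, py = proj.to_xy(pois["lat"].to_numpy(), pois["lon"].to_numpy())
        poi_xy = np.column_stack([px, py])
        _, poi_node_idx = node_tree.query(poi_xy)
        util_poi_mask = ~pois["category"].isin(["city/outdoors", "outdoors"]).to_numpy()
        util_poi_idx = np.flatnonzero(util_poi_mask)
        poi_tree = cKDTree(poi_xy)
        node_poi_dist, _ = poi_tree.query(nodes)
    else:
        poi_xy = np.zeros((0, 2))
        util_poi_idx = np.array([], dtype=int)
        node_poi_dist = np.full(len(nodes), np.inf)
    clear_nodes = np.flatnonzero(node_poi_dist >= 60.0)
    if len(clear_nodes) == 0:
        clear_nodes = np.arange(len(nodes))

    # homes: users spread uniformly over tracts, near a network node
    tracts = world.tracts
    n_tr = len(tracts) if tracts is not None else 0
    if n_tr:
        lat_n, lon_n = proj.to_latlon(nodes[:, 0], nodes[:, 1])
        node_tract = world.tract_of(lat_n, lon_n)
        by_tract = {}
        for i, tr in enumerate(node_tract):
            if tr is not None:
                by_tract.setdefault(tr, []).append(i)

    users = [f"user_{u:05d}" for u in range(behavior.n_users)]
    home_tract, home_xy = [], []
    if n_tr:
        # planar tract bounds, for clamping homes safely inside a tract
        tract_bounds = {}
        for tid, geom in zip(tracts["tract_id"], tracts["geometry"]):
            xy = np.asarray(geom.exterior.coords)
            bx, by = proj.to_xy(xy[:, 1], xy[:, 0])
            tract_bounds[tid] = (bx.min(), by.min(), bx.max(), by.max())
    for u in range(behavior.n_users):
        if n_tr:
            tr = tracts["tract_id"].iloc[int(rng.integers(0, n_tr))]
            cand = by_tract.get(tr)
            ni = int(rng.choice(cand)) if cand else int(rng.integers(0, len(nodes)))
        else:
            tr = None
            ni = int(rng.integers(0, len(nodes)))
        home = nodes[ni] + rng.uniform(-10.0, 10.0, size=2)
        if tr is not None:
            # keep the home >= 25 m inside its tract so nighttime jitter
            # cannot leak the modal tract across a boundary
            x0, y0, x1, y1 = tract_bounds[tr]
            m = min(25.0, (x1 - x0) / 2.0, (y1 - y0) / 2.0)
            home = np.array([np.clip(home[0], x0 + m, x1 - m),
                             np.clip(home[1], y0 + m, y1 - m)])
        home_tract.append(tr)
        home_xy.append(home)

    day_dates = [behavior.start_date + dt.timedelta(days=d)
                 for d in range(behavior.n_days)]

    ping_frames = []
    truth_rows = []
    seg_counter = 0
    v_lo, v_hi = behavior.walk_speed_range
    dv_lo, dv_hi = behavior.drive_speed_range

    # nighttime ping schedule, shared across users (22:00-06:00 local,
    # sparse cadence); trips must end before the night window opens
    n_night = int(8 * 3600 // behavior.stationary_interval_s)
    night_offsets = np.arange(n_night) * behavior.stationary_interval_s
    night_naive = pd.DatetimeIndex([
        dt.datetime.combine(date, dt.time(22, 0)) + dt.timedelta(seconds=float(o))
        for date in day_dates for o in night_offsets])
    t_night_all = _local_to_epoch(night_naive, tz)
    night_start = t_night_all[::n_night]

    # planted trips ----------------------------------------------------
    for u, uid in enumerate(users):
        u_t, u_lat, u_lon = [], [], []
        for d, date in enumerate(day_dates):
            post = d >= behavior.intervention_day
            r_u = behavior.utilitarian_rate_pre * (
                behavior.utilitarian_post_multiplier if post else 1.0)
            r_l = behavior.leisure_rate_pre * (
                behavior.leisure_post_multiplier if post else 1.0)
            n_util = rng.poisson(r_u)
            n_leis = rng.poisson(r_l)
            n_drv = rng.poisson(behavior.drive_rate)
            if n_util + n_leis + n_drv == 0:
                continue
            weekday = date.weekday() < 5
            trips = []
            for _ in range(n_util):
                if weekday:
                    h = rng.normal(7.5, 1.0) if rng.random() < 0.5 else rng.normal(16.0, 1.0)
                else:
                    h = rng.normal(12.5, 1.5)
                trips.append(("walk_utilitarian", float(np.clip(h, 6.0, 21.0))))
            for _ in range(n_leis):
                trips.append(("walk_leisure",
                              float(np.clip(rng.normal(14.0, 3.0), 6.0, 21.0))))
            for _ in range(n_drv):
                trips.append(("drive", float(rng.uniform(7.0, 21.0))))
            trips.sort(key=lambda x: x[1])

            naive = pd.DatetimeIndex(
                [dt.datetime.combine(date, dt.time()) +
                 dt.timedelta(hours=h) for _, h in trips])
            starts = _local_to_epoch(naive, tz)
            prev_end = -np.inf
            for (kind, _), t0 in zip(trips, starts):
                t0 = int(max(t0, prev_end + 300))
                if kind == "drive":
                    L = float(rng.uniform(*behavior.drive_length_range))
                    v = float(rng.uniform(dv_lo, dv_hi))
                    line = world.excluded["geometry"].iloc[
                        int(rng.integers(0, max(1, len(world.excluded))))] \
                        if len(world.excluded) else None
                    if line is None:
                        continue
                    path = _drive_path(line, L, proj, rng)
                    dest_cat = None
                else:
                    v = float(rng.uniform(v_lo, v_hi))
                    if kind == "walk_utilitarian" and len(util_poi_idx):
                        L = float(rng.uniform(*behavior.utilitarian_length_range))
                        pi = int(util_poi_idx[rng.integers(0, len(util_poi_idx))])
                        head = [tuple(poi_xy[pi])]
                        start_key = node_keys[int(poi_node_idx[pi])]
                        dest_cat = pois["category"].iloc[pi]
                    else:
                        kind = "walk_leisure"
                        L = float(rng.uniform(*behavior.leisure_length_range))
                        ni = int(clear_nodes[rng.integers(0, len(clear_nodes))])
                        head, start_key = None, node_keys[ni]
                        dest_cat = None
                    path = _lattice_path(G, start_key, L, rng, head=head)
                if len(path) < 2:
                    continue
                # finish before the stationary night window opens
                cap = int(night_start[d] - L / v - 60)
                if t0 > cap:
                    t0 = cap
                    if t0 < prev_end + 300:
                        continue
                t, lat, lon = emit_pings(path, v, t0, behavior.ping_interval_s,
                                         behavior.gps_noise_sd_m, rng, proj)
                plen = float(np.hypot(*np.diff(path, axis=0).T).sum())
                u_t.append(t); u_lat.append(lat); u_lon.append(lon)
                truth_rows.append((f"gt_{seg_counter:07d}", uid, kind,
                                   int(t[0]), int(t[-1]), plen, dest_cat, d,
                                   home_tract[u]))
                seg_counter += 1
                prev_end = t[-1]

        # stationary nights at home --------------------------------------
        t_night = t_night_all
        n = len(t_night)
        xy = np.tile(home_xy[u], (n, 1))
        if behavior.gps_noise_sd_m > 0:
            xy = xy + rng.normal(0.0, behavior.gps_noise_sd_m, size=(n, 2))
        lat, lon = proj.to_latlon(xy[:, 0], xy[:, 1])
        u_t.append(t_night); u_lat.append(lat); u_lon.append(lon)
        for d in range(behavior.n_days):
            sl = slice(d * n_night, (d + 1) * n_night)
            truth_rows.append((f"gt_{seg_counter:07d}", uid, "stationary",
                               int(t_night[sl][0]), int(t_night[sl][-1]),
                               0.0, None, d, home_tract[u]))
            seg_counter += 1

        t_all = np.concatenate(u_t)
        ping_frames.append(pd.DataFrame({
            "user_id": uid, "t": t_all,
            "lat": np.concatenate(u_lat), "lon": np.concatenate(u_lon),
            "accuracy_m": behavior.gps_noise_sd_m,
        }))

    pings = pd.concat(ping_frames, ignore_index=True)
    pings["t"] = pd.to_datetime(pings["t"], unit="s", utc=True)
    pings = (pings.sort_values(["user_id", "t"], kind="mergesort")
                  .drop_duplicates(subset=["user_id", "t"], keep="first")
                  .reset_index(drop=True))
    truth = pd.DataFrame(truth_rows, columns=cols_t)
    truth["t_start"] = pd.to_datetime(truth["t_start"], unit="s", utc=True)
    truth["t_end"] = pd.to_datetime(truth["t_end"], unit="s", utc=True)
    return pings, truth


def _drive_path(line_lonlat: LineString, length: float,
                proj: LocalProjector, rng: np.random.Generator) -> np.ndarray:
    """Constant-heading travel along a road line.

    The trip is clamped to the room available from a random start in a
    random direction (never turning back: a U-turn within one ping gap
    would masquerade as a slow pair and break speed separability).
    """
    xy = np.asarray(line_lonlat.coords)
    x, y = proj.to_xy(xy[:, 1], xy[:, 0])
    line = LineString(np.column_stack([x, y]))
    L = line.length
    pos = float(rng.uniform(0.0, L))
    direction = 1 if rng.random() < 0.5 else -1
    room = (L - pos) if direction > 0 else pos
    if room < L / 2.0:  # start in the half with more room
        direction *= -1
        room = L - room
    end = pos + direction * min(length, room)
    coords = [line.interpolate(pos), line.interpolate(end)]
    return np.array([(p.x, p.y) for p in coords])


# ---------------------------------------------------------------------------
# Tract attributes with a planted linear outcome


def simulate_tract_attributes(n_tracts: int, n_msas: int,
                              beta: Optional[Dict[str, float]] = None,
                              noise_sd: float = 100.0,
                              seed: int = 0,
                              corr: Optional[np.ndarray] = None,
                              msa_intercepts=None,
                              ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw tract covariates and an outcome from the area-level model.

    Covariates come from a correlated Gaussian copula mapped to
    plausible units; the outcome is ``sum_j beta_j * z(x_j) + MSA
    intercept + N(0, noise_sd)`` where ``z`` standardizes each covariate
    over the generated sample (n-1 denominator).  Returns the attribute
    table and a truth table with the noise-free linear predictor and the
    noisy outcome (mean meters walked per person per day).
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if n_msas > n_tracts or n_msas <= 0 or n_tracts <= 0:
        raise ConfigurationError("need 0 < n_msas <= n_tracts")
    beta = dict(DEFAULT_BETA) if beta is None else dict(beta)
    corr = DEFAULT_COVARIATE_CORR if corr is None else np.asarray(corr)
    rng = np.random.default_rng(seed)

    z = rng.multivariate_normal(np.zeros(6), corr, size=n_tracts,
                                method="cholesky")
    u = norm.cdf(z)
    attrs = pd.DataFrame({
        "tract_id": [f"tract_{i:04d}" for i in range(n_tracts)],
        "msa_id": [f"msa_{i % n_msas:02d}" for i in range(n_tracts)],
        "median_income": 60_000.0 + 22_000.0 * z[:, 0],
        "frac_black": 0.02 + 0.9 * u[:, 1],
        "frac_public_transit": 0.01 + 0.6 * u[:, 2],
        "frac_over64": 0.05 + 0.3 * u[:, 3],
        "park_access": 50.0 + 15.0 * z[:, 4],
        "obesity_prev": 0.15 + 0.3 * u[:, 5],
        "population": np.round(rng.lognormal(np.log(4000.0), 0.4,
                                             size=n_tracts)),
    })

    if msa_intercepts is None:
        msa_intercepts = {f"msa_{m:02d}": DEFAULT_INTERCEPT + 25.0 * (m - (n_msas - 1) / 2.0)
                          for m in range(n_msas)}
    elif np.isscalar(msa_intercepts):
        msa_intercepts = {f"msa_{m:02d}": float(msa_intercepts)
                          for m in range(n_msas)}

    lin = np.array([msa_intercepts[m] for m in attrs["msa_id"]], dtype=float)
    for name in MODEL_COVARIATES:
        x = attrs[name].to_numpy(dtype=float)
        sd = x.std(ddof=1) if n_tracts > 1 else 1.0
        zx = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        lin = lin + beta.get(name, 0.0) * zx
    outcome = lin + (rng.normal(0.0, noise_sd, size=n_tracts)
                     if noise_sd > 0 else 0.0)
    truth = pd.DataFrame({
        "tract_id": attrs["tract_id"],
        "linear_predictor": lin,
        "outcome": outcome,
    })
    return attrs[TRACT_ATTRIBUTE_COLUMNS], truth
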
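"""Bout segmentation, filtering and pedestrian-area rules, checked
against brute-force references and planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import walkpulse as wp
from walkpulse.config import DetectConfig
from walkpulse.geodesy import EARTH_RADIUS_M, haversine_m
from walkpulse.walk_detect import (detect_walks, filter_min_distance,
                                   in_pedestrian_area, pairwise_speeds,
                                   pedestrian_mask, segment_bouts)

from conftest import T0, lon_deg, make_stream, make_world


# ---------------------------------------------------------------------------
# pairwise_speeds


def test_zero_displacement_zero_speed():
    pings = make_stream([0.0], [10.0])
    sp = pairwise_speeds(pings)
    assert sp["speed_mps"].iloc[0] == 0.0
    assert sp["gap_distance_m"].iloc[0] == 0.0


def test_derived_speed_example():
    """Two fixes 0.0006 deg of longitude apart at 42.36N, 30 s apart:
    ~49.3 m at ~1.64 m/s."""
    pings = pd.DataFrame({
        "user_id": "u", "t": [T0, T0 + pd.Timedelta(seconds=30)],
        "lat": [42.36, 42.36], "lon": [-71.06, -71.0594],
        "accuracy_m": np.nan})
    sp = pairwise_speeds(pings)
    assert sp["gap_distance_m"].iloc[0] == pytest.approx(49.31, abs=0.05)
    assert sp["speed_mps"].iloc[0] == pytest.approx(1.644, abs=0.002)


def test_same_timestamp_infinite_speed():
    pings = make_stream([30.0], [0.0])
    assert np.isinf(pairwise_speeds(pings)["speed_mps"]).all()


def test_unsorted_input_rejected():
    pings = make_stream([10.0, 10.0], [30.0, 30.0])
    with pytest.raises(ValueError):
        pairwise_speeds(pings.iloc[::-1].reset_index(drop=True))


# ---------------------------------------------------------------------------
# segment_bouts


def _speeds_stream(speeds, dt=30.0):
    return make_stream([s * dt for s in speeds], [dt] * len(speeds))


def test_all_slow_pairs_one_bout():
    bouts = segment_bouts(_speeds_stream([1.5, 1.5, 1.5]))
    assert len(bouts) == 1
    assert bouts["n_pings"].iloc[0] == 4


def test_fast_pair_splits_bouts():
    bouts = segment_bouts(_speeds_stream([1.5, 3.0, 1.5]))
    assert len(bouts) == 2
    assert (bouts["n_pings"] == 2).all()


def test_speed_boundary_inclusive():
    """A pair moving exactly at the threshold speed is inside a bout
    (the rule is 'did not exceed')."""
    pings = make_stream([60.0], [30.0])
    d = float(haversine_m(*pings[["lat", "lon"]].iloc[0],
                          *pings[["lat", "lon"]].iloc[1]))
    cfg = DetectConfig(speed_threshold_mps=d / 30.0)  # boundary exactly
    assert len(segment_bouts(pings, cfg)) == 1
    just_under = DetectConfig(speed_threshold_mps=d / 30.0 * (1 - 1e-12))
    assert len(segment_bouts(pings, just_under)) == 0


def test_long_time_gap_splits_bouts():
    pings = make_stream([30.0, 30.0], [30.0, 400.0])  # 400 s > max gap
    bouts = segment_bouts(pings)
    assert len(bouts) == 1
    assert bouts["n_pings"].iloc[0] == 2


def test_bouts_are_time_disjoint_per_user(small_sim):
    _, _, pings, _ = small_sim
    bouts = segment_bouts(pings.sort_values(["user_id", "t"]).reset_index(drop=True))
    for _, g in bouts.groupby("user_id"):
        g = g.sort_values("start_t")
        assert (g["start_t"].iloc[1:].to_numpy()
                >= g["end_t"].iloc[:-1].to_numpy()).all()


def test_empty_input_empty_output():
    empty = make_stream([], [])
    assert len(segment_bouts(empty)) == 0


# ---------------------------------------------------------------------------
# distance filter


def test_min_distance_boundary():
    bouts = pd.DataFrame({"distance_m": [49.9, 50.0, 120.0]})
    kept = filter_min_distance(bouts)
    assert list(kept["distance_m"]) == [50.0, 120.0]
    assert len(filter_min_distance(bouts.iloc[0:0])) == 0


# ---------------------------------------------------------------------------
# pedestrian area


def _bout_over(pings):
    b = segment_bouts(pings)
    assert len(b) == 1
    return b, pings


def test_pings_on_footway_qualify():
    L = 200.0
    world = make_world(ped_lines=[[(0.0, 0.0), (lon_deg(L), 0.0)]])
    bouts, pings = _bout_over(make_stream([40.0, 40.0], [30.0, 30.0]))
    assert pedestrian_mask(bouts, pings, world).all()
    assert in_pedestrian_area(bouts.iloc[0], pings, world)


def test_pings_inside_park_qualify_without_roads():
    side = lon_deg(500.0)
    world = make_world(parks=[[(-side, -side), (side, -side),
                               (side, side), (-side, side)]])
    bouts, pings = _bout_over(make_stream([40.0, 40.0], [30.0, 30.0]))
    assert pedestrian_mask(bouts, pings, world).all()


def test_ping_beyond_buffer_disqualifies():
    """One ping 25 m from the nearest pedestrian segment (buffer 20 m),
    outside parks: bout rejected."""
    world = make_world(ped_lines=[[(0.0, 0.0), (lon_deg(200.0), 0.0)]])
    lat_off = float(np.degrees(25.0 / EARTH_RADIUS_M))
    pings = make_stream([40.0, 40.0], [30.0, 30.0])
    pings.loc[1, "lat"] = lat_off  # 25 m north of the footway
    bouts = segment_bouts(pings)
    assert not pedestrian_mask(bouts, pings, world).any()


def test_empty_world_rejects_all_with_warning(caplog):
    world = make_world()
    bouts, pings = _bout_over(make_stream([40.0, 40.0], [30.0, 30.0]))
    with caplog.at_level("WARNING"):
        assert not pedestrian_mask(bouts, pings, world).any()
    assert "no pedestrian" in caplog.text


# ---------------------------------------------------------------------------
# detect_walks end to end


def test_planted_drive_yields_no_bouts(small_sim):
    world, _, pings, truth = small_sim
    drives = truth[truth["kind"] == "drive"]
    bouts = detect_walks(pings, world)
    for _, d in drives.iterrows():
        hit = bouts[(bouts["user_id"] == d["user_id"])
                    & (bouts["start_t"] <= d["t_end"])
                    & (bouts["end_t"] >= d["t_start"])]
        assert len(hit) == 0


def test_planted_walk_recovered_with_distance_tolerance(tiny_world):
    """A planted ~400 m utilitarian walk comes back as one bout whose
    measured distance is within noise+corner-cut tolerance."""
    _, world, _ = tiny_world
    beh = wp.BehaviorConfig(n_users=1, n_days=3, seed=21,
                            utilitarian_rate_pre=1.0, leisure_rate_pre=0.0,
                            drive_rate=0.0,
                            utilitarian_length_range=(400.0, 400.0))
    pings, truth = wp.simulate_traces(world, beh)
    bouts = detect_walks(pings, world)
    walks = truth[truth["kind"] == "walk_utilitarian"]
    assert len(bouts) == len(walks)
    for _, b in bouts.iterrows():
        # chord sampling can only shorten the measured path, at worst by
        # 1/sqrt(2) (every inter-ping gap straddling a right-angle turn);
        # noise inflates it slightly
        assert 400.0 / np.sqrt(2) - 10 <= b["distance_m"] <= 440.0


def test_stationary_jitter_produces_no_bouts(tiny_world):
    """A user who never leaves home generates only jittered stationary
    pings; the detector must find zero walks."""
    _, world, _ = tiny_world
    beh = wp.BehaviorConfig(n_users=3, n_days=10, seed=22,
                            utilitarian_rate_pre=0.0, leisure_rate_pre=0.0,
                            drive_rate=0.0)
    pings, truth = wp.simulate_traces(world, beh)
    assert (truth["kind"] == "stationary").all()
    assert len(detect_walks(pings, world)) == 0


def test_idempotence_on_detected_bout(small_sim):
    """Re-running detection on the pings of a detected bout returns
    that bout unchanged."""
    world, _, pings, _ = small_sim
    pings = pings.sort_values(["user_id", "t"]).reset_index(drop=True)
    bouts = detect_walks(pings, world)
    for _, b in bouts.head(5).iterrows():
        sub = pings.iloc[b["start_idx"]:b["end_idx"] + 1].reset_index(drop=True)
        again = detect_walks(sub, world)
        assert len(again) == 1
        assert again["n_pings"].iloc[0] == b["n_pings"]
        assert again["distance_m"].iloc[0] == pytest.approx(b["distance_m"])


# ---------------------------------------------------------------------------
# properties


def _brute_segment(pings, cfg):
    """Single-pass reference segmentation (independent of the
    vectorized implementation)."""
    lat = pings["lat"].to_numpy()
    lon = pings["lon"].to_numpy()
    ts = pings["t"].astype("int64").to_numpy() / 1e9
    uid = pings["user_id"].to_numpy()
    bouts, run = [], [0]
    for i in range(len(pings) - 1):
        d = float(haversine_m(lat[i], lon[i], lat[i + 1], lon[i + 1]))
        gap = ts[i + 1] - ts[i]
        ok = (uid[i] == uid[i + 1] and gap > 0
              and gap <= cfg.max_ping_gap_s
              and d / gap <= cfg.speed_threshold_mps)
        if ok:
            run.append(i + 1)
        else:
            if len(run) >= cfg.min_pings_per_bout:
                bouts.append((run[0], run[-1]))
            run = [i + 1]
    if len(run) >= cfg.min_pings_per_bout:
        bouts.append((run[0], run[-1]))
    return bouts


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.0, 300.0), st.floats(1.0, 400.0)),
                min_size=1, max_size=15))
def test_segmentation_matches_brute_force(pairs):
    pings = make_stream([p[0] for p in pairs], [p[1] for p in pairs])
    cfg = DetectConfig()
    got = [(a, b) for a, b in
           zip(segment_bouts(pings, cfg)["start_idx"],
               segment_bouts(pings, cfg)["end_idx"])]
    assert got == _brute_segment(pings, cfg)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(0.1, 4.0), min_size=1, max_size=12),
       st.floats(1.5, 3.0))
def test_threshold_monotonicity(speeds, higher):
    """Raising the speed threshold never shrinks the set of pings
    covered by candidate bouts (a raw bout count is not monotone: a
    higher threshold can merge two bouts across a fast pair)."""
    pings = _speeds_stream(speeds)

    def covered(threshold):
        b = segment_bouts(pings, DetectConfig(speed_threshold_mps=threshold))
        return int(b["n_pings"].sum()) if len(b) else 0

    assert covered(max(1.5, higher)) >= covered(1.5)
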
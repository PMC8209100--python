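"""Panel aggregation: home tracts, weights, summaries, engagement,
temporal patterns, relative change and quintile series."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import walkpulse as wp
from walkpulse.panel_stats import (active_user_days, assign_home_tract,
                                   engagement_stats, hourly_weekday_matrix,
                                   population_quantile_groups,
                                   poststratification_weights,
                                   quintile_timeseries, relative_change,
                                   user_day_summaries, weighted_mean)

D0 = dt.date(2020, 2, 17)  # a Monday


def _summaries(rows):
    """rows: (user, day_offset, n_util, n_leis, m_util, m_leis, minutes,
    weight, tract)"""
    recs = []
    for (u, d, nu, nl, mu, ml, mins, w, tr) in rows:
        recs.append({
            "user_id": u, "date": D0 + dt.timedelta(days=d),
            "home_tract": tr, "weight": w,
            "n_bouts_total": nu + nl, "n_bouts_utilitarian": nu,
            "n_bouts_leisure": nl,
            "distance_m_total": mu + ml, "distance_m_utilitarian": mu,
            "distance_m_leisure": ml, "minutes_total": mins,
        })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# home tract


def test_modal_nighttime_tract_wins(small_sim):
    world, beh, pings, truth = small_sim
    homes = assign_home_tract(pings, world, beh.timezone)
    want = truth.drop_duplicates("user_id").set_index("user_id")["home_tract"]
    got = homes.set_index("user_id")["home_tract"]
    assert (got == want.loc[got.index]).all()


def test_tie_breaks_to_smallest_tract_id(tiny_world):
    _, world, _ = tiny_world
    # one nighttime ping in each of two tracts -> tie -> smallest id
    c0 = world._project_geoms(world.tracts["geometry"][:2])
    pts = [g.centroid for g in c0]
    lat, lon = world.projector.to_latlon(
        np.array([p.x for p in pts]), np.array([p.y for p in pts]))
    pings = pd.DataFrame({
        "user_id": "u1",
        "t": pd.to_datetime(["2020-02-01 03:00:00",
                             "2020-02-02 03:00:00"], utc=True),
        "lat": lat, "lon": lon, "accuracy_m": np.nan})
    homes = assign_home_tract(pings, world, "UTC")
    t0, t1 = world.tracts["tract_id"][:2]
    assert homes["home_tract"].iloc[0] == min(t0, t1)


def test_user_outside_layer_excluded(tiny_world, caplog):
    _, world, _ = tiny_world
    pings = pd.DataFrame({
        "user_id": "far_away",
        "t": pd.to_datetime(["2020-02-01 03:00:00"], utc=True),
        "lat": [-45.0], "lon": [10.0], "accuracy_m": np.nan})
    with caplog.at_level("WARNING"):
        homes = assign_home_tract(pings, world, "UTC")
    assert len(homes) == 0
    assert "excluded" in caplog.text


# ---------------------------------------------------------------------------
# weights


def test_weight_ratio_example():
    """Two tracts, populations 1000/3000, 100 devices each ->
    weights 0.5 and 1.5."""
    homes = pd.DataFrame({
        "user_id": [f"u{i}" for i in range(200)],
        "home_tract": ["a"] * 100 + ["b"] * 100})
    pop = pd.DataFrame({"tract_id": ["a", "b"], "population": [1000, 3000]})
    w = poststratification_weights(homes, pop)
    assert np.allclose(w["weight"][:100], 0.5)
    assert np.allclose(w["weight"][100:], 1.5)


def test_proportional_devices_give_unit_weights():
    homes = pd.DataFrame({
        "user_id": [f"u{i}" for i in range(30)],
        "home_tract": ["a"] * 10 + ["b"] * 20})
    pop = pd.DataFrame({"tract_id": ["a", "b"], "population": [500, 1000]})
    w = poststratification_weights(homes, pop)
    assert np.allclose(w["weight"], 1.0)


def test_weighted_device_share_equals_population_share():
    rng = np.random.default_rng(3)
    tracts = [f"t{i}" for i in range(8)]
    homes = pd.DataFrame({
        "user_id": [f"u{i}" for i in range(300)],
        "home_tract": rng.choice(tracts, size=300)})
    pop = pd.DataFrame({"tract_id": tracts,
                        "population": rng.integers(500, 5000, size=8)})
    w = poststratification_weights(homes, pop).merge(homes, on="user_id")
    share = w.groupby("home_tract")["weight"].sum() / w["weight"].sum()
    pop_share = (pop.set_index("tract_id")["population"]
                 / pop["population"].sum())
    assert np.allclose(share.sort_index(), pop_share.sort_index(), atol=1e-12)


# ---------------------------------------------------------------------------
# summaries


def test_user_day_counts_and_zero_rows():
    bouts = pd.DataFrame({
        "bout_id": ["b0", "b1", "b2"],
        "user_id": ["u1", "u1", "u1"],
        "date": [D0, D0, D0],
        "purpose": ["utilitarian", "utilitarian", "leisure"],
        "distance_m": [300.0, 200.0, 900.0],
        "duration_min": [5.0, 4.0, 15.0]})
    homes = pd.DataFrame({"user_id": ["u1", "u2"], "home_tract": ["a", "a"]})
    weights = pd.DataFrame({"user_id": ["u1", "u2"], "weight": [1.0, 1.0]})
    calendar = pd.DataFrame({"user_id": ["u1", "u2"], "date": [D0, D0]})
    s = user_day_summaries(bouts, homes, weights, calendar)
    r1 = s[s["user_id"] == "u1"].iloc[0]
    assert (r1["n_bouts_total"], r1["n_bouts_utilitarian"],
            r1["n_bouts_leisure"]) == (3, 2, 1)
    assert r1["distance_m_total"] == 1400.0
    r2 = s[s["user_id"] == "u2"].iloc[0]
    assert r2["n_bouts_total"] == 0 and r2["distance_m_total"] == 0.0


def test_weighted_mean_arithmetic():
    assert weighted_mean([10.0, 20.0], [0.5, 1.5]) == pytest.approx(17.5)


def test_zero_inflation_closed_form():
    """Adding k zero-walking users scales the unweighted per-user mean
    by n/(n+k)."""
    rows = [("u%d" % i, 0, 1, 0, 400.0, 0.0, 6.0, 1.0, "a") for i in range(4)]
    s = _summaries(rows)
    m0 = weighted_mean(s["distance_m_total"], s["weight"])
    rows += [("z%d" % i, 0, 0, 0, 0.0, 0.0, 0.0, 1.0, "a") for i in range(4)]
    s2 = _summaries(rows)
    m1 = weighted_mean(s2["distance_m_total"], s2["weight"])
    assert m1 == pytest.approx(m0 * 4 / 8)


# ---------------------------------------------------------------------------
# engagement


def test_guideline_boundary_five_days():
    rows = [("u1", d, 1, 0, 400.0, 0.0, 31.0, 1.0, "a") for d in range(5)]
    rows += [("u2", d, 1, 0, 400.0, 0.0, 31.0, 1.0, "a") for d in range(4)]
    # pad the week so both users are present all 7 days
    rows += [("u1", d, 0, 0, 0.0, 0.0, 0.0, 1.0, "a") for d in range(5, 7)]
    rows += [("u2", d, 0, 0, 0.0, 0.0, 0.0, 1.0, "a") for d in range(4, 7)]
    e = engagement_stats(_summaries(rows))
    assert len(e) == 1
    assert e["frac_guideline"].iloc[0] == pytest.approx(0.5)  # u1 yes, u2 no


def test_single_short_bout_engagement():
    rows = [("u1", 0, 1, 0, 200.0, 0.0, 5.0, 1.0, "a")]
    e = engagement_stats(_summaries(rows))
    assert e["frac_ge1_bout"].iloc[0] == 1.0
    assert e["frac_ge10_min"].iloc[0] == 0.0


# ---------------------------------------------------------------------------
# hourly matrix


def test_single_cell_matrix():
    bouts = pd.DataFrame({
        "bout_id": ["b0"], "user_id": ["u1"],
        "start_t": pd.to_datetime(["2020-02-17 07:30:00"], utc=True),  # Monday
        "date": [D0], "purpose": ["utilitarian"], "distance_m": [300.0],
        "duration_min": [5.0]})
    calendar = pd.DataFrame({"user_id": ["u1"], "date": [D0]})
    weights = pd.DataFrame({"user_id": ["u1"], "weight": [1.0]})
    m = hourly_weekday_matrix(bouts, calendar, weights, timezone="UTC")
    assert m.loc[7, 0] == 1.0
    assert m.to_numpy().sum() == 1.0


def test_matrix_conserves_bout_count(small_sim):
    world, beh, pings, _ = small_sim
    bouts = wp.detect_walks(pings, world, timezone=beh.timezone)
    labeled, _ = wp.classify_all(bouts, world)
    calendar = active_user_days(pings, beh.timezone)
    weights = pd.DataFrame({"user_id": calendar["user_id"].unique()})
    weights["weight"] = 1.0
    m = hourly_weekday_matrix(labeled, calendar, weights,
                              timezone=beh.timezone)
    days = pd.to_datetime(calendar["date"]).dt.weekday.value_counts()
    # column sums x weighted user-days per weekday recompose the total
    total = sum(m[d].sum() * days[d] for d in days.index)
    assert total == pytest.approx(len(labeled), rel=1e-9)


# ---------------------------------------------------------------------------
# relative change


def _windows():
    return wp.PeriodWindows(pre_start=D0, pre_end=D0 + dt.timedelta(days=6),
                            intervention_date=D0 + dt.timedelta(days=7),
                            post_start=D0 + dt.timedelta(days=7),
                            post_end=D0 + dt.timedelta(days=13))


def test_relative_change_arithmetic():
    rows = [("u1", d, 1, 0, 10.0, 0.0, 1.0, 1.0, "a") for d in range(7)]
    rows += [("u1", d, 1, 0, 3.0, 0.0, 1.0, 1.0, "a") for d in range(7, 14)]
    ch = relative_change(_summaries(rows), _windows(), group_by="city")
    assert ch["pct_change"].iloc[0] == pytest.approx(-70.0)


def test_no_change_zero_pct():
    rows = [("u1", d, 1, 0, 10.0, 0.0, 1.0, 1.0, "a") for d in range(14)]
    ch = relative_change(_summaries(rows), _windows(), group_by="city")
    assert ch["pct_change"].iloc[0] == pytest.approx(0.0)


def test_zero_pre_mean_is_missing_with_warning(caplog):
    rows = [("u1", d, 0, 0, 0.0, 0.0, 0.0, 1.0, "a") for d in range(7)]
    rows += [("u1", d, 1, 0, 5.0, 0.0, 1.0, 1.0, "a") for d in range(7, 14)]
    with caplog.at_level("WARNING"):
        ch = relative_change(_summaries(rows), _windows(), group_by="city")
    assert np.isnan(ch["pct_change"].iloc[0])
    assert "zero pre-period" in caplog.text


# ---------------------------------------------------------------------------
# quintiles


def test_equal_population_tracts_one_per_quintile():
    attrs = pd.DataFrame({
        "tract_id": [f"t{i}" for i in range(5)],
        "median_income": [10, 20, 30, 40, 50],
        "population": [100] * 5})
    g = population_quantile_groups(attrs, "median_income")
    assert list(g.sort_values("tract_id")["group"]) == [1, 2, 3, 4, 5]


def test_constant_attribute_single_group(caplog):
    attrs = pd.DataFrame({"tract_id": ["a", "b"], "median_income": [1, 1],
                          "population": [5, 5]})
    with caplog.at_level("WARNING"):
        g = population_quantile_groups(attrs, "median_income")
    assert (g["group"] == 1).all()
    assert "constant" in caplog.text


def test_quintile_means_recompose_overall_mean():
    rng = np.random.default_rng(11)
    tracts = [f"t{i}" for i in range(10)]
    attrs = pd.DataFrame({"tract_id": tracts,
                          "median_income": rng.normal(size=10),
                          "population": rng.integers(100, 1000, size=10)})
    rows = []
    for i, u in enumerate(f"u{k}" for k in range(60)):
        rows.append((u, i % 7, 1, 0, float(rng.uniform(0, 800)), 0.0, 5.0,
                     float(rng.uniform(0.5, 2.0)), tracts[i % 10]))
    s = _summaries(rows)
    series, _ = quintile_timeseries(s, attrs, "median_income")
    groups = population_quantile_groups(attrs, "median_income")
    sg = s.merge(groups, left_on="home_tract", right_on="tract_id")
    overall = weighted_mean(s["distance_m_total"], s["weight"])
    parts = sg.groupby("group").apply(
        lambda g: (weighted_mean(g["distance_m_total"], g["weight"]),
                   g["weight"].sum()), include_groups=False)
    recomposed = sum(m * w for m, w in parts) / sum(w for _, w in parts)
    assert recomposed == pytest.approx(overall, rel=1e-9)


def test_planted_income_gradient_recovered():
    """A planted income-dependent post-period recovery (low-income drop
    larger) shows up as quintile-1 change below quintile-5 change."""
    tracts = [f"t{i}" for i in range(5)]
    attrs = pd.DataFrame({"tract_id": tracts,
                          "median_income": [10, 20, 30, 40, 50],
                          "population": [100] * 5})
    rows = []
    for i, tr in enumerate(tracts):
        mult = 0.2 + 0.15 * i  # low income drops hardest
        for d in range(14):
            m = 10.0 if d < 7 else 10.0 * mult
            rows.append((f"u{i}", d, 1, 0, m, 0.0, 1.0, 1.0, tr))
    _, changes = quintile_timeseries(_summaries(rows), attrs,
                                     "median_income", windows=_windows())
    tot = changes[changes["purpose"] == "total"].set_index("group")
    assert tot.loc[1, "pct_change"] < tot.loc[5, "pct_change"]
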
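"""Panel aggregation of labelled walk bouts.

Builds per-user-day walking summaries (with explicit zero days), joins
home census tracts, applies post-stratification weights so device counts
match population shares, and derives the descriptive statistics of the
analysis: weekly engagement, hour-by-weekday temporal patterns, pre/post
relative changes, and population-weighted quintile series over tract
attributes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PeriodWindows
from .geo_io import GeoWorld

logger = logging.getLogger("walkpulse")


def weighted_mean(x, w) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(x) == 0 or w.sum() == 0:
        return np.nan
    return float(np.average(x, weights=w))


# ---------------------------------------------------------------------------
# Home tracts and weights


def assign_home_tract(pings: pd.DataFrame, world: GeoWorld,
                      timezone: str = "UTC") -> pd.DataFrame:
    """Map each user to a home tract.

    Home is the modal tract of pings observed in the local 22:00-06:00
    window; users with no nighttime pings fall back to the modal tract
    of all their pings.  Users whose pings match no tract are excluded
    (count logged).  Modal ties break to the lexicographically smallest
    tract id.
    """
    local = pings["t"].dt.tz_convert(timezone)
    hour = local.dt.hour
    night = (hour >= 22) | (hour < 6)
    tract = pd.Series(world.tract_of(pings["lat"].to_numpy(),
                                     pings["lon"].to_numpy()),
                      index=pings.index)
    df = pd.DataFrame({"user_id": pings["user_id"], "tract": tract,
                       "night": night}).dropna(subset=["tract"])

    def modal(s: pd.Series):
        counts = s.value_counts()
        top = counts[counts == counts.max()].index
        return sorted(top)[0]

    rows = []
    for uid, g in df.groupby("user_id", sort=True):
        sub = g[g["night"]]
        src = sub if len(sub) else g
        rows.append((uid, modal(src["tract"])))
    out = pd.DataFrame(rows, columns=["user_id", "home_tract"])
    n_excluded = pings["user_id"].nunique() - len(out)
    if n_excluded:
        logger.warning("assign_home_tract: %d user(s) matched no tract "
                       "and were excluded", n_excluded)
    return out


def poststratification_weights(homes: pd.DataFrame,
                               tract_population: pd.DataFrame) -> pd.DataFrame:
    """Per-user post-stratification weights.

    ``w(user in tract a) = (pop_a / total pop) / (devices_a / total
    devices)``, then normalized to mean 1 over users.  Only tracts with
    at least one device contribute users (a zero-device tract has no
    users to weight).
    """
    pop = tract_population.set_index("tract_id")["population"].astype(float)
    devices = homes["home_tract"].value_counts()
    pop = pop.reindex(devices.index).fillna(0.0)
    pop_share = pop / pop.sum()
    dev_share = devices / devices.sum()
    w_tract = pop_share / dev_share
    w = homes["home_tract"].map(w_tract).astype(float)
    w = w / w.mean()
    return pd.DataFrame({"user_id": homes["user_id"], "weight": w})


# ---------------------------------------------------------------------------
# Per-user-day summaries


def active_user_days(pings: pd.DataFrame, timezone: str = "UTC") -> pd.DataFrame:
    """Distinct (user_id, local date) pairs with at least one ping: the
    denominator for per-user daily averages."""
    date = pings["t"].dt.tz_convert(timezone).dt.date
    return (pd.DataFrame({"user_id": pings["user_id"], "date": date})
            .drop_duplicates().reset_index(drop=True))


def user_day_summaries(bouts: pd.DataFrame, homes: pd.DataFrame,
                       weights: pd.DataFrame,
                       calendar: pd.DataFrame) -> pd.DataFrame:
    """One row per active (user, date) with bout counts, meters and
    minutes split by purpose; zero-walking days are explicit rows.

    ``calendar`` is the active user-day table (see
    :func:`active_user_days`); bouts must carry ``purpose`` and ``date``.
    Users absent from ``homes`` (no tract match) are dropped.
    """
    base = calendar.merge(homes, on="user_id").merge(weights, on="user_id")
    if len(bouts):
        b = bouts.copy()
        b["util"] = (b["purpose"] == "utilitarian")
        b["dist_util"] = b["distance_m"] * b["util"]
        agg = (b.groupby(["user_id", "date"], sort=False)
               .agg(n_bouts_total=("bout_id", "size"),
                    n_bouts_utilitarian=("util", "sum"),
                    distance_m_total=("distance_m", "sum"),
                    distance_m_utilitarian=("dist_util", "sum"),
                    minutes_total=("duration_min", "sum"))
               .reset_index())
    else:
        agg = pd.DataFrame(columns=["user_id", "date", "n_bouts_total",
                                    "n_bouts_utilitarian", "distance_m_total",
                                    "distance_m_utilitarian", "minutes_total"])
    out = base.merge(agg, on=["user_id", "date"], how="left")
    for c in ("n_bouts_total", "n_bouts_utilitarian", "distance_m_total",
              "distance_m_utilitarian", "minutes_total"):
        out[c] = out[c].fillna(0.0)
    out["n_bouts_leisure"] = out["n_bouts_total"] - out["n_bouts_utilitarian"]
    out["distance_m_leisure"] = out["distance_m_total"] - out["distance_m_utilitarian"]
    return out


# ---------------------------------------------------------------------------
# Engagement


def engagement_stats(summaries: pd.DataFrame) -> pd.DataFrame:
    """Weekly engagement per ISO week (Monday start).

    Per week: weighted fraction of users with >=1 bout; weighted
    fraction with >=10 walking minutes; mean bouts per user per day;
    weighted fraction meeting the activity guideline (>=30 walking
    minutes on >=5 distinct days of the week).
    """
    s = summaries.copy()
    iso = pd.to_datetime(s["date"]).dt.isocalendar()
    s["week"] = iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    rows = []
    for wk, g in s.groupby("week", sort=True):
        per_user = g.groupby("user_id").agg(
            weight=("weight", "first"),
            bouts=("n_bouts_total", "sum"),
            minutes=("minutes_total", "sum"),
            days_30min=("minutes_total", lambda m: int((m >= 30).sum())),
            n_days=("date", "nunique"),
        )
        w = per_user["weight"]
        rows.append({
            "week": wk,
            "n_users": len(per_user),
            "frac_ge1_bout": weighted_mean(per_user["bouts"] >= 1, w),
            "frac_ge10_min": weighted_mean(per_user["minutes"] >= 10, w),
            "bouts_per_user_day": weighted_mean(
                per_user["bouts"] / per_user["n_days"], w),
            "frac_guideline": weighted_mean(per_user["days_30min"] >= 5, w),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Temporal patterns


def hourly_weekday_matrix(bouts: pd.DataFrame, calendar: pd.DataFrame,
                          weights: pd.DataFrame,
                          period: Optional[Tuple] = None,
                          purpose: Optional[str] = None,
                          timezone: str = "UTC") -> pd.DataFrame:
    """24x7 matrix: weighted mean bouts per active user starting in
    local hour h (rows 0-23) on weekday d (columns 0=Mon..6=Sun).

    Entry(h, d) = weighted bout count in the cell divided by the
    weighted number of active user-days on weekday d within the period.
    """
    cal = calendar.merge(weights, on="user_id")
    b = bouts.copy()
    if purpose is not None:
        b = b[b["purpose"] == purpose]
    if period is not None:
        lo, hi = period
        cal = cal[(cal["date"] >= lo) & (cal["date"] <= hi)]
        b = b[(b["date"] >= lo) & (b["date"] <= hi)]
    b = b.merge(weights, on="user_id")
    local = b["start_t"].dt.tz_convert(timezone)
    hour = local.dt.hour
    wday = local.dt.weekday
    denom = (cal.assign(wd=pd.to_datetime(cal["date"]).dt.weekday)
             .groupby("wd")["weight"].sum())
    mat = np.zeros((24, 7))
    num = (pd.DataFrame({"h": hour, "d": wday, "w": b["weight"]})
           .groupby(["h", "d"])["w"].sum())
    for (h, d), v in num.items():
        if d in denom.index and denom[d] > 0:
            mat[h, d] = v / denom[d]
    return pd.DataFrame(mat, index=pd.RangeIndex(24, name="hour"),
                        columns=pd.RangeIndex(7, name="weekday"))


# ---------------------------------------------------------------------------
# Pre/post relative change


def _window_mask(dates: pd.Series, lo, hi) -> pd.Series:
    return (dates >= lo) & (dates <= hi)


def _period_means(summaries: pd.DataFrame, windows: PeriodWindows,
                  value: str) -> Tuple[float, float]:
    d = summaries["date"]
    pre = summaries[_window_mask(d, windows.pre_start, windows.pre_end)]
    post = summaries[_window_mask(d, windows.post_start, windows.post_end)]
    return (weighted_mean(pre[value], pre["weight"]),
            weighted_mean(post[value], post["weight"]))


def relative_change(summaries: pd.DataFrame, windows: PeriodWindows,
                    group_by: str = "city",
                    tract_attributes: Optional[pd.DataFrame] = None,
                    attribute: Optional[str] = None,
                    value: str = "distance_m_total") -> pd.DataFrame:
    """Percent change, post vs pre, of the weighted per-user-day value.

    ``group_by``: 'city' (whole panel), 'tract' (home tract), 'purpose'
    (total/utilitarian/leisure distance), or 'quintile' (population-
    weighted quintiles of ``attribute`` from ``tract_attributes``).
    A zero pre-period mean yields a missing change with a warning.
    """
    rows = []
    if group_by == "purpose":
        for purpose, col in (("total", "distance_m_total"),
                             ("utilitarian", "distance_m_utilitarian"),
                             ("leisure", "distance_m_leisure")):
            pre, post = _period_means(summaries, windows, col)
            rows.append(("purpose", purpose, pre, post))
    elif group_by == "city":
        pre, post = _period_means(summaries, windows, value)
        rows.append(("city", "all", pre, post))
    elif group_by == "tract":
        for tr, g in summaries.groupby("home_tract", sort=True):
            pre, post = _period_means(g, windows, value)
            rows.append(("tract", tr, pre, post))
    elif group_by == "quintile":
        if tract_attributes is None or attribute is None:
            raise ValueError("quintile grouping needs tract_attributes and attribute")
        groups = population_quantile_groups(tract_attributes, attribute)
        s = summaries.merge(groups, left_on="home_tract", right_on="tract_id")
        for q, g in s.groupby("group", sort=True):
            pre, post = _period_means(g, windows, value)
            rows.append((f"quintile:{attribute}", q, pre, post))
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    out = pd.DataFrame(rows, columns=["group_type", "group", "mean_pre", "mean_post"])
    zero = out["mean_pre"] == 0
    if zero.any():
        logger.warning("relative_change: %d group(s) have zero pre-period "
                       "mean; change undefined", int(zero.sum()))
    out["pct_change"] = np.where(
        zero, np.nan, 100.0 * (out["mean_post"] - out["mean_pre"]) / out["mean_pre"])
    return out


# ---------------------------------------------------------------------------
# Quintile series


def population_quantile_groups(tract_attributes: pd.DataFrame, attribute: str,
                               n_groups: int = 5,
                               population_weighted: bool = True) -> pd.DataFrame:
    """Rank tracts by an attribute and cut into groups holding ~equal
    population (or equal tract counts if ``population_weighted`` is
    False).  Returns tract_id -> group (1 = lowest attribute values).
    """
    df = tract_attributes[["tract_id", attribute, "population"]].copy()
    if df[attribute].nunique() <= 1:
        logger.warning("population_quantile_groups: attribute %r is constant; "
                       "single group returned", attribute)
        return pd.DataFrame({"tract_id": df["tract_id"], "group": 1})
    df = df.sort_values([attribute, "tract_id"], kind="mergesort")
    w = (df["population"].astype(float) if population_weighted
         else pd.Series(1.0, index=df.index))
    cum = w.cumsum() - w / 2.0
    share = cum / w.sum()
    df["group"] = np.minimum(n_groups, np.floor(share * n_groups).astype(int) + 1)
    return df[["tract_id", "group"]].reset_index(drop=True)


def quintile_timeseries(summaries: pd.DataFrame,
                        tract_attributes: pd.DataFrame, attribute: str,
                        n_groups: int = 5,
                        windows: Optional[PeriodWindows] = None,
                        population_weighted: bool = True
                        ) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Daily weighted mean distance per attribute group, plus (when
    ``windows`` is given) a per-group utilitarian/leisure change table.
    """
    groups = population_quantile_groups(tract_attributes, attribute,
                                        n_groups, population_weighted)
    s = summaries.merge(groups, left_on="home_tract", right_on="tract_id")
    series = (s.groupby(["group", "date"])
              .apply(lambda g: weighted_mean(g["distance_m_total"], g["weight"]),
                     include_groups=False)
              .rename("mean_distance_m").reset_index())
    changes = None
    if windows is not None:
        rows = []
        for q, g in s.groupby("group", sort=True):
            for purpose, col in (("total", "distance_m_total"),
                                 ("utilitarian", "distance_m_utilitarian"),
                                 ("leisure", "distance_m_leisure")):
                pre, post = _period_means(g, windows, col)
                pct = (np.nan if pre == 0
                       else 100.0 * (post - pre) / pre)
                rows.append((q, purpose, pre, post, pct))
        changes = pd.DataFrame(rows, columns=["group", "purpose", "mean_pre",
                                              "mean_post", "pct_change"])
    return series, changes
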
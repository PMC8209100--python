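"""Trip-purpose labelling: utilitarian vs leisure walking.

Short bouts (up to 750 m by default) are utilitarian — they overwhelm-
ingly correspond to errands and transport legs.  Longer bouts are judged
by their destination: the closest POI within 25 m of the final ping.  A
long bout is leisure when no POI is matched or when the matched POI is a
city/outdoors destination (which includes residential areas); any other
matched category (food, work, transportation, ...) makes it utilitarian.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import ClassifyConfig
from .geo_io import GeoWorld


def nearest_poi(lat: float, lon: float, world: GeoWorld,
                radius_m: float) -> Optional[pd.Series]:
    """The POI minimizing great-circle distance to the point, among POIs
    within ``radius_m``; None if there is none.  Exact distance ties
    break toward the lowest ``poi_id``."""
    cand = world.pois_within(lat, lon, radius_m)
    if len(cand) == 0:
        return None
    cand = cand.sort_values(["dist_m", "poi_id"], kind="mergesort")
    return cand.iloc[0]


def classify_bout(bout: pd.Series, world: GeoWorld,
                  config: Optional[ClassifyConfig] = None
                  ) -> Tuple[str, Optional[str]]:
    """Label one bout; returns (purpose, destination_category).

    Requires ``distance_m`` and ``end_lat``/``end_lon`` on the bout.
    """
    config = config or ClassifyConfig()
    d = float(bout["distance_m"])
    short = (d <= config.distance_threshold_m if config.boundary_to_utilitarian
             else d < config.distance_threshold_m)
    poi = nearest_poi(float(bout["end_lat"]), float(bout["end_lon"]),
                      world, config.poi_match_radius_m)
    dest = None if poi is None else poi["category"]
    if short:
        return "utilitarian", dest
    if poi is None or poi["category"] in config.leisure_categories:
        return "leisure", dest
    return "utilitarian", dest


def classify_all(bouts: pd.DataFrame, world: GeoWorld,
                 config: Optional[ClassifyConfig] = None
                 ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Label every bout and summarize destinations.

    Returns the labelled bout table and a per-destination-category
    summary (count, share, mean bout distance); bouts without a matched
    POI appear under category ``(none)``.
    """
    config = config or ClassifyConfig()
    bouts = bouts.copy()
    purposes, dests = [], []
    for _, b in bouts.iterrows():
        p, c = classify_bout(b, world, config)
        purposes.append(p)
        dests.append(c)
    bouts["purpose"] = purposes
    bouts["destination_category"] = dests
    key = bouts["destination_category"].fillna("(none)")
    if len(bouts):
        summary = (bouts.assign(_cat=key)
                   .groupby("_cat")
                   .agg(n_bouts=("bout_id", "size"),
                        mean_distance_m=("distance_m", "mean"))
                   .reset_index().rename(columns={"_cat": "destination_category"}))
        summary["share"] = summary["n_bouts"] / summary["n_bouts"].sum()
    else:
        summary = pd.DataFrame(columns=["destination_category", "n_bouts",
                                        "mean_distance_m", "share"])
    return bouts, summary
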
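"""Evaluation of detection/classification against planted ground truth.

The synthetic generator emits a truth table of planted segments (walks,
drives, stationary nights).  These helpers match detected bouts to
truth segments by user and time overlap and compute recovery metrics:
sensitivity (planted walks recovered), false-discovery rate (detected
bouts not overlapping a planted walk), drives mistaken for walks, and
purpose-label accuracy.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd


def match_bouts(bouts: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """For each bout, the ``segment_id`` of the same-user truth segment
    with the largest time overlap (NaN if none overlaps)."""
    out = pd.Series(pd.NA, index=bouts.index, dtype=object)
    for uid, b in bouts.groupby("user_id"):
        tr = truth[truth["user_id"] == uid].sort_values("t_start")
        if len(tr) == 0:
            continue
        ts = tr["t_start"].to_numpy()
        te = tr["t_end"].to_numpy()
        ids = tr["segment_id"].to_numpy()
        for i, (b0, b1) in enumerate(zip(b["start_t"].to_numpy(),
                                         b["end_t"].to_numpy())):
            j = np.searchsorted(ts, b1, side="right") - 1
            best, best_ov = None, np.timedelta64(0, "ns")
            while j >= 0 and te[j] >= b0 - np.timedelta64(1, "h"):
                ov = min(b1, te[j]) - max(b0, ts[j])
                if ov >= best_ov and ov >= np.timedelta64(0, "ns"):
                    if best is None or ov > best_ov:
                        best, best_ov = ids[j], ov
                j -= 1
            out.iloc[out.index.get_loc(b.index[i])] = best
    return out


def detection_metrics(bouts: pd.DataFrame, truth: pd.DataFrame) -> Dict[str, float]:
    """Sensitivity/FDR of detected bouts against planted truth.

    sensitivity = planted walk segments overlapped by >=1 detected bout
    / planted walks; false_discovery_rate = detected bouts whose best
    match is not a planted walk / detected bouts; drives_detected =
    bouts whose best match is a planted drive.
    """
    walks = truth[truth["kind"].str.startswith("walk")]
    matched = match_bouts(bouts, truth)
    kind_of = truth.set_index("segment_id")["kind"]
    matched_kind = matched.map(lambda s: kind_of.get(s) if pd.notna(s) else None)
    is_walk = matched_kind.astype(str).str.startswith("walk").fillna(False) \
        if len(matched) else pd.Series(dtype=bool)
    recovered = matched[is_walk].dropna().unique() if len(matched) else []
    sens = len(set(recovered) & set(walks["segment_id"])) / max(1, len(walks))
    fdr = (1.0 - is_walk.mean()) if len(bouts) else 0.0
    drives = int((matched_kind == "drive").sum()) if len(matched) else 0
    return {"sensitivity": float(sens),
            "false_discovery_rate": float(fdr),
            "drives_detected": drives,
            "n_planted_walks": int(len(walks)),
            "n_detected_bouts": int(len(bouts))}


def classification_accuracy(labeled: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of detected bouts matched to a planted walk whose
    purpose label equals the planted purpose."""
    matched = match_bouts(labeled, truth)
    kind_of = truth.set_index("segment_id")["kind"]
    planted = matched.map(lambda s: kind_of.get(s) if pd.notna(s) else None)
    mask = planted.astype(str).str.startswith("walk")
    if mask.sum() == 0:
        return float("nan")
    expect = planted[mask].map({"walk_utilitarian": "utilitarian",
                                "walk_leisure": "leisure"})
    return float((labeled.loc[mask[mask].index, "purpose"] == expect).mean())
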
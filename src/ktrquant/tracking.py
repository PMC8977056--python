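"""Frame-to-frame centroid linking and complete-track filtering.

Objects in consecutive frames are linked when their centroid displacement
is at most 3 px (Euclidean), matched one-to-one greedily by ascending
distance; unmatched objects start new tracks. Only tracks present as a
single object in every frame are kept for trajectory analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def link_objects(features: pd.DataFrame, max_dist: float = 3.0) -> pd.DataFrame:
    """Assign a ``track_id`` column by greedy nearest-centroid linking.

    ``features`` needs columns frame, object_id, x, y (one compartment;
    typically nuclei). Within each consecutive frame pair, candidate links
    with distance <= max_dist are taken in ascending distance order, ties
    broken by lower object id, each object used at most once.
    """
    features = features.sort_values(["frame", "object_id"]).reset_index(drop=True)
    frames = sorted(features["frame"].unique())
    track_of: dict[tuple[int, int], int] = {}
    next_track = 0

    prev = features[features["frame"] == frames[0]]
    for oid in prev["object_id"]:
        track_of[(frames[0], oid)] = next_track
        next_track += 1

    for fprev, fcur in zip(frames[:-1], frames[1:]):
        cur = features[features["frame"] == fcur]
        pxy = prev[["x", "y"]].to_numpy()
        cxy = cur[["x", "y"]].to_numpy()
        pid = prev["object_id"].to_numpy()
        cid = cur["object_id"].to_numpy()
        if len(pid) and len(cid):
            d = np.sqrt(((cxy[:, None, :] - pxy[None, :, :]) ** 2).sum(-1))
            cand = [(d[i, j], int(cid[i]), int(pid[j]), i, j)
                    for i in range(len(cid)) for j in range(len(pid))
                    if d[i, j] <= max_dist]
            cand.sort(key=lambda c: (c[0], c[1], c[2]))
            used_cur: set[int] = set()
            used_prev: set[int] = set()
            for dist, c, p, i, j in cand:
                if i in used_cur or j in used_prev:
                    continue
                used_cur.add(i)
                used_prev.add(j)
                track_of[(fcur, c)] = track_of[(fprev, p)]
        for oid in cid:
            if (fcur, oid) not in track_of:
                track_of[(fcur, oid)] = next_track
                next_track += 1
        prev = cur

    out = features.copy()
    out["track_id"] = [track_of[(f, o)] for f, o in zip(out["frame"], out["object_id"])]
    return out


def filter_complete_tracks(tracked: pd.DataFrame, n_frames: int) -> pd.DataFrame:
    """Keep only tracks with exactly one object in every one of ``n_frames`` frames."""
    counts = tracked.groupby("track_id")["frame"].agg(["size", "nunique"])
    complete = counts[(counts["size"] == n_frames) & (counts["nunique"] == n_frames)].index
    return tracked[tracked["track_id"].isin(complete)].reset_index(drop=True)
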
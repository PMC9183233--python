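"""Nearest-neighbour nucleus tracking.

Detections are linked frame to frame by the nearest-centroid rule: each
detection at frame t is matched to the nearest detection in the previous
frame (falling back to frame t−2 only when t−1 offers no candidate within
the cap) provided the 3D Euclidean distance is strictly below the cap
(default 6 µm).  A detection with no candidate starts a new track; when two
or more detections claim the same previous-frame object, all claimants start
new tracks.  Lookback to t−2 only considers detections that are still the
tail of their track, so every detection belongs to exactly one track.

Within a frame detections are evaluated in ascending input order and exact
distance ties are broken toward the lower candidate index, making the result
deterministic for a given input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrackParams:
    max_link_dist: float = 6.0    # µm, strict upper bound
    lookback: int = 2             # frames

    def __post_init__(self) -> None:
        if self.max_link_dist <= 0:
            raise ValueError("max_link_dist must be positive")
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")


def link_tracks(detections: pd.DataFrame,
                params: TrackParams = TrackParams()) -> pd.DataFrame:
    """Link a detections table (frame, x_um, y_um, z_um[, label]) into tracks.

    Returns the input rows plus a ``track_id`` column; every row is assigned
    to exactly one track.
    """
    req = {"frame", "x_um", "y_um", "z_um"}
    if not req <= set(detections.columns):
        raise ValueError(f"detections must have columns {sorted(req)}")
    det = detections.reset_index(drop=True)
    if "label" in det.columns and det.duplicated(subset=["frame", "label"]).any():
        raise ValueError("duplicate (frame, label) detections")

    frames = np.sort(det.frame.unique())
    by_frame = {f: det.index[det.frame == f].to_numpy() for f in frames}
    xyz = det[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    track_of = np.full(len(det), -1, dtype=int)   # per detection
    tail = {}                                     # track_id -> detection idx
    next_track = 0

    def new_track(i):
        nonlocal next_track
        track_of[i] = next_track
        tail[next_track] = i
        next_track += 1

    prev: dict[int, np.ndarray] = {}
    for fi, f in enumerate(frames):
        idxs = by_frame[f]
        # candidate previous frames: consecutive frame indices only
        claims = {}   # detection idx at t -> claimed previous detection idx
        for i in idxs:
            cand = None
            for back in range(1, params.lookback + 1):
                pf = f - back
                pool = prev.get(pf)
                if pool is None or len(pool) == 0:
                    continue
                if back > 1:
                    # only detections still at the tail of their track
                    pool = np.array([j for j in pool
                                     if tail.get(track_of[j]) == j], dtype=int)
                    if len(pool) == 0:
                        continue
                d = np.linalg.norm(xyz[pool] - xyz[i], axis=1)
                k = int(np.argmin(d))
                if d[k] < params.max_link_dist:
                    cand = pool[k]
                    break
            if cand is None:
                new_track(i)
            else:
                claims[i] = cand
        # resolve conflicts: >=2 claimants on the same previous detection
        counts = {}
        for i, j in claims.items():
            counts[j] = counts.get(j, 0) + 1
        for i, j in claims.items():
            if counts[j] >= 2:
                new_track(i)
            else:
                tid = track_of[j]
                track_of[i] = tid
                tail[tid] = i
        prev[f] = idxs

    out = det.copy()
    out["track_id"] = track_of
    # sanity: cap respected within tracks on consecutive links
    _assert_cap(out, params)
    return out


def _assert_cap(tracks: pd.DataFrame, params: TrackParams) -> None:
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        p = g[["x_um", "y_um", "z_um"]].to_numpy()
        if len(p) > 1:
            d = np.linalg.norm(np.diff(p, axis=0), axis=1)
            gap = np.diff(g.frame.to_numpy())
            assert np.all(d[gap <= params.lookback] < params.max_link_dist)


def track_spans(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per track: first/last frame and number of detections."""
    g = tracks.groupby("track_id")
    return pd.DataFrame({
        "track_id": list(g.groups),
        "first_frame": g.frame.min().to_numpy(),
        "last_frame": g.frame.max().to_numpy(),
        "n_frames": g.frame.count().to_numpy(),
    })
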
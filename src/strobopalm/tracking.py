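"""Nearest-neighbour linking of localizations in adjacent frames into tracks.

Tracks are chains of localizations in strictly consecutive frames (no gap
closing by default: a missing frame terminates the track).  Linking frame
k -> k+1 is greedy nearest-neighbour within a maximum radius; when two
candidate pairs are equidistant the pair containing the lower row index wins,
which makes the result deterministic given input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .loc_data import AcquisitionSettings, LocalizationTable

__all__ = ["Track", "TrackSet", "link_tracks", "track_length_distribution"]

#: Default maximum displacement between consecutive frames, nm.  A bound
#: molecule localized with ~15 nm precision moves ~sigma*sqrt(2) ~ 21 nm
#: between frames; 300 nm leaves a wide margin while still separating poles.
DEFAULT_LINK_RADIUS_NM = 300.0


@dataclass
class Track:
    """One single-molecule track: row indices into the source table."""

    rows: np.ndarray     # indices into the table, ordered by frame
    frames: np.ndarray   # strictly consecutive frame indices

    @property
    def length_frames(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    """All tracks from one table; every localization belongs to exactly one track."""

    tracks: list[Track]
    max_link_distance_nm: float
    n_localizations: int
    acquisition: AcquisitionSettings | None = None

    def __len__(self) -> int:
        return len(self.tracks)

    def lengths(self) -> np.ndarray:
        return np.array([t.length_frames for t in self.tracks], dtype=np.int64)

    def track_ids(self) -> np.ndarray:
        """Per-localization track id (row-aligned with the source table)."""
        ids = np.full(self.n_localizations, -1, dtype=np.int64)
        for i, t in enumerate(self.tracks):
            ids[t.rows] = i
        return ids


def _greedy_pairs(
    prev_xy: np.ndarray, cur_xy: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Greedy distance-ordered matching between two frames.

    Pairs are accepted shortest-first; ties broken by (previous-row, current-row)
    index order.  Returns (index-into-prev, index-into-cur) pairs.
    """
    tree = cKDTree(cur_xy)
    cand: list[tuple[float, int, int]] = []
    for i, neighbours in enumerate(tree.query_ball_point(prev_xy, radius)):
        for j in neighbours:
            d = float(np.hypot(*(prev_xy[i] - cur_xy[j])))
            cand.append((d, i, j))
    cand.sort()
    used_prev: set[int] = set()
    used_cur: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_prev or j in used_cur:
            continue
        used_prev.add(i)
        used_cur.add(j)
        pairs.append((i, j))
    return pairs


def link_tracks(
    table: LocalizationTable,
    max_link_distance_nm: float = DEFAULT_LINK_RADIUS_NM,
    acquisition: AcquisitionSettings | None = None,
) -> TrackSet:
    """Link localizations in adjacent frames into tracks.

    Unmatched localizations start new tracks; an empty table yields an empty
    TrackSet.  Conservation holds: ``n_tracks + sum(length - 1) == n_rows``.
    """
    if max_link_distance_nm <= 0:
        raise ValueError("max_link_distance_nm must be > 0")
    n = len(table)
    if n == 0:
        return TrackSet([], max_link_distance_nm, 0, acquisition)

    frames = table.df["frame"].to_numpy()
    xy = table.positions()
    order = np.argsort(frames, kind="stable")

    # group row indices by frame, in frame order
    frame_values, starts = np.unique(frames[order], return_index=True)
    groups = {
        int(f): order[s:e]
        for f, s, e in zip(
            frame_values, starts, np.append(starts[1:], len(order))
        )
    }

    open_tracks: dict[int, list[int]] = {}   # row index of last loc -> chain
    finished: list[list[int]] = []
    prev_frame: int | None = None
    prev_rows: np.ndarray | None = None

    for f in frame_values:
        cur_rows = groups[int(f)]
        if prev_frame is not None and int(f) == prev_frame + 1 and prev_rows is not None:
            pairs = _greedy_pairs(xy[prev_rows], xy[cur_rows], max_link_distance_nm)
        else:
            pairs = []
        matched_cur = set()
        new_open: dict[int, list[int]] = {}
        for i, j in pairs:
            prev_row = int(prev_rows[i])
            cur_row = int(cur_rows[j])
            chain = open_tracks.pop(prev_row)
            chain.append(cur_row)
            new_open[cur_row] = chain
            matched_cur.add(cur_row)
        # tracks whose last loc found no continuation are finished
        finished.extend(open_tracks.values())
        open_tracks = new_open
        for r in cur_rows:
            if int(r) not in matched_cur:
                open_tracks[int(r)] = [int(r)]
        prev_frame = int(f)
        prev_rows = cur_rows
    finished.extend(open_tracks.values())

    tracks = [
        Track(rows=np.asarray(chain, dtype=np.int64), frames=frames[chain])
        for chain in finished
    ]
    tracks.sort(key=lambda t: (t.frames[0], t.rows[0]))
    return TrackSet(tracks, max_link_distance_nm, n, acquisition)


def track_length_distribution(tracks: TrackSet) -> dict[int, int]:
    """Histogram of track lengths (frames): {length: count}.

    Counts sum to the number of tracks; support is the positive integers.
    """
    if len(tracks) == 0:
        raise ValueError("empty TrackSet has no length distribution")
    lengths = tracks.lengths()
    vals, counts = np.unique(lengths, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}
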
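"""Linking droplet detections across hourly timepoints.

Immobilized droplets barely move between frames, so identity is carried by
proximity: consecutive frames are linked by greedy globally-nearest
matching under an allowed-movement gate.  If the gate were larger than the
droplet radius a different droplet could be picked up at the next frame, so
the default gate is half the nominal radius.  Droplets that make a large
jump ("movers") break their chain and are flagged for removal rather than
silently dropped, preserving an audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrackingConfig", "link_timepoints", "build_tracks"]

COMPLETE = "complete"
REMOVED_MOVER = "removed_mover"
REMOVED_GAP = "removed_gap"


@dataclass
class TrackingConfig:
    allowed_movement_px: float
    require_full_length: bool = True
    nominal_radius_px: float | None = None

    def __post_init__(self) -> None:
        if self.allowed_movement_px <= 0:
            raise ValueError("allowed_movement_px must be positive")
        if (
            self.nominal_radius_px is not None
            and self.allowed_movement_px >= self.nominal_radius_px
        ):
            warnings.warn(
                "allowed movement >= droplet radius: risk of linking a "
                "different droplet at the next timepoint",
                stacklevel=2,
            )


def link_timepoints(
    dets_t: pd.DataFrame, dets_t1: pd.DataFrame, m: float
) -> tuple[dict[int, int], set[int], set[int]]:
    """Match detections of consecutive frames by greedy nearest centers.

    Repeatedly pairs the globally closest (detection@t, detection@t+1)
    couple with center distance <= ``m`` and removes both; ties are broken
    by the lower ``droplet_index``.  Greedy-nearest coincides with the
    optimal assignment when inter-droplet spacing is large against the
    jitter, and never lets two droplets claim the same partner.

    Returns
    -------
    (mapping, unmatched_t, unmatched_t1)
        ``mapping`` maps droplet_index at t to droplet_index at t+1; the
        sets hold indices left unmatched on either side.
    """
    if m <= 0:
        raise ValueError("allowed movement must be positive")
    idx_t = dets_t["droplet_index"].to_numpy() if len(dets_t) else np.array([], int)
    idx_t1 = dets_t1["droplet_index"].to_numpy() if len(dets_t1) else np.array([], int)
    mapping: dict[int, int] = {}
    if len(idx_t) == 0 or len(idx_t1) == 0:
        return mapping, set(idx_t.tolist()), set(idx_t1.tolist())

    a = dets_t[["x", "y"]].to_numpy(float)
    b = dets_t1[["x", "y"]].to_numpy(float)
    dist = np.hypot(a[:, 0][:, None] - b[:, 0][None, :], a[:, 1][:, None] - b[:, 1][None, :])

    # candidate pairs within the gate, ordered by (distance, index, index)
    ii, jj = np.nonzero(dist <= m)
    order = np.lexsort((idx_t1[jj], idx_t[ii], dist[ii, jj]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_i or j in used_j:
            continue
        mapping[int(idx_t[i])] = int(idx_t1[j])
        used_i.add(i)
        used_j.add(j)
    unmatched_t = {int(idx_t[i]) for i in range(len(idx_t)) if i not in used_i}
    unmatched_t1 = {int(idx_t1[j]) for j in range(len(idx_t1)) if j not in used_j}
    return mapping, unmatched_t, unmatched_t1


def build_tracks(
    detections: pd.DataFrame, config: TrackingConfig, n_timepoints: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chain pairwise links over all timepoints of one tile.

    Parameters
    ----------
    detections : pandas.DataFrame
        Per-timepoint detections with columns ``timepoint, droplet_index,
        x, y, radius`` (``hough_score`` optional), one tile.
    config : TrackingConfig
    n_timepoints : int, optional
        Length of the experiment; defaults to the largest timepoint seen
        plus one.  Pass it explicitly when trailing frames may hold no
        detections at all.

    Returns
    -------
    (tracks, members)
        ``tracks`` has one row per track: ``track_id, status, max_step,
        t_start, t_end, n_timepoints``.  ``members`` has one row per
        (track, timepoint) with the matched detection's coordinates.

    A chain that spans every timepoint is ``complete`` (its max step is
    <= the gate by construction).  A broken chain is ``removed_mover``
    when detections were present at the frame where it broke (the droplet
    jumped out of the gate) and ``removed_gap`` when that frame held no
    detections at all (a missed frame).  Only complete tracks should enter
    downstream analysis.
    """
    timepoints = sorted(detections["timepoint"].unique()) if len(detections) else []
    if n_timepoints is None:
        n_timepoints = (int(max(timepoints)) + 1) if timepoints else 0
    if len(detections) and n_timepoints < 2:
        raise ValueError("tracking needs at least 2 timepoints")
    n_t = n_timepoints
    by_t = {
        t: detections[detections["timepoint"] == t].reset_index(drop=True)
        for t in range(n_t)
    }
    frame_counts = {t: len(by_t.get(t, ())) for t in range(n_t)}

    # chains keyed by (timepoint, droplet_index) of their current tail
    chains: dict[tuple[int, int], list[tuple[int, int]]] = {
        (0, int(i)): [(0, int(i))] for i in by_t.get(0, pd.DataFrame({"droplet_index": []}))["droplet_index"]
    }
    finished: list[list[tuple[int, int]]] = []
    for t in range(n_t - 1):
        mapping, unmatched_t, unmatched_t1 = link_timepoints(
            by_t[t], by_t[t + 1], config.allowed_movement_px
        )
        new_chains: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for (tt, di), chain in chains.items():
            if tt != t:  # already finished earlier
                finished.append(chain)
                continue
            if di in mapping:
                nj = mapping[di]
                chain = chain + [(t + 1, nj)]
                new_chains[(t + 1, nj)] = chain
            else:
                finished.append(chain)
        for j in unmatched_t1:  # droplet appearing mid-experiment
            new_chains[(t + 1, int(j))] = [(t + 1, int(j))]
        chains = new_chains
    finished.extend(chains.values())

    det_lookup = {
        (int(r.timepoint), int(r.droplet_index)): r for r in detections.itertuples()
    }
    track_rows = []
    member_rows = []
    for track_id, chain in enumerate(sorted(finished, key=lambda c: (c[0][0], c[0][1]))):
        pts = np.array(
            [[det_lookup[key].x, det_lookup[key].y] for key in chain], float
        )
        steps = np.hypot(*np.diff(pts, axis=0).T) if len(pts) > 1 else np.array([0.0])
        max_step = float(steps.max()) if steps.size else 0.0
        t_start, t_end = chain[0][0], chain[-1][0]
        full = t_start == 0 and t_end == n_t - 1
        if full or not config.require_full_length:
            status = COMPLETE
        else:
            # which frame broke the chain?
            break_frames = []
            if t_start > 0:
                break_frames.append(t_start - 1)
            if t_end < n_t - 1:
                break_frames.append(t_end + 1)
            if any(frame_counts.get(bf, 0) > 0 for bf in break_frames):
                status = REMOVED_MOVER
            else:
                status = REMOVED_GAP
        track_rows.append((track_id, status, max_step, t_start, t_end, len(chain)))
        for t, di in chain:
            det = det_lookup[(t, di)]
            member_rows.append((track_id, t, di, det.x, det.y, det.radius))

    tracks = pd.DataFrame(
        track_rows,
        columns=["track_id", "status", "max_step", "t_start", "t_end", "n_timepoints"],
    )
    members = pd.DataFrame(
        member_rows, columns=["track_id", "timepoint", "droplet_index", "x", "y", "radius"]
    )
    return tracks, members
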
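"""Death-time calling and killing-kinetics analytics.

A cell's viability-channel trace is background-corrected so that "alive"
reads as (approximately) zero; the death time is the first timepoint the
corrected intensity rises above a threshold and stays there.  The analysis
strata follow the assay design: E:T 1:1 droplets with all cells alive at
t = 0 carry the cytotoxicity readout (killer fraction, per-hour lytic-hit
histogram, fast/slow killer split at 4 h); droplets with a single effector
and several targets reveal serial killers; effector-free droplets are the
spontaneous-death control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticsSummary",
    "call_death_time",
    "select_eligible",
    "killer_fraction",
    "kinetics_histogram",
    "detect_serial_killers",
    "control_viability",
]

EVENT_COLUMNS = ["track_id", "cell_type", "death_time"]


def call_death_time(
    trace: np.ndarray, theta: float, persistence: int = 1
) -> int | None:
    """First timepoint a corrected viability trace exceeds ``theta`` and
    stays above it for ``persistence`` consecutive frames (truncated at the
    series end); ``None`` if it never does."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    above = np.asarray(trace, float) > theta
    n = len(above)
    for t in range(n):
        run = above[t : min(t + persistence, n)]
        if run.all():
            return t
    return None


def select_eligible(census_per_track: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split complete 1:1 tracks into the eligible set and logged exclusions.

    Eligibility for the cytotoxicity readout: occupancy exactly 1:1 and no
    dead cell at t = 0.  ``census_per_track`` needs columns ``track_id,
    k_effector, k_target, dead_at_t0`` (count of viability objects at the
    first timepoint).

    Returns ``(eligible, exclusions)``; exclusions carry a ``reason``
    column (``not_1_1`` | ``dead_at_t0``) and eligible + excluded account
    for every input row exactly.
    """
    df = census_per_track
    is_pair = (df["k_effector"] == 1) & (df["k_target"] == 1)
    dead0 = df["dead_at_t0"] > 0
    eligible = df[is_pair & ~dead0].reset_index(drop=True)
    excl = df[~(is_pair & ~dead0)].copy()
    excl["reason"] = np.where(~is_pair[~(is_pair & ~dead0)], "not_1_1", "dead_at_t0")
    return eligible, excl.reset_index(drop=True)


def killer_fraction(
    eligible: pd.DataFrame, events: pd.DataFrame
) -> tuple[float, int, int]:
    """Fraction of eligible 1:1 droplets whose target died in the window.

    Effector deaths are not counted; the killer fraction concerns target
    death only.  Returns ``(fraction, n_kills, n_eligible)``.
    """
    if len(eligible) == 0:
        raise ValueError("eligible set is empty")
    kills = events[
        (events["cell_type"] == "target")
        & events["track_id"].isin(eligible["track_id"])
    ]["track_id"].nunique()
    return kills / len(eligible), int(kills), int(len(eligible))


@dataclass
class KineticsSummary:
    n_droplets_total: int = 0
    n_droplets_with_cells: int = 0
    n_pairs_1_1: int = 0
    n_eligible: int = 0
    killer_fraction: float | None = None
    n_kills: int = 0
    histogram: list[int] = field(default_factory=list)
    T_fast: int = 4
    fast_killer_fraction: float | None = None
    slow_killer_fraction: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_droplets_total": self.n_droplets_total,
            "n_droplets_with_cells": self.n_droplets_with_cells,
            "n_pairs_1_1": self.n_pairs_1_1,
            "n_eligible": self.n_eligible,
            "killer_fraction": self.killer_fraction,
            "n_kills": self.n_kills,
            "histogram": list(map(int, self.histogram)),
            "T_fast": self.T_fast,
            "fast_killer_fraction": self.fast_killer_fraction,
            "slow_killer_fraction": self.slow_killer_fraction,
        }


def kinetics_histogram(
    events: pd.DataFrame, n_timepoints: int, t_fast: int = 4
) -> tuple[np.ndarray, float | None, float | None]:
    """Per-hour lytic-hit histogram and the fast/slow killer split.

    ``events`` are target-death events from eligible 1:1 droplets.  Fast
    killers delivered their hit at or before ``t_fast`` hours.  With zero
    events the histogram is all zeros and the fractions are ``None``
    (undefined, not 0).
    """
    hist = np.zeros(n_timepoints, int)
    times = events["death_time"].to_numpy(int) if len(events) else np.array([], int)
    for t in times:
        hist[t] += 1
    if len(times) == 0:
        return hist, None, None
    fast = float((times <= t_fast).sum() / len(times))
    return hist, fast, 1.0 - fast


def detect_serial_killers(
    census_per_track: pd.DataFrame, events: pd.DataFrame
) -> pd.DataFrame:
    """Droplets where one effector killed at least two targets.

    Qualifying droplets hold exactly 1 effector and >= 2 targets with >= 2
    target-death events.  Returns ``track_id, k_target, n_kills,
    kill_times`` (sorted hour list).
    """
    cand = census_per_track[
        (census_per_track["k_effector"] == 1) & (census_per_track["k_target"] >= 2)
    ]
    rows = []
    tgt_events = events[events["cell_type"] == "target"]
    for row in cand.itertuples():
        times = sorted(
            tgt_events.loc[tgt_events["track_id"] == row.track_id, "death_time"].tolist()
        )
        if len(times) >= 2:
            rows.append((row.track_id, int(row.k_target), len(times), times))
    return pd.DataFrame(rows, columns=["track_id", "k_target", "n_kills", "kill_times"])


def control_viability(
    target_only: pd.DataFrame, events: pd.DataFrame, n_timepoints: int
) -> np.ndarray | None:
    """Cumulative spontaneous target-death fraction in effector-free droplets.

    The denominator is the number of target cells alive at t = 0 in the
    target-only stratum; deaths already present at t = 0 are excluded from
    both sides.  Returns one fraction per timepoint, or ``None`` when the
    stratum is empty.
    """
    if len(target_only) == 0:
        return None
    ev = events[
        events["track_id"].isin(target_only["track_id"])
        & (events["cell_type"] == "target")
    ]
    n_dead_t0 = int((ev["death_time"] == 0).sum())
    denom = int(target_only["k_target"].sum()) - n_dead_t0
    if denom <= 0:
        return None
    curve = np.zeros(n_timepoints)
    late = ev[ev["death_time"] >= 1]
    for t in range(n_timepoints):
        curve[t] = (late["death_time"] <= t).sum() / denom
    return curve
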
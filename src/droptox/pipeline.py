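"""End-to-end pipeline driver and the script-vs-truth validation harness.

``run_pipeline`` executes detect -> track -> census -> kinetics per tile
and concatenates the outputs; ``validate_against_truth`` reproduces the
script-vs-manual comparison (droplet count, occupancy-class distribution,
1:1 pairing count, dead-cell count at chosen timepoints) with the
generator's ground truth standing in for manual counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cells as _cells
from . import detect as _detect
from . import kinetics as _kin
from . import track as _track
from .io import ExperimentStack, read_experiment, write_json, write_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_against_truth"]

logger = logging.getLogger(__name__)

FLUOR_FOR_TYPE = {"effector": "effector_tracker", "target": "target_tracker"}


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults follow the 50 µm droplet / 10 µm cell
    geometry at 1 µm per pixel."""

    nominal_radius_px: float = 25.0
    radius_factor_low: float = 0.8
    radius_factor_high: float = 1.2
    sensitivity: float = 0.35
    canny_sigma: float = 2.0
    allowed_movement_px: float | None = None  # default: half the nominal radius
    cell: _cells.CellDetectionConfig = field(default_factory=_cells.CellDetectionConfig)
    #: corrected-intensity threshold for death calling
    theta: float = 150.0
    persistence: int = 1
    t_fast: int = 4
    validation_timepoints: tuple[int, ...] = (3, 4, 10)

    def __post_init__(self) -> None:
        if self.allowed_movement_px is None:
            self.allowed_movement_px = 0.5 * self.nominal_radius_px

    @property
    def radius_range(self) -> tuple[float, float]:
        return (
            self.radius_factor_low * self.nominal_radius_px,
            self.radius_factor_high * self.nominal_radius_px,
        )


@dataclass
class PipelineResult:
    droplets: pd.DataFrame       # all detections
    tracks: pd.DataFrame         # per-track status
    members: pd.DataFrame        # per (track, timepoint) matched detection
    census: pd.DataFrame         # per (track, timepoint) counts
    census_per_track: pd.DataFrame
    traces: pd.DataFrame         # long: track_id, cell_type, timepoint, intensity
    events: pd.DataFrame         # track_id, cell_type, death_time
    eligible: pd.DataFrame
    exclusions: pd.DataFrame
    summary: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        write_table(self.droplets, out_dir / "droplets.csv")
        tracks = self.tracks.merge(
            self.members.pivot(index="track_id", columns="timepoint", values=["x", "y"]).pipe(
                lambda d: d.set_axis([f"{a}_t{t}" for a, t in d.columns], axis=1)
            ),
            on="track_id",
            how="left",
        )
        write_table(tracks, out_dir / "tracks.csv")
        write_table(self.census, out_dir / "census.csv")
        write_table(self.events, out_dir / "events.csv")
        write_json(self.summary, out_dir / "summary.json")


def _measure_track(
    stack: ExperimentStack,
    tile_id: int,
    track_members: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[list[dict], list[dict]]:
    """Per-timepoint channel measurements for one complete track.

    Returns census rows and trace rows.  The viability background is the
    median in-disk viability intensity at t = 0 (the droplet's own blank),
    so an alive cell reads ~0 after correction.
    """
    cc = cfg.cell
    rows = track_members.sort_values("timepoint")
    track_id = int(rows["track_id"].iloc[0])
    objs_by_t: dict[int, dict[str, pd.DataFrame]] = {}
    background0 = 0.0
    for r in rows.itertuples():
        t = int(r.timepoint)
        center, radius = (r.x, r.y), float(r.radius)
        per_channel: dict[str, pd.DataFrame] = {}
        for channel in ("effector_tracker", "target_tracker", "viability"):
            img = stack.get(tile_id, t, channel)
            binary, filtered, origin = _cells.preprocess_channel(img, center, radius, cc)
            raw_crop = img[
                origin[1] : origin[1] + binary.shape[0],
                origin[0] : origin[0] + binary.shape[1],
            ].astype(float)
            _, objects = _cells.count_cells(
                binary,
                cc.min_area_px,
                cc.max_area_px,
                intensity=raw_crop,
                origin=origin,
                split_min_distance=int(round(cc.cell_diameter_px / 2)),
            )
            per_channel[channel] = objects
            if channel == "viability" and t == 0:
                h, w = img.shape
                yy, xx = np.mgrid[
                    max(0, int(r.y - radius)) : min(h, int(r.y + radius) + 1),
                    max(0, int(r.x - radius)) : min(w, int(r.x + radius) + 1),
                ]
                disk = (xx - r.x) ** 2 + (yy - r.y) ** 2 <= radius**2
                background0 = float(
                    np.median(img[yy[disk], xx[disk]]) if disk.any() else 0.0
                )
        objs_by_t[t] = per_channel

    t0 = int(rows["timepoint"].min())
    census_rows: list[dict] = []
    trace_vals: dict[str, dict[int, float]] = {"effector": {}, "target": {}}
    n_e0 = len(objs_by_t[t0]["effector_tracker"])
    n_t0 = len(objs_by_t[t0]["target_tracker"])
    base = _cells.census_droplet(track_id, n_e0, n_t0)
    for t, per_channel in sorted(objs_by_t.items()):
        attributed = _cells.attribute_dead_cells(
            per_channel["viability"],
            per_channel["effector_tracker"],
            per_channel["target_tracker"],
            cc.cell_diameter_px,
            effector_objects_t0=objs_by_t[t0]["effector_tracker"],
            target_objects_t0=objs_by_t[t0]["target_tracker"],
        )
        counts = attributed["attributed_type"].value_counts() if len(attributed) else {}
        census_rows.append(
            {
                "track_id": track_id,
                "timepoint": t,
                "n_effector": len(per_channel["effector_tracker"]),
                "n_target": len(per_channel["target_tracker"]),
                "n_viability": len(attributed),
                "dead_effector": int(counts.get("effector", 0)),
                "dead_target": int(counts.get("target", 0)),
                "dead_unknown": int(counts.get("unknown", 0)),
                "occupancy": base["occupancy"],
            }
        )
        for ctype in ("effector", "target"):
            sub = attributed[attributed["attributed_type"] == ctype] if len(attributed) else attributed
            val = float(sub["mean_intensity"].max()) if len(sub) else 0.0
            trace_vals[ctype][t] = max(val - background0, 0.0) if len(sub) else 0.0

    trace_rows = [
        {"track_id": track_id, "cell_type": ctype, "timepoint": t, "intensity": v}
        for ctype, d in trace_vals.items()
        for t, v in sorted(d.items())
    ]
    return census_rows, trace_rows


def run_pipeline(
    stack: ExperimentStack | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run detect -> track -> census -> kinetics on a whole experiment.

    Tiles are processed independently; only complete tracks (no gaps, no
    mover jumps) enter the census and kinetics.  Deterministic for a fixed
    input.
    """
    if not isinstance(stack, ExperimentStack):
        stack = read_experiment(stack)
    cfg = config or PipelineConfig()
    n_t = stack.n_timepoints

    all_dets, all_tracks, all_members = [], [], []
    census_rows: list[dict] = []
    trace_rows: list[dict] = []
    track_offset = 0
    tcfg = _track.TrackingConfig(
        allowed_movement_px=cfg.allowed_movement_px,
        nominal_radius_px=cfg.nominal_radius_px,
    )
    for tile_id in stack.tile_ids:
        dets_t = []
        for t in range(n_t):
            d = _detect.find_droplets(
                stack.get(tile_id, t, "brightfield"),
                cfg.radius_range,
                sensitivity=cfg.sensitivity,
                canny_sigma=cfg.canny_sigma,
            )
            d.insert(0, "timepoint", t)
            dets_t.append(d)
        dets = pd.concat(dets_t, ignore_index=True)
        dets.insert(0, "tile_id", tile_id)
        all_dets.append(dets)

        tracks, members = _track.build_tracks(dets, tcfg, n_timepoints=n_t)
        tracks["track_id"] += track_offset
        members["track_id"] += track_offset
        tracks.insert(1, "tile_id", tile_id)
        track_offset += len(tracks) or 0
        all_tracks.append(tracks)
        all_members.append(members)

        complete_ids = tracks.loc[tracks["status"] == _track.COMPLETE, "track_id"]
        logger.info(
            "tile %d: %d detections, %d tracks (%d complete)",
            tile_id, len(dets), len(tracks), len(complete_ids),
        )
        for track_id in complete_ids:
            tm = members[members["track_id"] == track_id]
            c_rows, t_rows = _measure_track(stack, tile_id, tm, cfg)
            census_rows.extend(c_rows)
            trace_rows.extend(t_rows)

    droplets = pd.concat(all_dets, ignore_index=True) if all_dets else pd.DataFrame()
    tracks = pd.concat(all_tracks, ignore_index=True) if all_tracks else pd.DataFrame()
    members = pd.concat(all_members, ignore_index=True) if all_members else pd.DataFrame()
    census = pd.DataFrame(census_rows)
    traces = pd.DataFrame(trace_rows)

    # per-track census + death events from cumulative dead-count increments
    per_track_rows, event_rows = [], []
    if len(census):
        for track_id, g in census.groupby("track_id"):
            g = g.sort_values("timepoint")
            first = g.iloc[0]
            k_e, k_t = int(first["n_effector"]), int(first["n_target"])
            rec = _cells.census_droplet(int(track_id), k_e, k_t)
            rec["dead_at_t0"] = int(first["n_viability"])
            per_track_rows.append(rec)
            for col, ctype in (
                ("dead_effector", "effector"),
                ("dead_target", "target"),
                ("dead_unknown", "unknown"),
            ):
                series = g[col].cummax().to_numpy()  # dead cells stay dead
                prev = 0
                for t, v in zip(g["timepoint"], series):
                    for _ in range(int(v) - prev):
                        event_rows.append(
                            {"track_id": int(track_id), "cell_type": ctype, "death_time": int(t)}
                        )
                    prev = max(prev, int(v))
    census_per_track = pd.DataFrame(
        per_track_rows,
        columns=["track_id", "k_effector", "k_target", "occupancy", "pair_1_1",
                 "effector_only", "target_only", "multi", "dead_at_t0"],
    )
    events = pd.DataFrame(event_rows, columns=_kin.EVENT_COLUMNS)

    # kinetics on the eligible 1:1 stratum, death times from the traces
    if len(census_per_track):
        eligible, exclusions = _kin.select_eligible(census_per_track)
    else:
        eligible = census_per_track.copy()
        exclusions = census_per_track.copy()
    kill_events = []
    for row in eligible.itertuples():
        tr = traces[
            (traces["track_id"] == row.track_id) & (traces["cell_type"] == "target")
        ].sort_values("timepoint")["intensity"].to_numpy()
        dt = _kin.call_death_time(tr, cfg.theta, cfg.persistence)
        if dt is not None:
            kill_events.append(
                {"track_id": row.track_id, "cell_type": "target", "death_time": dt}
            )
    kill_events = pd.DataFrame(kill_events, columns=_kin.EVENT_COLUMNS)

    summary = _kin.KineticsSummary(
        n_droplets_total=int((tracks["status"] == _track.COMPLETE).sum()) if len(tracks) else 0,
        n_droplets_with_cells=int(
            ((census_per_track["k_effector"] + census_per_track["k_target"]) > 0).sum()
        ) if len(census_per_track) else 0,
        n_pairs_1_1=int(census_per_track["pair_1_1"].sum()) if len(census_per_track) else 0,
        n_eligible=len(eligible),
        T_fast=cfg.t_fast,
    )
    if len(eligible):
        frac, n_kills, _ = _kin.killer_fraction(eligible, kill_events)
        hist, fast, slow = _kin.kinetics_histogram(kill_events, n_t, cfg.t_fast)
        summary.killer_fraction = frac
        summary.n_kills = n_kills
        summary.histogram = hist.tolist()
        summary.fast_killer_fraction = fast
        summary.slow_killer_fraction = slow
    summary_dict = summary.as_dict()
    if len(census_per_track):
        curve = _kin.control_viability(
            census_per_track[census_per_track["target_only"]], events, n_t
        )
        summary_dict["control_viability"] = None if curve is None else curve.tolist()
        serial = _kin.detect_serial_killers(census_per_track, events)
        summary_dict["n_serial_killers"] = int(len(serial))
    else:
        summary_dict["control_viability"] = None
        summary_dict["n_serial_killers"] = 0
    summary_dict["exclusions"] = (
        exclusions["reason"].value_counts().to_dict() if len(exclusions) else {}
    )
    if len(tracks):
        summary_dict["tracks_by_status"] = tracks["status"].value_counts().to_dict()
    else:
        summary_dict["tracks_by_status"] = {}
    summary_dict["n"] = {"tiles": len(stack.tile_ids), "timepoints": n_t}

    result = PipelineResult(
        droplets=droplets,
        tracks=tracks,
        members=members,
        census=census,
        census_per_track=census_per_track,
        traces=traces,
        events=events,
        eligible=eligible,
        exclusions=exclusions,
        summary=summary_dict,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def match_tracks_to_truth(result: PipelineResult, truth) -> pd.DataFrame:
    """Pair each complete track with the ground-truth droplet nearest its
    t = 0 center (within one nominal radius).

    Returns columns ``track_id, droplet_id, distance``; tracks with no
    truth droplet within range are omitted.
    """
    from scipy.spatial import cKDTree

    t0_all = truth.droplets_at(0)
    complete = result.tracks.loc[
        result.tracks["status"] == "complete", ["track_id", "tile_id"]
    ]
    m0 = result.members[result.members["timepoint"] == 0].merge(complete, on="track_id")
    frames = []
    for tile_id, grp in m0.groupby("tile_id"):
        t0 = t0_all[t0_all["tile_id"] == tile_id]
        if len(grp) == 0 or len(t0) == 0:
            continue
        tree = cKDTree(t0[["x", "y"]].to_numpy())
        dist, idx = tree.query(grp[["x", "y"]].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "track_id": grp["track_id"].to_numpy(),
                    "droplet_id": t0["droplet_id"].to_numpy()[idx],
                    "distance": dist,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["track_id", "droplet_id", "distance"])
    out = pd.concat(frames, ignore_index=True)
    r = float(t0_all["radius"].median())
    return out[out["distance"] <= r].reset_index(drop=True)


# ---------------------------------------------------------------------------
# validation harness
# ---------------------------------------------------------------------------

def _pct_dev(obs: float, truth: float) -> float:
    return 100.0 * abs(obs - truth) / max(truth, 1.0)


def validate_against_truth(
    result: PipelineResult,
    truth,
    timepoints: tuple[int, ...] = (3, 4, 10),
) -> dict:
    """Compare pipeline outputs with generator ground truth.

    Metrics, mover droplets excluded from the truth side (the pipeline
    removes them by design):

    - droplet count (complete tracks vs true droplets),
    - droplets per occupancy class (census t = 0 vs true loading),
    - 1:1 pairing count,
    - cumulative dead-cell count at each requested timepoint.

    Each metric's percent deviation is ``100 |obs - truth| / max(truth, 1)``;
    the report carries every per-metric value and the overall maximum.
    """
    truth_occ = truth.occupancy(include_movers=False)
    n_truth = len(truth_occ)
    n_obs = int((result.tracks["status"] == "complete").sum()) if len(result.tracks) else 0

    report: dict = {"timepoints": list(timepoints), "metrics": {}}
    devs = [("droplet_count", _pct_dev(n_obs, n_truth))]
    report["metrics"]["droplet_count"] = {
        "observed": n_obs, "truth": n_truth, "deviation_pct": devs[-1][1]
    }

    # cell distribution: per-class droplet fractions, compared in
    # percentage points (class fractions are what the assay reports)
    truth_classes = truth_occ.groupby(["k_effector", "k_target"]).size()
    if len(result.census_per_track):
        obs_classes = result.census_per_track.groupby(["k_effector", "k_target"]).size()
    else:
        obs_classes = pd.Series(dtype=int)
    n_obs_tracks = max(int(obs_classes.sum()), 1)
    class_report = {}
    for key in sorted(set(truth_classes.index) | set(obs_classes.index)):
        o, tr = int(obs_classes.get(key, 0)), int(truth_classes.get(key, 0))
        d = _pct_dev(o / n_obs_tracks, tr / max(n_truth, 1))
        class_report[f"{key[0]}:{key[1]}"] = {
            "observed": o, "truth": tr, "deviation_pct": d
        }
        devs.append((f"occupancy_{key[0]}:{key[1]}", d))
    report["metrics"]["occupancy_classes"] = class_report

    truth_pairs = int(((truth_occ["k_effector"] == 1) & (truth_occ["k_target"] == 1)).sum())
    obs_pairs = int(result.census_per_track["pair_1_1"].sum()) if len(result.census_per_track) else 0
    devs.append(("pairing_1_1", _pct_dev(obs_pairs, truth_pairs)))
    report["metrics"]["pairing_1_1"] = {
        "observed": obs_pairs, "truth": truth_pairs, "deviation_pct": devs[-1][1]
    }

    nonmover_ids = set(truth_occ["droplet_id"])
    truth_cells = truth.cells[truth.cells["droplet_id"].isin(nonmover_ids)]
    dead_report = {}
    for t in timepoints:
        truth_dead = int((truth_cells["death_time"] <= t).sum())
        if len(result.census):
            at_t = result.census[result.census["timepoint"] == t]
            obs_dead = int(
                (at_t["dead_effector"] + at_t["dead_target"] + at_t["dead_unknown"]).sum()
            )
        else:
            obs_dead = 0
        d = _pct_dev(obs_dead, truth_dead)
        dead_report[str(t)] = {"observed": obs_dead, "truth": truth_dead, "deviation_pct": d}
        devs.append((f"dead_cells_t{t}", d))
    report["metrics"]["dead_cells"] = dead_report

    worst = max(devs, key=lambda kv: kv[1])
    report["max_deviation_pct"] = worst[1]
    report["max_deviation_metric"] = worst[0]
    return report
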
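"""Ground-truthed synthetic droplet time-lapse generator.

Emulates the imaging side of a droplet cytotoxicity experiment: immobilized
~50 µm water-in-oil droplets hex-packed in tiled fields, two-species Poisson
cell loading, hourly frames over 10 h, and four channels per frame —
brightfield (dark droplet rims on a light background), a stable target
tracker, an exponentially decaying effector tracker, and a viability dye
that switches from background to bright at a cell's death time and stays on.

Droplets receive small per-frame jitter; a configurable fraction of
"movers" make one large jump (greater than any sensible tracking gate) at a
random frame, planting removal cases for the tracker.  Every droplet and
cell is recorded in ground-truth tables that downstream tests use as the
oracle.

Cells are rendered as 2-D Gaussian spots (full width at half maximum equal
to the cell diameter) and droplet rims as Gaussian-profile annuli — the
minimum structure the detection and segmentation pipeline needs, with no
claim of point-spread-function realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .encapsulation import EncapsulationParams
from .io import CHANNELS, ExperimentStack

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_death_time_dist",
    "sample_fates",
    "generate_experiment",
]

EFFECTOR = "effector"
TARGET = "target"

_DROPLET_COLUMNS = ["tile_id", "droplet_id", "timepoint", "x", "y", "radius", "is_mover"]
_CELL_COLUMNS = [
    "cell_id",
    "droplet_id",
    "tile_id",
    "cell_type",
    "offset_x",
    "offset_y",
    "death_time",
]


def default_death_time_dist(n_timepoints: int = 11) -> np.ndarray:
    """Default lytic-hit time distribution (probability per hour index).

    Shaped after typical NK-cell killing kinetics: ~86% of lethal hits land
    within 4 h of contact ("fast killers"), and about half of those within
    the first hour; the remaining mass is spread over the later hours.
    Index 0 carries no mass — deaths already present at t = 0 are handled
    separately (and excluded from kinetics downstream).
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    p = np.zeros(11)
    p[1] = 0.86 * 0.52
    p[2] = 0.25
    p[3] = p[4] = (0.86 - p[1] - p[2]) / 2.0
    p[5:11] = (1.0 - 0.86) / 6.0
    p = p[:n_timepoints]
    return p / p.sum()


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment.

    Defaults reproduce the platform's standard conditions at desk scale:
    7e6/10e6 cells per mL co-flowed 1:1 into 70 pL (~50 µm) droplets, 15
    tiles of 512 px (~1,000 droplets total), hourly frames for 10 h
    (11 timepoints).
    """

    tile_shape: tuple[int, int] = (512, 512)
    n_tiles: int = 15
    pixel_size_um: float = 1.0
    droplet_diameter_mean_um: float = 50.0
    droplet_diameter_sd_um: float = 2.0
    cell_diameter_um: float = 10.0
    encapsulation: EncapsulationParams = field(default_factory=EncapsulationParams)
    n_timepoints: int = 11
    # motion
    jitter_sd_px: float = 0.8
    mover_fraction: float = 0.02
    # fates
    killer_prob: float = 0.2
    death_time_dist: np.ndarray | None = None  # default: default_death_time_dist
    dead_at_t0_prob: float = 0.02
    spontaneous_target_rate: float = 0.05  # effector-free droplets, whole window
    # optics
    brightfield_level: float = 3000.0
    ring_depth: float = 2000.0
    ring_sigma_px: float = 1.3
    fluor_background: float = 100.0
    target_amplitude: float = 3000.0
    effector_amplitude: float = 3000.0
    effector_half_life_h: float = 10.0
    viability_amplitude: float = 3000.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not self.droplet_diameter_mean_um > self.cell_diameter_um > 0:
            raise ValueError("need droplet_diameter_mean > cell_diameter > 0")
        if not 0 <= self.killer_prob <= 1:
            raise ValueError("killer_prob must be in [0, 1]")
        if not 0 <= self.mover_fraction <= 1:
            raise ValueError("mover_fraction must be in [0, 1]")
        if self.death_time_dist is None:
            self.death_time_dist = default_death_time_dist(self.n_timepoints)
        else:
            self.death_time_dist = np.asarray(self.death_time_dist, dtype=float)
            if len(self.death_time_dist) > self.n_timepoints:
                raise ValueError("death_time_dist support exceeds n_timepoints")

    # -- derived pixel geometry ------------------------------------------
    @property
    def droplet_radius_px(self) -> float:
        return 0.5 * self.droplet_diameter_mean_um / self.pixel_size_um

    @property
    def droplet_radius_sd_px(self) -> float:
        return 0.5 * self.droplet_diameter_sd_um / self.pixel_size_um

    @property
    def cell_radius_px(self) -> float:
        return 0.5 * self.cell_diameter_um / self.pixel_size_um

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["encapsulation"] = {
            k: d["encapsulation"][k]
            for k in ("conc_effector", "conc_target", "droplet_volume_pl", "dilution_factor")
        }
        d["death_time_dist"] = [float(x) for x in self.death_time_dist]
        d["tile_shape"] = list(self.tile_shape)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "encapsulation" in d:
            d["encapsulation"] = EncapsulationParams(**d["encapsulation"])
        if "tile_shape" in d:
            d["tile_shape"] = tuple(d["tile_shape"])
        if d.get("death_time_dist") is not None:
            d["death_time_dist"] = np.asarray(d["death_time_dist"], float)
        return cls(**d)


@dataclass
class GroundTruth:
    """The generator's per-droplet / per-cell record, used as test oracle.

    ``droplets`` is long-form: one row per (droplet, timepoint) with the
    droplet center, radius and mover flag.  ``cells`` has one row per cell
    with its type, rigid offset from the droplet center and death time
    (NaN when the cell never dies).  A cell's position at time t is the
    droplet center at t plus its offset.
    """

    droplets: pd.DataFrame
    cells: pd.DataFrame
    config: GeneratorConfig

    @property
    def n_droplets(self) -> int:
        return self.droplets["droplet_id"].nunique()

    def droplets_at(self, timepoint: int) -> pd.DataFrame:
        return self.droplets[self.droplets["timepoint"] == timepoint].reset_index(drop=True)

    def occupancy(self, include_movers: bool = True) -> pd.DataFrame:
        """Per-droplet (k_effector, k_target) occupancy table."""
        d0 = self.droplets_at(0)[["droplet_id", "tile_id", "is_mover"]]
        if not include_movers:
            d0 = d0[~d0["is_mover"]]
        counts = (
            self.cells.pivot_table(
                index="droplet_id", columns="cell_type", values="cell_id", aggfunc="count"
            )
            .reindex(columns=[EFFECTOR, TARGET], fill_value=0)
            .fillna(0)
            .astype(int)
        )
        out = d0.merge(counts, left_on="droplet_id", right_index=True, how="left")
        out[[EFFECTOR, TARGET]] = out[[EFFECTOR, TARGET]].fillna(0).astype(int)
        return out.rename(columns={EFFECTOR: "k_effector", TARGET: "k_target"})

    def cell_positions(self, timepoint: int) -> pd.DataFrame:
        """Cells with absolute (x, y) at one timepoint."""
        d = self.droplets_at(timepoint)[["droplet_id", "x", "y"]]
        m = self.cells.merge(d, on="droplet_id", suffixes=("", "_droplet"))
        m["x"] = m["x"] + m["offset_x"]
        m["y"] = m["y"] + m["offset_y"]
        return m

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.droplets.to_csv(out_dir / "ground_truth_droplets.csv", index=False)
        self.cells.to_csv(out_dir / "ground_truth_cells.csv", index=False)
        self.config.to_yaml(out_dir / "generator_config.yaml")

    @classmethod
    def load(cls, out_dir: str | Path) -> "GroundTruth":
        out_dir = Path(out_dir)
        return cls(
            droplets=pd.read_csv(out_dir / "ground_truth_droplets.csv"),
            cells=pd.read_csv(out_dir / "ground_truth_cells.csv"),
            config=GeneratorConfig.from_yaml(out_dir / "generator_config.yaml"),
        )


# ---------------------------------------------------------------------------
# fate sampling
# ---------------------------------------------------------------------------

def sample_fates(
    cells: pd.DataFrame,
    killer_prob: float,
    death_time_dist: np.ndarray,
    seed: int | np.random.Generator = 0,
    dead_at_t0_prob: float = 0.0,
    spontaneous_target_rate: float = 0.0,
    n_timepoints: int | None = None,
) -> pd.DataFrame:
    """Assign death events to target cells.

    A target co-encapsulated with at least one effector dies with
    probability ``killer_prob`` (a lytic hit), its death hour drawn from
    ``death_time_dist``.  Targets in effector-free droplets (the internal
    negative control) die spontaneously with probability
    ``spontaneous_target_rate`` over the whole window, at an hour uniform
    over the observation span.  Independently, any cell may already be dead
    at t = 0 with probability ``dead_at_t0_prob``; such droplets are
    excluded from kinetics downstream.  Effector death is otherwise not
    simulated.

    Returns a DataFrame of death events: cell_id, droplet_id, cell_type,
    death_time (hour index).
    """
    if not 0 <= killer_prob <= 1:
        raise ValueError("killer_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.asarray(death_time_dist, float)
    p = p / p.sum() if p.sum() > 0 else p
    if n_timepoints is None:
        n_timepoints = len(p)
    events: list[tuple] = []
    if len(cells) == 0:
        return pd.DataFrame(events, columns=["cell_id", "droplet_id", "cell_type", "death_time"])

    eff_per_droplet = (
        cells[cells["cell_type"] == EFFECTOR].groupby("droplet_id").size()
    )
    hours = np.arange(len(p))
    late_hours = np.arange(1, n_timepoints)
    for row in cells.itertuples():
        death: float | None = None
        if dead_at_t0_prob > 0 and rng.random() < dead_at_t0_prob:
            death = 0
        elif row.cell_type == TARGET:
            n_eff = int(eff_per_droplet.get(row.droplet_id, 0))
            if n_eff >= 1:
                if killer_prob > 0 and rng.random() < killer_prob:
                    death = int(rng.choice(hours, p=p))
            elif spontaneous_target_rate > 0 and rng.random() < spontaneous_target_rate:
                death = int(rng.choice(late_hours))
        if death is not None:
            events.append((row.cell_id, row.droplet_id, row.cell_type, int(death)))
    return pd.DataFrame(events, columns=["cell_id", "droplet_id", "cell_type", "death_time"])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _hex_lattice(shape: tuple[int, int], margin: float, pitch: float) -> np.ndarray:
    """Hex-packed slot centers (x, y) keeping ``margin`` from tile borders."""
    h, w = shape
    xs0 = np.arange(margin, w - margin + 1e-9, pitch)
    ys = np.arange(margin, h - margin + 1e-9, pitch * np.sqrt(3) / 2)
    slots = []
    for i, y in enumerate(ys):
        xs = xs0 + (pitch / 2 if i % 2 else 0.0)
        xs = xs[xs <= w - margin + 1e-9]
        slots.extend((x, y) for x in xs)
    return np.asarray(slots, float).reshape(-1, 2)


def _sample_cell_offsets(
    rng: np.random.Generator, n: int, r_avail: float, min_sep: float
) -> np.ndarray:
    """Uniform offsets in a disk of radius ``r_avail`` with pairwise
    separation >= ``min_sep`` (rejection sampling; the separation relaxes
    if a configuration cannot be found, which at Poisson occupancies is
    vanishingly rare)."""
    for sep in (min_sep, 0.75 * min_sep, 0.0):
        for _ in range(300):
            theta = rng.uniform(0, 2 * np.pi, n)
            rad = r_avail * np.sqrt(rng.uniform(0, 1, n))
            pts = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
            if n < 2:
                return pts
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            if d[np.triu_indices(n, 1)].min() >= sep:
                return pts
    return pts  # pragma: no cover


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_ring(img: np.ndarray, x: float, y: float, r: float, depth: float, sigma: float) -> None:
    h, w = img.shape
    pad = int(np.ceil(r + 4 * sigma))
    x0, x1 = max(0, int(x) - pad), min(w, int(x) + pad + 1)
    y0, y1 = max(0, int(y) - pad), min(h, int(y) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - x, yy - y)
    img[y0:y1, x0:x1] -= depth * np.exp(-((d - r) ** 2) / (2 * sigma**2))


def _add_spot(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    pad = int(np.ceil(4 * sigma))
    x0, x1 = max(0, int(x) - pad), min(w, int(x) + pad + 1)
    y0, y1 = max(0, int(y) - pad), min(h, int(y) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    img[y0:y1, x0:x1] += amp * np.exp(-d2 / (2 * sigma**2))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_experiment(config: GeneratorConfig) -> tuple[ExperimentStack, GroundTruth]:
    """Generate a full synthetic experiment.

    Returns the image stack (uint16, channels ordered as
    :data:`droptox.io.CHANNELS`) and the ground-truth tables.  Bit-identical
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    r_mean = config.droplet_radius_px
    r_sd = config.droplet_radius_sd_px
    r_max = r_mean + 3 * r_sd
    margin = r_max + 4
    pitch = 2 * r_max + 8
    h, w = config.tile_shape
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"droplet layout infeasible: tile {config.tile_shape} cannot hold a "
            f"droplet of radius {r_mean:.1f} px with margin {margin:.1f} px"
        )

    lam_e = config.encapsulation.lambda_effector
    lam_t = config.encapsulation.lambda_target
    sigma_spot = config.cell_diameter_um / config.pixel_size_um / 2.355
    min_sep = 1.6 * config.cell_diameter_um / config.pixel_size_um

    droplet_rows: list[tuple] = []
    cell_rows: list[tuple] = []
    droplet_id = 0
    cell_id = 0

    slots = _hex_lattice(config.tile_shape, margin, pitch)
    if len(slots) == 0:
        raise ValueError("droplet layout infeasible: no lattice slots fit the tile")
    # neighbour lists for mover destinations
    dmat = np.linalg.norm(slots[:, None] - slots[None, :], axis=-1)
    neighbours = [np.flatnonzero((dmat[i] > 0) & (dmat[i] <= 1.15 * pitch)) for i in range(len(slots))]

    per_tile: dict[int, list[dict]] = {}
    for tile_id in range(config.n_tiles):
        order = rng.permutation(len(slots))
        taken = np.zeros(len(slots), bool)
        droplets: list[dict] = []
        for idx in order:
            if taken[idx]:
                continue
            taken[idx] = True
            is_mover = rng.random() < config.mover_fraction
            dest = None
            if is_mover:
                free = [j for j in neighbours[idx] if not taken[j]]
                if free:
                    dest = free[int(rng.integers(len(free)))]
                    taken[dest] = True  # reserve the landing slot
                else:
                    is_mover = False
            radius = float(np.clip(rng.normal(r_mean, r_sd), r_mean - 3 * r_sd, r_mean + 3 * r_sd))
            base = slots[idx] + rng.uniform(-2, 2, 2)
            centers = np.tile(base, (config.n_timepoints, 1))
            mover_frame = None
            if is_mover:
                mover_frame = int(rng.integers(1, config.n_timepoints))
                dest_xy = slots[dest] + rng.uniform(-2, 2, 2)
                centers[mover_frame:] = dest_xy
            jit = np.clip(
                rng.normal(0, config.jitter_sd_px, (config.n_timepoints, 2)), -2.5, 2.5
            )
            centers = centers + jit

            k_e = rng.poisson(lam_e)
            k_t = rng.poisson(lam_t)
            n_cells = k_e + k_t
            r_avail = max(radius - config.cell_radius_px - 2.0, 1.0)
            offsets = _sample_cell_offsets(rng, n_cells, r_avail, min_sep)
            types = [EFFECTOR] * k_e + [TARGET] * k_t
            cells_here = []
            for (ox, oy), ctype in zip(offsets, types):
                cells_here.append(
                    {"cell_id": cell_id, "cell_type": ctype, "offset": (float(ox), float(oy))}
                )
                cell_id += 1
            droplets.append(
                {
                    "droplet_id": droplet_id,
                    "radius": radius,
                    "is_mover": bool(is_mover),
                    "mover_frame": mover_frame,
                    "centers": centers,
                    "cells": cells_here,
                }
            )
            for t in range(config.n_timepoints):
                droplet_rows.append(
                    (tile_id, droplet_id, t, float(centers[t, 0]), float(centers[t, 1]),
                     radius, bool(is_mover))
                )
            droplet_id += 1
        per_tile[tile_id] = droplets

    # assemble the cell table, then fates
    for tile_id, droplets in per_tile.items():
        for d in droplets:
            for c in d["cells"]:
                cell_rows.append(
                    (c["cell_id"], d["droplet_id"], tile_id, c["cell_type"],
                     c["offset"][0], c["offset"][1])
                )
    cells_df = pd.DataFrame(
        cell_rows, columns=["cell_id", "droplet_id", "tile_id", "cell_type", "offset_x", "offset_y"]
    )
    events = sample_fates(
        cells_df,
        config.killer_prob,
        config.death_time_dist,
        rng,
        dead_at_t0_prob=config.dead_at_t0_prob,
        spontaneous_target_rate=config.spontaneous_target_rate,
        n_timepoints=config.n_timepoints,
    )
    death_by_cell = dict(zip(events["cell_id"], events["death_time"]))
    cells_df["death_time"] = cells_df["cell_id"].map(death_by_cell)

    droplets_df = pd.DataFrame(droplet_rows, columns=_DROPLET_COLUMNS)

    # render
    tiles: dict[int, np.ndarray] = {}
    for tile_id, droplets in per_tile.items():
        arr = np.zeros((config.n_timepoints, len(CHANNELS), h, w), np.float32)
        arr[:, 0] = config.brightfield_level
        arr[:, 1:] = config.fluor_background
        for t in range(config.n_timepoints):
            amp_eff = config.effector_amplitude * 2.0 ** (-t / config.effector_half_life_h)
            for d in droplets:
                cx, cy = d["centers"][t]
                _add_ring(arr[t, 0], cx, cy, d["radius"], config.ring_depth, config.ring_sigma_px)
                for c in d["cells"]:
                    x = cx + c["offset"][0]
                    y = cy + c["offset"][1]
                    if c["cell_type"] == EFFECTOR:
                        _add_spot(arr[t, 1], x, y, amp_eff, sigma_spot)
                    else:
                        _add_spot(arr[t, 2], x, y, config.target_amplitude, sigma_spot)
                    death = death_by_cell.get(c["cell_id"])
                    if death is not None and t >= death:
                        _add_spot(arr[t, 3], x, y, config.viability_amplitude, sigma_spot)
        if config.noise_sd > 0:
            arr += rng.normal(0, config.noise_sd, arr.shape).astype(np.float32)
        tiles[tile_id] = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)

    truth = GroundTruth(droplets=droplets_df, cells=cells_df, config=config)
    return ExperimentStack(tiles), truth
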
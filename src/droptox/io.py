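"""Experiment containers, on-disk layout and table round-tripping.

An experiment is a set of tiles (independent fields of view), each imaged at
hourly timepoints in four channels: brightfield plus three fluorescence
channels (effector tracker, target tracker, viability).  On disk each tile is
one multi-page TIFF, pages ordered time-major then channel, described by a
``layout.yaml`` next to the TIFFs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CHANNELS",
    "ExperimentStack",
    "ExperimentLayout",
    "read_experiment",
    "write_experiment",
    "write_table",
    "read_table",
]

#: fixed channel order of every stack: page index within a timepoint
CHANNELS: tuple[str, ...] = (
    "brightfield",
    "effector_tracker",
    "target_tracker",
    "viability",
)


class ExperimentStack:
    """In-memory multi-tile, multi-timepoint, multi-channel image stack.

    ``tiles[tile_id]`` is an array of shape ``(n_timepoints, n_channels,
    height, width)`` with channels ordered as :data:`CHANNELS`.
    """

    def __init__(self, tiles: Mapping[int, np.ndarray]):
        if not tiles:
            raise ValueError("experiment contains no tiles")
        shapes = {a.shape for a in tiles.values()}
        dtypes = {a.dtype for a in tiles.values()}
        if len(shapes) != 1 or len(dtypes) != 1:
            raise ValueError(
                f"tiles disagree in shape/dtype: shapes={shapes}, dtypes={dtypes}"
            )
        shape = next(iter(shapes))
        if len(shape) != 4 or shape[1] != len(CHANNELS):
            raise ValueError(
                f"tile arrays must be (time, {len(CHANNELS)} channels, h, w), got {shape}"
            )
        self.tiles = dict(tiles)

    @property
    def tile_ids(self) -> list[int]:
        return sorted(self.tiles)

    @property
    def n_timepoints(self) -> int:
        return next(iter(self.tiles.values())).shape[0]

    @property
    def tile_shape(self) -> tuple[int, int]:
        return next(iter(self.tiles.values())).shape[2:]

    def get(self, tile_id: int, timepoint: int, channel: str) -> np.ndarray:
        """2-D image for one (tile, timepoint, channel)."""
        try:
            arr = self.tiles[tile_id]
        except KeyError:
            raise KeyError(f"no such tile: {tile_id}") from None
        if not 0 <= timepoint < arr.shape[0]:
            raise IndexError(
                f"timepoint {timepoint} out of range for tile {tile_id} "
                f"({arr.shape[0]} timepoints)"
            )
        try:
            c = CHANNELS.index(channel)
        except ValueError:
            raise KeyError(f"no such channel: {channel!r} (have {CHANNELS})") from None
        return arr[timepoint, c]


@dataclasses.dataclass
class ExperimentLayout:
    """Description of an on-disk experiment directory."""

    root: Path
    tile_ids: list[int]
    n_timepoints: int
    channels: tuple[str, ...] = CHANNELS
    tile_pattern: str = "tile_{tile_id:03d}.tif"

    def tile_path(self, tile_id: int) -> Path:
        return Path(self.root) / self.tile_pattern.format(tile_id=tile_id)

    def save(self) -> Path:
        path = Path(self.root) / "layout.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "tile_ids": list(map(int, self.tile_ids)),
                    "n_timepoints": int(self.n_timepoints),
                    "channels": list(self.channels),
                    "tile_pattern": self.tile_pattern,
                },
                fh,
            )
        return path

    @classmethod
    def load(cls, root: str | Path) -> "ExperimentLayout":
        root = Path(root)
        with open(root / "layout.yaml") as fh:
            meta = yaml.safe_load(fh)
        return cls(
            root=root,
            tile_ids=list(meta["tile_ids"]),
            n_timepoints=int(meta["n_timepoints"]),
            channels=tuple(meta["channels"]),
            tile_pattern=meta.get("tile_pattern", "tile_{tile_id:03d}.tif"),
        )


def write_experiment(stack: ExperimentStack, out_dir: str | Path) -> ExperimentLayout:
    """Write one multi-page TIFF per tile (pages time-major, channel-minor)
    plus ``layout.yaml``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = ExperimentLayout(
        root=out_dir, tile_ids=stack.tile_ids, n_timepoints=stack.n_timepoints
    )
    for tile_id in stack.tile_ids:
        arr = stack.tiles[tile_id]
        t, c, h, w = arr.shape
        tifffile.imwrite(layout.tile_path(tile_id), arr.reshape(t * c, h, w))
    layout.save()
    return layout


def read_experiment(layout: ExperimentLayout | str | Path) -> ExperimentStack:
    """Load an experiment directory back into an :class:`ExperimentStack`.

    Validates that every (tile, timepoint, channel) page resolves and that
    all tiles share shape and dtype; a missing or short file raises an error
    naming the offender.
    """
    if not isinstance(layout, ExperimentLayout):
        layout = ExperimentLayout.load(layout)
    if tuple(layout.channels) != CHANNELS:
        raise ValueError(
            f"unsupported channel set {layout.channels}; expected {CHANNELS}"
        )
    n_c = len(CHANNELS)
    tiles: dict[int, np.ndarray] = {}
    for tile_id in layout.tile_ids:
        path = layout.tile_path(tile_id)
        if not path.exists():
            raise FileNotFoundError(f"missing image file for tile {tile_id}: {path}")
        pages = tifffile.imread(path)
        pages = np.atleast_3d(pages)
        if pages.ndim == 2:  # single page
            pages = pages[None]
        expected = layout.n_timepoints * n_c
        if pages.shape[0] != expected:
            # identify the first missing (timepoint, channel) page
            missing = pages.shape[0]
            t, c = divmod(missing, n_c)
            raise ValueError(
                f"tile {tile_id}: expected {expected} pages "
                f"({layout.n_timepoints} timepoints x {n_c} channels), got "
                f"{pages.shape[0]}; first missing page is timepoint {t}, "
                f"channel {CHANNELS[c]!r}"
            )
        tiles[tile_id] = pages.reshape(
            layout.n_timepoints, n_c, pages.shape[1], pages.shape[2]
        )
    return ExperimentStack(tiles)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV output table (stable column order, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    # round-trip float parsing so write -> read -> write is bit-identical
    return pd.read_csv(path, float_precision="round_trip")


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
    return path
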
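"""Per-droplet fluorescence preprocessing and cell counting.

For every tracked droplet and channel the script crops a square around the
droplet, applies a white top-hat filter (background removal), zeroes every
pixel outside the droplet disk, thresholds to a binary image, and counts
the surviving connected components as cells.  Counts at the first
timepoint define the droplet's E:T occupancy class; cell division is not
considered, so occupancy stays frozen for the whole experiment.

Dead cells light up in the viability channel; each viability object is
attributed to the cell type (effector or target) whose nearest tracker
object lies within one cell diameter, falling back to the t = 0 tracker
positions when a tracker dye has decayed below detectability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "CellDetectionConfig",
    "preprocess_channel",
    "count_cells",
    "census_droplet",
    "attribute_dead_cells",
]

OBJECT_COLUMNS = ["x", "y", "area", "mean_intensity"]


@dataclass
class CellDetectionConfig:
    """Segmentation knobs, all derived from the nominal cell diameter."""

    cell_diameter_px: float = 10.0
    crop_margin_px: int = 4
    #: structuring-element radius for the white top-hat
    tophat_radius_px: float | None = None  # default 1.5 x cell radius
    min_area_px: float | None = None  # default 0.25 x nominal cell area
    max_area_px: float | None = None  # default 4 x nominal cell area
    #: minimum foreground/background separation for Otsu to be trusted
    contrast_floor: float = 150.0

    def __post_init__(self) -> None:
        area = np.pi * (self.cell_diameter_px / 2) ** 2
        if self.tophat_radius_px is None:
            self.tophat_radius_px = 1.5 * self.cell_diameter_px / 2
        if self.min_area_px is None:
            self.min_area_px = 0.25 * area
        if self.max_area_px is None:
            self.max_area_px = 4.0 * area


def preprocess_channel(
    fluor_image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    config: CellDetectionConfig,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Crop one droplet from a fluorescence image and binarise it.

    Steps, in order: square crop of side ``2 r + 2 margin`` around the
    droplet center; white top-hat with a disk structuring element; set
    non-droplet pixels to zero; threshold (Otsu over the in-disk pixels,
    with a contrast floor below which the droplet is declared empty).

    Returns
    -------
    (binary, filtered, origin)
        ``binary`` and the top-hat-filtered crop, plus the (x0, y0) tile
        coordinates of the crop's top-left pixel.
    """
    if config.tophat_radius_px <= 0:
        raise ValueError("tophat_radius_px must be positive")
    x, y = center
    h, w = fluor_image.shape
    half = int(np.ceil(radius)) + config.crop_margin_px
    x0, x1 = max(0, int(round(x)) - half), min(w, int(round(x)) + half + 1)
    y0, y1 = max(0, int(round(y)) - half), min(h, int(round(y)) + half + 1)
    crop = fluor_image[y0:y1, x0:x1].astype(float)

    selem = morphology.disk(int(round(config.tophat_radius_px)), decomposition="sequence")
    filtered = morphology.white_tophat(crop, selem)

    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    filtered = np.where(disk, filtered, 0.0)

    inside = filtered[disk]
    binary = np.zeros_like(filtered, bool)
    if inside.size:
        spread = float(np.percentile(inside, 99.8) - np.median(inside))
        if spread >= config.contrast_floor:
            thresh = threshold_otsu(inside)
            binary = disk & (filtered > thresh)
            # a component whose intensity peak sits on the rim is the clipped
            # tail of a source outside the droplet; a genuine in-droplet cell
            # peaks at its own center, well inside the disk
            if binary.any():
                dist = np.hypot(xx - x, yy - y)
                labels = measure.label(binary, connectivity=2)
                for lab in range(1, labels.max() + 1):
                    comp = labels == lab
                    peak = np.unravel_index(
                        np.argmax(np.where(comp, filtered, -np.inf)), filtered.shape
                    )
                    if dist[peak] > radius - 2.0:
                        binary[comp] = False
    return binary, filtered, (x0, y0)


def _split_component(
    comp_mask: np.ndarray, intensity: np.ndarray, min_distance: int
) -> list[np.ndarray]:
    """Split one binary component at its intensity peaks.

    Two cells whose blobs touch binarise into a single component; their
    intensity profile still shows one peak per cell.  Peaks are local
    maxima at least ``min_distance`` apart and above half the component
    maximum (suppressing noise ripples on the flanks); pixels are assigned
    to the nearest peak.  A component with a single peak is returned whole.
    """
    from skimage.feature import peak_local_max

    vals = np.where(comp_mask, intensity, -np.inf)
    smooth = ndi.gaussian_filter(np.where(comp_mask, intensity, 0.0), 1.0)
    smooth = np.where(comp_mask, smooth, -np.inf)
    peaks = peak_local_max(
        smooth,
        min_distance=min_distance,
        threshold_abs=0.5 * float(vals.max()),
        exclude_border=False,
    )
    if len(peaks) <= 1:
        return [comp_mask]
    yy, xx = np.nonzero(comp_mask)
    d2 = (yy[:, None] - peaks[:, 0][None, :]) ** 2 + (xx[:, None] - peaks[:, 1][None, :]) ** 2
    owner = d2.argmin(axis=1)
    pieces = []
    for k in range(len(peaks)):
        piece = np.zeros_like(comp_mask)
        piece[yy[owner == k], xx[owner == k]] = True
        pieces.append(piece)
    return pieces


def count_cells(
    binary: np.ndarray,
    min_area: float,
    max_area: float,
    intensity: np.ndarray | None = None,
    origin: tuple[int, int] = (0, 0),
    split_min_distance: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Count 8-connected components of a binary crop within area bounds.

    With ``split_min_distance`` set (and an intensity image available),
    components holding several intensity peaks are split into one object
    per peak — touching cells otherwise merge into one count.

    Returns the count and an object table with centroids in tile
    coordinates (``origin`` offsets the crop), areas and mean intensities
    (NaN when no intensity image is given).
    """
    labels = measure.label(binary, connectivity=2)
    rows = []
    for p in measure.regionprops(labels):
        if p.area < min_area:
            continue
        comp = labels == p.label
        if split_min_distance and intensity is not None:
            pieces = _split_component(comp, intensity, int(split_min_distance))
        else:
            pieces = [comp]
        if len(pieces) == 1 and p.area > max_area:
            continue
        for piece in pieces:
            area = int(piece.sum())
            if not min_area <= area <= max_area:
                continue
            yy, xx = np.nonzero(piece)
            if intensity is not None:
                w = intensity[yy, xx]
                mean_int = float(w.mean())
            else:
                mean_int = np.nan
            rows.append(
                (float(xx.mean()) + origin[0], float(yy.mean()) + origin[1], area, mean_int)
            )
    objects = pd.DataFrame(rows, columns=OBJECT_COLUMNS)
    return len(objects), objects


def census_droplet(
    track_id: int, n_effector: int, n_target: int
) -> dict:
    """Occupancy record of one complete track from its t = 0 counts.

    Flags the strata the analysis cares about: 1:1 pairs (the cytotoxicity
    readout), single-species droplets (internal negative controls), and
    multi-cell droplets (serial-killing candidates).
    """
    return {
        "track_id": track_id,
        "k_effector": int(n_effector),
        "k_target": int(n_target),
        "occupancy": f"E:T {int(n_effector)}:{int(n_target)}",
        "pair_1_1": n_effector == 1 and n_target == 1,
        "effector_only": n_effector > 0 and n_target == 0,
        "target_only": n_target > 0 and n_effector == 0,
        "multi": n_effector + n_target > 2,
    }


def attribute_dead_cells(
    viability_objects: pd.DataFrame,
    effector_objects: pd.DataFrame,
    target_objects: pd.DataFrame,
    cell_diameter_px: float,
    effector_objects_t0: pd.DataFrame | None = None,
    target_objects_t0: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each viability object of one droplet/timepoint to a cell type.

    The nearest tracker-object centroid decides; when a tracker channel has
    no objects at the current timepoint (decayed dye) its t = 0 objects are
    used instead.  Objects with no tracker centroid within
    ``cell_diameter_px`` are counted as ``unknown``.

    Returns the viability objects with an added ``attributed_type`` column
    (``effector`` | ``target`` | ``unknown``).
    """
    def _fallback(now: pd.DataFrame, t0: pd.DataFrame | None) -> pd.DataFrame:
        if len(now) or t0 is None:
            return now
        return t0

    eff = _fallback(effector_objects, effector_objects_t0)
    tgt = _fallback(target_objects, target_objects_t0)

    out = viability_objects.copy()
    types = []
    for v in viability_objects.itertuples():
        best_type, best_d = "unknown", np.inf
        for name, objs in (("effector", eff), ("target", tgt)):
            if len(objs) == 0:
                continue
            d = np.hypot(objs["x"] - v.x, objs["y"] - v.y).min()
            if d < best_d:
                best_type, best_d = name, d
        types.append(best_type if best_d <= cell_diameter_px else "unknown")
    out["attributed_type"] = types
    return out
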
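"""Droplet detection in brightfield frames.

Droplets appear as dark circular rims on a light background.  Each frame is
contrast-stretched, edge-filtered and run through a circular Hough
transform; overlapping detections are suppressed and droplets touching the
tile border are discarded (partial droplets would corrupt per-droplet
counts).  Detection is fully deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skimage import exposure, feature, transform, util

__all__ = ["stretch_contrast", "find_droplets", "make_droplet_mask"]

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["droplet_index", "x", "y", "radius", "hough_score"]


def stretch_contrast(image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linear contrast stretch.

    Rescales the intensity window between the ``low_pct`` and ``high_pct``
    percentiles to the full output range of the image's dtype (to [0, 1]
    for float images), clipping values outside the window.  A constant
    image is returned unchanged (logged).
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    lo, hi = np.percentile(image, [low_pct, high_pct])
    if hi <= lo:
        logger.warning("stretch_contrast: constant image window, returned unchanged")
        return image.copy()
    return exposure.rescale_intensity(image, in_range=(lo, hi))


def _refine_radius(
    image: np.ndarray, x: float, y: float, r0: float, halfwidth: float = 3.0
) -> float:
    """Refine a droplet radius to the darkest ring around (x, y).

    The Hough accumulator locks onto the edges of the rim annulus; the
    radial-profile minimum recovers the annulus center line.
    """
    h, w = image.shape
    pad = int(np.ceil(r0 + halfwidth + 1))
    x0, x1 = max(0, int(x) - pad), min(w, int(x) + pad + 1)
    y0, y1 = max(0, int(y) - pad), min(h, int(y) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - x, yy - y).ravel()
    v = image[y0:y1, x0:x1].ravel().astype(float)
    radii = np.arange(max(r0 - halfwidth, 1.0), r0 + halfwidth + 0.25, 0.25)
    means = np.full(len(radii), np.inf)
    for i, r in enumerate(radii):
        sel = np.abs(d - r) <= 0.75
        if sel.any():
            means[i] = v[sel].mean()
    return float(radii[int(np.argmin(means))])


def find_droplets(
    brightfield: np.ndarray,
    radius_range: tuple[float, float],
    sensitivity: float = 0.35,
    canny_sigma: float = 2.0,
    refine_radii: bool = True,
) -> pd.DataFrame:
    """Detect droplets in one brightfield frame by circular Hough transform.

    Parameters
    ----------
    brightfield : 2-D array
        Raw brightfield tile.
    radius_range : (r_min, r_max)
        Radius search bounds in pixels (inclusive, 1 px steps).
    sensitivity : float
        Minimum normalised Hough accumulator score in (0, 1]; lower accepts
        weaker circles.
    canny_sigma : float
        Gaussian smoothing of the edge detector.
    refine_radii : bool
        Refine each radius to the darkest ring via a radial profile.

    Returns
    -------
    pandas.DataFrame
        Columns ``droplet_index`` (1-based, sorted by descending score),
        ``x, y`` (0-based pixel coordinates, origin top-left), ``radius``,
        ``hough_score``.  Detections whose disk crosses the tile border are
        removed; centers closer than ``r_min`` to a stronger detection are
        suppressed.
    """
    r_min, r_max = radius_range
    if not 0 < r_min <= r_max:
        raise ValueError(f"invalid radius_range {radius_range}")
    if not 0 < sensitivity <= 1:
        raise ValueError(f"sensitivity must be in (0, 1], got {sensitivity}")

    img = util.img_as_float(brightfield)
    img = stretch_contrast(img, 1, 99)
    edges = feature.canny(img, sigma=canny_sigma)
    radii = np.arange(int(np.floor(r_min)), int(np.ceil(r_max)) + 1)
    hspaces = transform.hough_circle(edges, radii)
    scores, cx, cy, rr = transform.hough_circle_peaks(
        hspaces,
        radii,
        min_xdistance=int(r_min),
        min_ydistance=int(r_min),
        threshold=sensitivity,
        normalize=True,
    )

    h, w = brightfield.shape
    rows = []
    for s, x, y, r in zip(scores, cx, cy, rr):
        r = float(r)
        if refine_radii:
            r = _refine_radius(img, float(x), float(y), r)
        # border rule: the full disk must lie inside the tile
        if x - r < 0 or y - r < 0 or x + r > w - 1 or y + r > h - 1:
            continue
        rows.append((float(x), float(y), r, float(s)))

    # greedy non-maximum suppression on center distance (hough_circle_peaks
    # suppresses per-axis; enforce the radial rule exactly)
    rows.sort(key=lambda t: -t[3])
    kept: list[tuple] = []
    for x, y, r, s in rows:
        if all(np.hypot(x - kx, y - ky) >= r_min for kx, ky, _, _ in kept):
            kept.append((x, y, r, s))

    return pd.DataFrame(
        [(i + 1, x, y, r, s) for i, (x, y, r, s) in enumerate(kept)],
        columns=DETECTION_COLUMNS,
    )


def make_droplet_mask(detections: pd.DataFrame, image_shape: tuple[int, int]) -> np.ndarray:
    """Label image of droplet disks.

    Each detection paints a disk of its radius with its ``droplet_index``
    (pixel-center containment).  Where disks overlap, the detection with
    the higher Hough score wins (earlier labels are never overwritten);
    overlaps are logged.
    """
    h, w = image_shape
    mask = np.zeros((h, w), np.int32)
    if len(detections) == 0:
        return mask
    ordered = detections.sort_values("hough_score", ascending=False)
    for det in ordered.itertuples():
        x, y, r = det.x, det.y, det.radius
        x0, x1 = max(0, int(np.floor(x - r))), min(w, int(np.ceil(x + r)) + 1)
        y0, y1 = max(0, int(np.floor(y - r))), min(h, int(np.ceil(y + r)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        region = mask[y0:y1, x0:x1]
        clash = disk & (region != 0)
        if clash.any():
            logger.info(
                "droplet %d overlaps an earlier label on %d px; keeping earlier",
                det.droplet_index,
                int(clash.sum()),
            )
        region[disk & (region == 0)] = det.droplet_index
    return mask
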
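"""Prominence-based local-maxima spot detection on 2D section images.

EdU-labeled nuclei appear as bright, roughly Gaussian spots on a dim
background, and one detected maximum corresponds to one nucleus. The
detector reports exactly the regional maxima whose *prominence* is at least
the ``tolerance``: a retained maximum at level v must not be connectable to
any strictly higher pixel by an 8-connected path whose minimum stays above
``v − tolerance``. Within one such tolerance basin only the highest maximum
survives; equal-valued maxima sharing a basin collapse to the one whose
plateau contains the lexicographically smallest (row, col) pixel. Plateaus
(connected sets of equal-valued maximal pixels) are reported as a single
peak, by default at the rounded centroid of the plateau.

Detection is per-section 2D: at 5x magnification the focal depth exceeds the
mounted section thickness, so each nucleus is in focus on exactly one
section and no z-deduplication is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import local_maxima

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionParams:
    tolerance: float = 1500.0
    exclude_border: int = 0
    plateau_policy: str = "centroid"  # or "first"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.plateau_policy not in ("centroid", "first"):
            raise ValueError(f"unknown plateau_policy {self.plateau_policy!r}")


def find_maxima(image: np.ndarray, params: DetectionParams | None = None) -> pd.DataFrame:
    """Detect prominence-filtered local maxima on a single-channel image.

    Returns a DataFrame with columns ``x_px`` (column), ``y_px`` (row) and
    ``value`` (the plateau intensity), sorted by (y_px, x_px). A constant
    image yields an empty result.
    """
    params = params or DetectionParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {image.shape}")
    if not np.all(np.isfinite(image.astype(np.float64))):
        raise ValueError("image contains non-finite values")
    work = image.astype(np.float64)

    # regional-maxima plateaus (a plateau with any strictly higher 8-neighbor
    # anywhere along its border is excluded entirely)
    mask = local_maxima(work, connectivity=2, allow_borders=True)
    if not mask.any():
        return _empty_peaks()
    lbl, n = ndimage.label(mask, structure=_STRUCT8)
    plateaus = []  # (value, lexmin (row,col), centroid (row,col))
    coords = np.argwhere(mask)
    ids = lbl[mask]
    order = np.argsort(ids, kind="stable")
    coords = coords[order]
    ids = ids[order]
    starts = np.searchsorted(ids, np.arange(1, n + 1))
    stops = np.append(starts[1:], len(ids))
    for s, e in zip(starts, stops):
        px = coords[s:e]
        value = work[px[0, 0], px[0, 1]]
        lexmin = tuple(px[np.lexsort((px[:, 1], px[:, 0]))[0]])
        centroid = (int(round(px[:, 0].mean())), int(round(px[:, 1].mean())))
        plateaus.append((value, lexmin, centroid))

    accepted = []
    for value in np.unique([p[0] for p in plateaus]):
        group = [p for p in plateaus if p[0] == value]
        # basin at this level: pixels reachable without dropping to v - tol
        basin = ndimage.label(work > value - params.tolerance, structure=_STRUCT8)[0]
        rids = [basin[p[1]] for p in group]
        needed = np.unique(rids)
        rmax = dict(zip(needed, ndimage.maximum(work, labels=basin, index=needed)))
        by_region: dict[int, list] = {}
        for p, rid in zip(group, rids):
            if rmax[rid] > value:  # a strictly higher summit shares the basin
                continue
            by_region.setdefault(int(rid), []).append(p)
        for peers in by_region.values():
            # equal-valued maxima in one basin: keep the lexicographic first
            accepted.append(min(peers, key=lambda p: p[1]))

    rows, cols, values = [], [], []
    for value, lexmin, centroid in accepted:
        r, c = centroid if params.plateau_policy == "centroid" else lexmin
        eb = params.exclude_border
        if eb and not (eb <= r < image.shape[0] - eb and eb <= c < image.shape[1] - eb):
            continue
        rows.append(r)
        cols.append(c)
        values.append(image[lexmin])
    out = pd.DataFrame({"x_px": cols, "y_px": rows, "value": values})
    return out.sort_values(["y_px", "x_px"], ignore_index=True)


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame({"x_px": pd.Series(dtype=int),
                         "y_px": pd.Series(dtype=int),
                         "value": pd.Series(dtype=float)})


def false_positive_review(
    peaks: pd.DataFrame,
    image: np.ndarray | None = None,
    min_peak_value: float = 0.0,
) -> pd.DataFrame:
    """Drop peaks whose intensity falls below ``min_peak_value``.

    Automated stand-in for manual curation of false positives: dim maxima
    that clear the prominence tolerance but are not plausible nuclei are
    removed by a brightness floor. Uses the recorded peak value, or looks it
    up in ``image`` when the peaks table lacks one. Removals are logged.
    """
    if min_peak_value < 0:
        raise ValueError("min_peak_value must be non-negative")
    if "value" in peaks.columns:
        vals = peaks["value"].to_numpy(dtype=float)
    else:
        if image is None:
            raise ValueError("peaks have no 'value' column and no image was given")
        vals = np.asarray(image, dtype=float)[peaks["y_px"].to_numpy(int),
                                              peaks["x_px"].to_numpy(int)]
    keep = vals >= min_peak_value
    removed = int((~keep).sum())
    if removed:
        logger.info("false-positive review removed %d of %d peaks", removed, len(peaks))
    return peaks[keep].reset_index(drop=True)


def detect_sections(
    images: list[np.ndarray],
    params: DetectionParams | None = None,
    min_peak_value: float = 0.0,
) -> pd.DataFrame:
    """Run the detector over a stack of section images.

    Returns one table with columns section_index, x_px, y_px, value.
    """
    frames = []
    for k, img in enumerate(images):
        peaks = find_maxima(img, params)
        if min_peak_value > 0:
            peaks = false_positive_review(peaks, img, min_peak_value)
        peaks.insert(0, "section_index", k)
        frames.append(peaks)
    if not frames:
        return pd.DataFrame(columns=["section_index", "x_px", "y_px", "value"])
    return pd.concat(frames, ignore_index=True)
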
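"""Serial-section stack assembly and bilateral utilities.

Detections made on individual transverse sections are lifted into a single
3D point cloud in physical µm coordinates. The convention, fixed here and
used throughout the package: x is the left-right axis (sagittal midplane
orthogonal to it), y is dorso-ventral, z is the rostro-caudal section axis.
The z coordinate of every nucleus is placed at the *center* of its section,
``(section_index + 0.5) * thickness``, which is unbiased when nuclei are
uniformly distributed through the section thickness.

Sections are assumed pre-aligned (registration is upstream of this package);
the synthetic generator produces aligned sections by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THICKNESS_UM = 50.0
DEFAULT_PIXEL_UM = 1.29


@dataclass
class SectionTable:
    """2D detections on one section.

    ``table`` must have columns ``x`` and ``y``; extra columns (e.g. a
    ground-truth ``label``) are carried through assembly untouched. ``units``
    says whether x/y are in µm (synthetic sectioning) or pixels (detector
    output).
    """

    index: int
    table: pd.DataFrame
    thickness_um: float = DEFAULT_THICKNESS_UM
    units: str = "um"

    def __post_init__(self) -> None:
        if self.units not in ("um", "px"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def z_offset_um(self) -> float:
        """z of the near face of the section."""
        return self.index * self.thickness_um

    def __len__(self) -> int:
        return len(self.table)


def assemble_stack(
    sections: list[SectionTable],
    thickness_um: float = DEFAULT_THICKNESS_UM,
    pixel_um: float = DEFAULT_PIXEL_UM,
) -> pd.DataFrame:
    """Assemble per-section detections into a 3D point cloud (µm).

    Pixel-unit sections are scaled by ``pixel_um``; z is set to the section
    center. Duplicate section indices are rejected; gaps in the index
    sequence are permitted and logged.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    indices = [s.index for s in sections]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise ValueError(f"duplicate section indices: {dupes}")
    if indices:
        missing = sorted(set(range(min(indices), max(indices) + 1)) - set(indices))
        if missing:
            logger.warning("missing sections in stack: %s", missing)

    frames = []
    for sec in sections:
        scale = pixel_um if sec.units == "px" else 1.0
        df = sec.table.copy()
        df["x_um"] = df.pop("x").to_numpy(dtype=float) * scale
        df["y_um"] = df.pop("y").to_numpy(dtype=float) * scale
        df["z_um"] = (sec.index + 0.5) * thickness_um
        df["section_index"] = sec.index
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["x_um", "y_um", "z_um", "section_index"])
    out = pd.concat(frames, ignore_index=True)
    cols = ["x_um", "y_um", "z_um", "section_index"]
    return out[cols + [c for c in out.columns if c not in cols]]


@dataclass
class MidlineEstimate:
    x_um: float
    n_left: int = 0
    n_right: int = 0


def estimate_midline(points: pd.DataFrame, min_points: int = 10) -> MidlineEstimate:
    """Estimate the sagittal midplane x = m as the median of x coordinates.

    Appropriate for whole-brain clouds from transverse sections, where the
    point distribution is approximately bilaterally symmetric. Returns the
    left/right counts about the estimate as a balance diagnostic.
    """
    x = np.asarray(points["x_um"], dtype=float)
    if len(x) < min_points:
        raise ValueError(f"need at least {min_points} points to estimate a midline, got {len(x)}")
    m = float(np.median(x))
    return MidlineEstimate(m, n_left=int((x < m).sum()), n_right=int((x > m).sum()))


def mirror_points(points: pd.DataFrame, midline_x: float) -> pd.DataFrame:
    """Reflect a cloud about the plane x = midline_x (an involution).

    y and z are unchanged; hemisphere labels, if present, are swapped.
    """
    if not np.isfinite(midline_x):
        raise ValueError("midline must be finite")
    out = points.copy()
    out["x_um"] = 2.0 * midline_x - out["x_um"].to_numpy(dtype=float)
    if "hemisphere" in out.columns:
        out["hemisphere"] = out["hemisphere"].map(
            {"left": "right", "right": "left", "midline": "midline"})
    return out


def assign_hemisphere(points: pd.DataFrame, midline_x: float) -> pd.DataFrame:
    """Tag each point left/right/midline relative to x = midline_x."""
    out = points.copy()
    x = out["x_um"].to_numpy(dtype=float)
    side = np.where(x < midline_x, "left", np.where(x > midline_x, "right", "midline"))
    out["hemisphere"] = side
    return out
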
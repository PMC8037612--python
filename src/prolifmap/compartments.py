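"""Compartment assignment, hierarchical counting, and high-density selection.

The brain is partitioned into a hierarchy of compartments::

    brain
    ├── mpz  (main proliferative zone)
    │   ├── cms        (caudate migratory stream)
    │   │   ├── sez        (subependymal zone, lateral ventricle walls)
    │   │   └── other_cms
    │   ├── rms        (rostral migratory stream)
    │   └── midlayer   (sheet under the external capsule)
    ├── sgz  (subgranular zone, dentate gyrus)
    └── other          (white matter + parenchyma)

Leaves partition the point set; every parent count is the exact sum of its
children. Compartment membership is mask-based (a label volume), replacing
the manual outlining used on real sections, and the phantom supplies
ground-truth masks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume import LabelVolume, OUTSIDE

logger = logging.getLogger(__name__)

#: hierarchy used with the phantom label volume (leaf values are label ids)
PHANTOM_TREE = {
    "brain": {
        "mpz": {
            "cms": {"sez": 1, "other_cms": 2},
            "rms": 3,
            "midlayer": 4,
        },
        "sgz": 5,
        "other": {"wm": 6, "parenchyma": 7},
    }
}

#: node order of the published count table
TABLE1_NODES = ["brain", "mpz", "sgz", "other", "cms", "rms", "midlayer", "sez", "other_cms"]


@dataclass
class CompartmentScheme:
    """A compartment hierarchy; leaves map names to integer label ids."""

    tree: dict = field(default_factory=lambda: PHANTOM_TREE)
    fallback: str = "parenchyma"  # leaf for points outside the labeled brain

    def leaves(self) -> dict[str, int]:
        out: dict[str, int] = {}

        def walk(node):
            for name, child in node.items():
                if isinstance(child, dict):
                    walk(child)
                else:
                    out[name] = int(child)

        walk(self.tree)
        return out

    def nodes(self) -> list[str]:
        """All node names, preorder (parents before children)."""
        out: list[str] = []

        def walk(node):
            for name, child in node.items():
                out.append(name)
                if isinstance(child, dict):
                    walk(child)

        walk(self.tree)
        return out

    def children(self, name: str) -> list[str]:
        sub = self._find(name)
        return list(sub.keys()) if isinstance(sub, dict) else []

    def leaf_ids(self, name: str) -> list[int]:
        """Leaf label ids under (and including) a node."""
        sub = self._find(name)
        if not isinstance(sub, dict):
            return [int(sub)]
        out: list[int] = []

        def walk(node):
            for child in node.values():
                if isinstance(child, dict):
                    walk(child)
                else:
                    out.append(int(child))

        walk(sub)
        return out

    def _find(self, name: str):
        def walk(node):
            for key, child in node.items():
                if key == name:
                    return child
                if isinstance(child, dict):
                    hit = walk(child)
                    if hit is not None:
                        return hit
            return None

        hit = walk(self.tree)
        if hit is None:
            raise KeyError(f"no compartment named {name!r}")
        return hit


DEFAULT_SCHEME = CompartmentScheme()


def load_table1() -> pd.DataFrame:
    """The packaged per-mouse count/density table (transcribed fixture)."""
    with resources.files("prolifmap.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


# ------------------------------------------------------------------ assignment


def assign_compartments(
    points: pd.DataFrame,
    volume: LabelVolume,
    scheme: CompartmentScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Attach a leaf compartment label to every point by voxel lookup.

    Points outside the labeled brain (out of the bounding box, or in
    label-0 voxels) fall back to the scheme's fallback leaf; their number
    is logged.
    """
    if volume.voxel_size_um is None or volume.voxel_size_um <= 0:
        raise ValueError("label volume has no valid voxel size")
    out = points.copy()
    labels = volume.label_at(out[["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
    unlabeled = labels == OUTSIDE
    if unlabeled.any():
        logger.warning("%d points outside the labeled brain assigned to %r",
                       int(unlabeled.sum()), scheme.fallback)
        labels = labels.copy()
        labels[unlabeled] = scheme.leaves()[scheme.fallback]
    out["label"] = labels.astype(np.int16)
    return out


# ---------------------------------------------------------------- count tables


def counts_table(
    points: pd.DataFrame,
    scheme: CompartmentScheme = DEFAULT_SCHEME,
    mouse_id: str = "",
    age_months: float = float("nan"),
) -> pd.DataFrame:
    """One table row of per-compartment NPC and AVND for a labeled cloud.

    NPC of a node is the point count over its leaves (so hierarchy sums hold
    exactly); AVND is the mean density over the same points, NaN when the
    node is empty.
    """
    if "label" not in points.columns:
        raise ValueError("points have no 'label' column; run assign_compartments first")
    if "density" not in points.columns:
        raise ValueError("points have no 'density' column; run neighbor_density first")
    labels = points["label"].to_numpy()
    dens = points["density"].to_numpy(dtype=float)
    row: dict[str, object] = {"mouse": mouse_id, "age_months": age_months}
    for node in scheme.nodes():
        sel = np.isin(labels, scheme.leaf_ids(node))
        row[f"{node}_npc"] = int(sel.sum())
        row[f"{node}_avnd"] = float(dens[sel].mean()) if sel.any() else float("nan")
        if not sel.any():
            logger.warning("compartment %r is empty; AVND undefined", node)
    return pd.DataFrame([row])


def verify_hierarchy(counts: pd.DataFrame, scheme: CompartmentScheme = DEFAULT_SCHEME) -> bool:
    """Check NPC(parent) == sum of NPC(children) for every row and node."""
    for node in scheme.nodes():
        kids = scheme.children(node)
        if not kids:
            continue
        total = sum(counts[f"{k}_npc"] for k in kids)
        if not (counts[f"{node}_npc"] == total).all():
            return False
    return True


# ------------------------------------------------------------ high-density set


def select_high_density(points: pd.DataFrame, fraction: float = 0.20) -> pd.DataFrame:
    """The ``ceil(fraction·n)`` points with the largest densities.

    Ties at the threshold break deterministically by (density desc,
    section_index asc, x asc, y asc). Idempotent at the same fraction.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if "density" not in points.columns:
        raise ValueError("points have no 'density' column")
    n = len(points)
    k = math.ceil(fraction * n)
    cols = ["density"]
    ascending = [False]
    for col, asc in (("section_index", True), ("x_um", True), ("y_um", True)):
        if col in points.columns:
            cols.append(col)
            ascending.append(asc)
    return points.sort_values(cols, ascending=ascending, kind="mergesort").head(k)


def bilateral_filter(
    points: pd.DataFrame,
    midline_x: float,
    pairing_radius_um: float = 200.0,
) -> pd.DataFrame:
    """Keep points whose mirror image has a selected partner nearby.

    A point survives iff at least one point of the input set lies within
    ``pairing_radius_um`` of its reflection about the plane x = midline_x.
    This suppresses unilateral aggregations while preserving bilaterally
    symmetric structures; a point on the midline pairs with itself.
    """
    if not np.isfinite(midline_x):
        raise ValueError("midline must be finite")
    xyz = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(xyz) == 0:
        return points.copy()
    mirrored = xyz.copy()
    mirrored[:, 0] = 2.0 * midline_x - mirrored[:, 0]
    tree = cKDTree(xyz)
    partners = tree.query_ball_point(mirrored, pairing_radius_um, return_length=True)
    return points[partners > 0]
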
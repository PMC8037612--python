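"""Synthetic brain phantom with known ground truth.

No raw images or deposited point clouds accompany the study this package
quantifies, so every downstream stage is exercised on a phantom: a mouse
brain modelled as an ellipsoid containing geometric stand-ins for the
proliferative compartments —

* CMS: paired curved shells on the dorsal/medial surface of a caudoputamen
  ellipsoid, split into the SEZ (medial, ventricle-facing band) and the rest;
* RMS: paired tubes running rostrally from the caudoputamen pole toward the
  olfactory bulbs;
* midlayer: paired thin horizontal sheets under the external-capsule level;
* SGZ: paired thin blades in a caudo-dorsal (hippocampal) region;
* white matter: a transverse slab spanning the midline (corpus-callosum
  analog) plus paired oblique fan slabs (internal-capsule analog);
* parenchyma: the remainder of the brain.

Nuclei are drawn from a Poisson process that is homogeneous within each
compartment, with per-compartment intensities calibrated so that the
expected counts reproduce the published per-compartment counts at a given
age. Everything is mirror-symmetric about x = 0 by construction (all shape
tests use ``|x|`` on a grid symmetric about the midplane), so the label
volume is voxel-exactly symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reconstruct import SectionTable, DEFAULT_PIXEL_UM, DEFAULT_THICKNESS_UM
from .volume import LabelVolume, OUTSIDE

logger = logging.getLogger(__name__)

# Leaf labels, in precedence order (earlier wins where shapes overlap).
SEZ = 1
CMS_OTHER = 2
RMS = 3
MIDLAYER = 4
SGZ = 5
WM = 6
PARENCHYMA = 7

LABEL_NAMES: dict[int, str] = {
    OUTSIDE: "outside",
    SEZ: "sez",
    CMS_OTHER: "other_cms",
    RMS: "rms",
    MIDLAYER: "midlayer",
    SGZ: "sgz",
    WM: "wm",
    PARENCHYMA: "parenchyma",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class PhantomSpec:
    """Geometry (all lengths in µm) and sampling pitch of the phantom.

    ``brain_extents_um`` are the full extents of the brain ellipsoid along
    (x, y, z); the defaults give a 6 × 4 × 8 mm brain, so the nominal 50 µm
    sectioning produces 160 transverse sections.
    """

    brain_extents_um: tuple[float, float, float] = (6000.0, 4000.0, 8000.0)
    voxel_size_um: float = 50.0
    # caudoputamen ellipsoid (per hemisphere, mirrored about x = 0)
    cp_center: tuple[float, float, float] = (1100.0, 0.0, 3200.0)
    cp_semi_axes: tuple[float, float, float] = (600.0, 650.0, 1000.0)
    # CMS shell: radial band outside the CP surface, dorsal or medial part
    cms_shell_band: tuple[float, float] = (1.0, 1.2)
    cms_dorsal_y_min: float = 300.0
    sez_medial_x_max: float = 700.0
    # RMS tube: segment from the rostral CP pole toward the olfactory bulb
    rms_start: tuple[float, float, float] = (1100.0, -100.0, 2200.0)
    rms_end: tuple[float, float, float] = (700.0, -400.0, 800.0)
    rms_radius_um: float = 200.0
    # midlayer sheets
    # slab faces sit on 50 µm voxel boundaries so voxelization is unbiased
    midlayer_y: float = 1300.0
    midlayer_half_thickness: float = 50.0
    midlayer_x_range: tuple[float, float] = (500.0, 2000.0)
    midlayer_z_range: tuple[float, float] = (2000.0, 5000.0)
    # SGZ blades
    sgz_y: float = 400.0
    sgz_half_thickness: float = 100.0
    sgz_x_range: tuple[float, float] = (800.0, 2000.0)
    sgz_z_range: tuple[float, float] = (4600.0, 5800.0)
    # white matter: transverse corpus-callosum slab + paired oblique fans
    cc_y: float = 1600.0
    cc_half_thickness: float = 100.0
    cc_x_max: float = 1800.0
    cc_z_range: tuple[float, float] = (2200.0, 4600.0)
    fan_y0: float = -400.0
    fan_slope: float = 0.5
    fan_half_thickness: float = 120.0
    fan_x_range: tuple[float, float] = (700.0, 1700.0)
    fan_z_range: tuple[float, float] = (2600.0, 4200.0)

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if any(e <= 0 for e in self.brain_extents_um):
            raise ValueError("brain extents must be positive")


@dataclass
class GroundTruth:
    """Sampled nucleus positions with their generating parameters."""

    points: pd.DataFrame  # columns x_um, y_um, z_um, label
    intensities: dict[int, float]  # expected nuclei per mm³ per label
    seed: int | None = None
    expected_counts: dict[int, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)


# --------------------------------------------------------------------- phantom


def build_phantom(spec: PhantomSpec | None = None) -> LabelVolume:
    """Rasterize the phantom compartments onto a label volume.

    The grid covers the brain bounding box, symmetric about x = 0, with z
    starting at 0 (rostral face). Overlaps between shapes are resolved
    silently by the precedence order CMS > RMS > midlayer > SGZ > WM >
    parenchyma; label 0 is outside the brain.
    """
    spec = spec or PhantomSpec()
    ex, ey, ez = spec.brain_extents_um
    ax, ay, az = ex / 2.0, ey / 2.0, ez / 2.0
    vox = spec.voxel_size_um
    nx, ny, nz = (int(round(e / vox)) for e in (ex, ey, ez))
    origin = np.array([-ax, -ay, 0.0])
    x = origin[0] + (np.arange(nx) + 0.5) * vox
    y = origin[1] + (np.arange(ny) + 0.5) * vox
    z = origin[2] + (np.arange(nz) + 0.5) * vox
    X = np.abs(x)[:, None, None]  # |x| makes every shape mirror-symmetric
    Y = y[None, :, None]
    Z = z[None, None, :]

    brain = (X / ax) ** 2 + (Y / ay) ** 2 + ((Z - az) / az) ** 2 <= 1.0

    cx, cy, cz = spec.cp_center
    sx, sy, sz = spec.cp_semi_axes
    rho = np.sqrt(((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 + ((Z - cz) / sz) ** 2)
    lo, hi = spec.cms_shell_band
    shell = (rho >= lo) & (rho <= hi)
    medial = X <= spec.sez_medial_x_max
    dorsal = Y >= spec.cms_dorsal_y_min
    sez = shell & medial
    cms_other = shell & dorsal & ~medial

    p0 = np.array(spec.rms_start)
    p1 = np.array(spec.rms_end)
    d = p1 - p0
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / float(d @ d)
    t = np.clip(t, 0.0, 1.0)
    dist2 = ((X - (p0[0] + t * d[0])) ** 2 + (Y - (p0[1] + t * d[1])) ** 2
             + (Z - (p0[2] + t * d[2])) ** 2)
    rms = dist2 <= spec.rms_radius_um ** 2

    def sheet(y0, half, xr, zr):
        return ((np.abs(Y - y0) <= half) & (X >= xr[0]) & (X <= xr[1])
                & (Z >= zr[0]) & (Z <= zr[1]))

    midlayer = sheet(spec.midlayer_y, spec.midlayer_half_thickness,
                     spec.midlayer_x_range, spec.midlayer_z_range)
    sgz = sheet(spec.sgz_y, spec.sgz_half_thickness, spec.sgz_x_range, spec.sgz_z_range)

    cc = ((np.abs(Y - spec.cc_y) <= spec.cc_half_thickness) & (X <= spec.cc_x_max)
          & (Z >= spec.cc_z_range[0]) & (Z <= spec.cc_z_range[1]))
    fan_center = spec.fan_y0 + spec.fan_slope * (X - (spec.fan_x_range[0] + spec.fan_x_range[1]) / 2.0)
    fan = ((np.abs(Y - fan_center) <= spec.fan_half_thickness)
           & (X >= spec.fan_x_range[0]) & (X <= spec.fan_x_range[1])
           & (Z >= spec.fan_z_range[0]) & (Z <= spec.fan_z_range[1]))
    wm = cc | fan

    data = np.zeros((nx, ny, nz), dtype=np.int16)
    # precedence: later assignments never overwrite earlier ones
    for label, mask in (
        (SEZ, sez), (CMS_OTHER, cms_other), (RMS, rms), (MIDLAYER, midlayer),
        (SGZ, sgz), (WM, wm), (PARENCHYMA, np.broadcast_to(True, data.shape)),
    ):
        sel = brain & mask & (data == 0)
        data[sel] = label

    return LabelVolume(data, vox, origin, dict(LABEL_NAMES))


# --------------------------------------------------------------- point process


def sample_nuclei(
    volume: LabelVolume,
    intensities: dict[int | str, float],
    seed: int | None = None,
) -> GroundTruth:
    """Draw nuclei from a piecewise-homogeneous Poisson process.

    ``intensities`` maps a label (id or name) to the expected number of
    nuclei per mm³ of that compartment. Within each label the count is
    Poisson(λ·V) and positions are uniform: a voxel of the label is chosen
    uniformly and the position jittered uniformly inside it, which keeps the
    label volume the single source of truth for membership.
    """
    rng = np.random.default_rng(seed)
    lam = {}
    present = set(int(v) for v in np.unique(volume.data))
    for key, value in intensities.items():
        label = NAME_TO_LABEL.get(key, key) if isinstance(key, str) else int(key)
        if label not in present:
            raise ValueError(f"label {key!r} not present in the volume")
        if value < 0:
            raise ValueError(f"intensity for label {key!r} is negative")
        lam[int(label)] = float(value)

    vox = volume.voxel_size_um
    vv = volume.voxel_volume_mm3
    chunks, labels, expected = [], [], {}
    for label in sorted(lam):
        voxels = np.argwhere(volume.data == label)
        mean = lam[label] * len(voxels) * vv
        expected[label] = mean
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        pick = voxels[rng.integers(0, len(voxels), size=n)]
        pos = volume.origin_um + (pick + rng.uniform(0.0, 1.0, size=(n, 3))) * vox
        chunks.append(pos)
        labels.append(np.full(n, label, dtype=np.int16))

    if chunks:
        pos = np.concatenate(chunks)
        lab = np.concatenate(labels)
    else:
        pos = np.empty((0, 3))
        lab = np.empty(0, dtype=np.int16)
    points = pd.DataFrame({"x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
                           "label": lab})
    return GroundTruth(points, lam, seed, expected)


def table1_intensities(
    volume: LabelVolume,
    age_months: float,
    mouse: str = "A",
    wm_factor: float = 8.0,
) -> dict[int, float]:
    """Per-compartment intensities calibrated to the published count table.

    Expected counts for the five delineated compartments (SEZ, rest of CMS,
    RMS, midlayer, SGZ) are taken from the table row for ``mouse`` at
    ``age_months`` (linear interpolation between tabulated ages; ``mouse``
    may be ``"A"``, ``"B"`` or ``"mean"``). The published "other" count is
    split between white matter and parenchyma so that the white-matter
    intensity is ``wm_factor`` times the parenchymal one — the table does
    not separate the two, only reports that the white-matter bundles are
    modestly denser than their surroundings.
    """
    from .compartments import load_table1

    t1 = load_table1()
    if mouse.lower() == "mean":
        rows = t1.groupby("age_months", as_index=True).mean(numeric_only=True)
    else:
        rows = t1[t1["mouse"].str.endswith("-" + mouse.upper())].set_index("age_months")
    ages = rows.index.to_numpy(dtype=float)
    if not (ages.min() <= age_months <= ages.max()):
        raise ValueError(f"age {age_months} outside tabulated range {ages.min()}-{ages.max()}")

    def count(col: str) -> float:
        return float(np.interp(age_months, ages, rows[col].to_numpy(dtype=float)))

    vols = volume.volumes_mm3()
    out = {
        SEZ: count("sez_npc") / vols[SEZ],
        CMS_OTHER: count("other_cms_npc") / vols[CMS_OTHER],
        RMS: count("rms_npc") / vols[RMS],
        MIDLAYER: count("midlayer_npc") / vols[MIDLAYER],
        SGZ: count("sgz_npc") / vols[SGZ],
    }
    other = count("other_npc")
    lam_par = other / (vols[PARENCHYMA] + wm_factor * vols[WM])
    out[PARENCHYMA] = lam_par
    out[WM] = wm_factor * lam_par
    return out


# ------------------------------------------------------------------ sectioning


def virtual_sectioning(
    points: pd.DataFrame,
    thickness_um: float = DEFAULT_THICKNESS_UM,
) -> list[SectionTable]:
    """Cut a 3D cloud into serial transverse sections along z.

    Each point goes to section ``floor(z / thickness)``; within-section x, y
    are preserved exactly. The output partitions the input.
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    idx = np.floor(points["z_um"].to_numpy(dtype=float) / thickness_um).astype(int)
    out = []
    order = np.argsort(idx, kind="stable")
    df = points.iloc[order]
    for k, grp in df.groupby(idx[order], sort=True):
        tab = pd.DataFrame({"x": grp["x_um"].to_numpy(dtype=float),
                            "y": grp["y_um"].to_numpy(dtype=float)})
        for col in grp.columns:
            if col not in ("x_um", "y_um", "z_um", "section_index"):
                tab[col] = grp[col].to_numpy()
        out.append(SectionTable(index=int(k), table=tab, thickness_um=thickness_um,
                                units="um"))
    return out


# ------------------------------------------------------------------- rendering


def render_sections(
    sections: list[SectionTable],
    psf_sigma_um: float = 3.0,
    pixel_um: float = DEFAULT_PIXEL_UM,
    bit_depth: int = 16,
    peak_intensity: float = 5000.0,
    background: float = 0.0,
    noise: str = "none",
    read_noise_sd: float = 0.0,
    seed: int | None = None,
    shape_px: tuple[int, int] | None = None,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> list[np.ndarray]:
    """Render sections as grayscale images with Gaussian spots.

    Each nucleus becomes an isotropic 2D Gaussian of peak ``peak_intensity``
    on a constant ``background``. ``noise`` is ``"none"`` or
    ``"poisson-gaussian"`` (shot noise on the expected image plus additive
    Gaussian read noise of ``read_noise_sd``). Images are (rows, cols) with
    column = (x − origin_x)/pixel_um and row = (y − origin_y)/pixel_um;
    nuclei falling outside the frame are clipped and logged.
    """
    maxval = 2 ** bit_depth - 1
    if peak_intensity > maxval:
        raise ValueError(f"peak_intensity {peak_intensity} exceeds {bit_depth}-bit range")
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma_um / pixel_um
    halfwin = max(1, int(np.ceil(4.0 * sigma_px)))

    if shape_px is None:
        xmax = ymax = 0.0
        for sec in sections:
            if len(sec.table):
                xmax = max(xmax, float(sec.table["x"].max()) - origin_um[0])
                ymax = max(ymax, float(sec.table["y"].max()) - origin_um[1])
        shape_px = (int(np.ceil(ymax / pixel_um)) + 2 * halfwin + 1,
                    int(np.ceil(xmax / pixel_um)) + 2 * halfwin + 1)

    nrow, ncol = shape_px
    clipped = 0
    images = []
    for sec in sections:
        img = np.full((nrow, ncol), float(background))
        cols = (sec.table["x"].to_numpy(dtype=float) - origin_um[0]) / pixel_um
        rows = (sec.table["y"].to_numpy(dtype=float) - origin_um[1]) / pixel_um
        for r, c in zip(rows, cols):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < nrow and 0 <= ci < ncol):
                clipped += 1
                continue
            r0, r1 = max(0, ri - halfwin), min(nrow, ri + halfwin + 1)
            c0, c1 = max(0, ci - halfwin), min(ncol, ci + halfwin + 1)
            rr = np.arange(r0, r1)[:, None] - r
            cc = np.arange(c0, c1)[None, :] - c
            img[r0:r1, c0:c1] += peak_intensity * np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma_px ** 2))
        if noise == "poisson-gaussian":
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if read_noise_sd > 0:
                img += rng.normal(0.0, read_noise_sd, size=img.shape)
        elif noise != "none":
            raise ValueError(f"unknown noise model {noise!r}")
        images.append(np.clip(np.round(img), 0, maxval).astype(dtype))
    if clipped:
        logger.warning("%d nuclei fell outside the rendered frame and were clipped", clipped)
    return images
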
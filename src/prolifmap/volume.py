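"""Compartment label volumes.

A :class:`LabelVolume` is a 3D integer mask over the brain bounding box with a
uniform voxel pitch. Axis order is (x, y, z) with x the left-right axis
(midline at x = 0), y dorso-ventral and z the rostro-caudal sectioning axis.
``origin_um`` is the physical coordinate of the *corner* of voxel (0, 0, 0),
so the center of voxel ``(i, j, k)`` sits at ``origin + (i+0.5, j+0.5, k+0.5)
* voxel_size``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Label value for voxels outside the brain.
OUTSIDE = 0


@dataclass
class LabelVolume:
    data: np.ndarray
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    # ------------------------------------------------------------------ geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um / 1000.0) ** 3

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (µm) of voxel centers along one axis."""
        n = self.data.shape[axis]
        return self.origin_um[axis] + (np.arange(n) + 0.5) * self.voxel_size_um

    def volumes_mm3(self) -> dict[int, float]:
        """Volume of every label (including 0) in mm³, from voxel counts."""
        ids, counts = np.unique(self.data, return_counts=True)
        return {int(i): float(c) * self.voxel_volume_mm3 for i, c in zip(ids, counts)}

    # ------------------------------------------------------------------ lookup

    def label_at(self, xyz: np.ndarray, outside: int = OUTSIDE) -> np.ndarray:
        """Nearest-voxel label lookup for points in µm.

        Points outside the bounding box get ``outside``.
        """
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        idx = np.floor((xyz - self.origin_um) / self.voxel_size_um).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(self.data.shape)), axis=1)
        out = np.full(len(xyz), outside, dtype=self.data.dtype)
        ii = idx[inside]
        out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def mirrored(self) -> "LabelVolume":
        """The volume reflected about the midplane voxel column (x axis)."""
        return LabelVolume(
            self.data[::-1].copy(), self.voxel_size_um, self.origin_um.copy(),
            dict(self.label_names),
        )

    # ------------------------------------------------------------------ I/O

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([self.voxel_size_um, self.voxel_size_um, self.voxel_size_um, 1.0])
        affine[:3, 3] = self.origin_um
        img = nib.Nifti1Image(self.data.astype(np.int16), affine)
        nib.save(img, str(path))
        if self.label_names:
            Path(str(path) + ".labels.json").write_text(
                json.dumps({str(k): v for k, v in self.label_names.items()}))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        affine = img.affine
        vox = float(affine[0, 0])
        names = {}
        sidecar = Path(str(path) + ".labels.json")
        if sidecar.exists():
            names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return cls(np.asarray(img.dataobj).astype(np.int32), vox, affine[:3, 3], names)

    def to_raw(self, path: str | Path) -> None:
        """Raw little-endian voxel dump plus a JSON header sidecar."""
        path = Path(path)
        data = np.ascontiguousarray(self.data.astype(np.int16))
        data.tofile(path)
        header = {
            "shape": list(data.shape),
            "dtype": "int16",
            "voxel_size_um": self.voxel_size_um,
            "origin_um": list(self.origin_um),
            "label_names": {str(k): v for k, v in self.label_names.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))

    @classmethod
    def from_raw(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.fromfile(path, dtype=np.dtype(header["dtype"]))
        data = data.reshape(header["shape"])
        return cls(
            data.astype(np.int32),
            float(header["voxel_size_um"]),
            np.asarray(header.get("origin_um", (0, 0, 0)), dtype=float),
            {int(k): v for k, v in header.get("label_names", {}).items()},
        )
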
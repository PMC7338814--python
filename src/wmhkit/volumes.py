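"""Volume containers and NIfTI I/O.

All in-memory volumes are plain numpy arrays on a shared voxel grid;
geometry travels alongside as a voxel-size triple (mm) and a NIfTI affine.
Millilitre computations always go through the voxel volume so anisotropic
acquisitions (e.g. 1 x 1 x 5 mm thick-slice FLAIR) are honoured.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "MultimodalVolume",
    "LesionMask",
    "read_volume",
    "write_volume",
    "voxel_volume_ml",
]


def voxel_volume_ml(voxel_mm) -> float:
    """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
    vx = np.asarray(voxel_mm, dtype=float)
    if vx.shape != (3,) or np.any(vx <= 0):
        raise ValueError(f"voxel_mm must be 3 positive values, got {voxel_mm!r}")
    return float(np.prod(vx)) / 1000.0


@dataclass
class MultimodalVolume:
    """Co-registered T1 and FLAIR intensities on one grid.

    Attributes
    ----------
    t1, flair : ndarray
        3-D intensity volumes of identical shape.
    voxel_mm : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, optional
        4x4 voxel-to-world affine; defaults to a diagonal scaling.
    """

    t1: np.ndarray
    flair: np.ndarray
    voxel_mm: tuple
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.t1 = np.asarray(self.t1, dtype=float)
        self.flair = np.asarray(self.flair, dtype=float)
        if self.t1.shape != self.flair.shape:
            raise ValueError(
                f"T1 and FLAIR grids differ: {self.t1.shape} vs {self.flair.shape}"
            )
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_mm) + [1.0])

    @property
    def shape(self):
        return self.t1.shape

    def stack(self, mask=None) -> np.ndarray:
        """Return intensities as an (n_voxels, 2) array, columns (T1, FLAIR)."""
        if mask is None:
            return np.column_stack([self.t1.ravel(), self.flair.ravel()])
        return np.column_stack([self.t1[mask], self.flair[mask]])


@dataclass
class LesionMask:
    """Binary or probabilistic WMH map with its geometry.

    ``values`` lie in [0, 1]; ``space`` records the grid the map lives on.
    """

    values: np.ndarray
    voxel_mm: tuple
    space: str = "FLAIR"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("lesion mask values must lie in [0, 1]")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)

    def binarize(self, threshold: float = 0.5) -> np.ndarray:
        return self.values >= threshold

    def volume_ml(self) -> float:
        """Integrate the (probabilistic) map into millilitres."""
        return float(self.values.sum()) * voxel_volume_ml(self.voxel_mm)


def read_volume(path):
    """Read a NIfTI volume.

    Returns
    -------
    data : ndarray
    voxel_mm : tuple of 3 floats
    affine : ndarray (4, 4)
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    voxel_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_mm, img.affine


def write_volume(path, data, voxel_mm=None, affine=None, sidecar: dict | None = None):
    """Write a NIfTI volume; optionally drop a JSON sidecar next to it."""
    data = np.asarray(data)
    if affine is None:
        vx = voxel_mm if voxel_mm is not None else (1.0, 1.0, 1.0)
        affine = np.diag(list(vx) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    if voxel_mm is not None:
        img.header.set_zooms(tuple(voxel_mm))
    nib.save(img, path)
    if sidecar is not None:
        base = str(path)
        for suffix in (".nii.gz", ".nii"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
                break
        with open(base + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
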
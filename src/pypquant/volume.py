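"""Image containers and NIfTI I/O.

The package works on reconstructed 3D SPECT volumes and 2D planar count
images.  Volumes carry an isotropic-or-not voxel spacing in mm; world
coordinates place the centre of voxel ``(0, 0, 0)`` at the origin, so the
centre of voxel ``(i, j, k)`` is ``(i, j, k) * voxel_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class ActivityVolume:
    """A 3D scalar grid of counts/voxel (or Bq/mL for ground truth).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.
    voxel_mm : tuple of 3 floats
        Voxel edge lengths in mm.
    units : str
        Free-text unit tag, e.g. ``"count/voxel"`` or ``"Bq/mL"``.
    """

    values: np.ndarray
    voxel_mm: tuple[float, float, float]
    units: str = "count/voxel"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ActivityVolume requires a 3D array")
        vm = np.asarray(self.voxel_mm, dtype=float)
        if vm.shape != (3,) or np.any(vm <= 0):
            raise ValueError("voxel_mm must be three positive lengths")
        self.voxel_mm = tuple(vm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_mm)) / 1000.0

    def coordinates(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along ``axis``."""
        return np.arange(self.values.shape[axis]) * self.voxel_mm[axis]

    def with_values(self, values: np.ndarray) -> "ActivityVolume":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class PlanarImage:
    """A 2D planar count image with pixel spacing in mm."""

    values: np.ndarray
    pixel_mm: tuple[float, float]
    units: str = "count/pixel"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PlanarImage requires a 2D array")
        pm = np.asarray(self.pixel_mm, dtype=float)
        if pm.shape != (2,) or np.any(pm <= 0):
            raise ValueError("pixel_mm must be two positive lengths")
        self.pixel_mm = tuple(pm)


def _affine(voxel_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


def save_volume(vol: ActivityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), _affine(vol.voxel_mm))
    img.header.set_zooms(vol.voxel_mm)
    nib.save(img, str(path))


def load_volume(path: str | Path, units: str = "count/voxel") -> ActivityVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return ActivityVolume(data, tuple(float(z) for z in zooms), units=units)


def save_planar(img2d: PlanarImage, path: str | Path) -> None:
    """Planar image stored as a NIfTI with a singleton third axis."""
    data = np.asarray(img2d.values, dtype=np.float32)[:, :, None]
    vm = (*img2d.pixel_mm, 1.0)
    img = nib.Nifti1Image(data, _affine(vm))
    img.header.set_zooms(vm)
    nib.save(img, str(path))


def load_planar(path: str | Path) -> PlanarImage:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError("expected a singleton third axis for a planar image")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()[:2]
    return PlanarImage(data, tuple(float(z) for z in zooms))
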
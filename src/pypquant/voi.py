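"""Volumes of interest and the heart/aorta differentiation metrics.

The differentiation workflow places an ellipsoidal VOI enclosing the entire
heart and three cylindrical VOIs along the descending aorta (height fixed at
19.5 mm, five pixels; diameter matched to the aorta).  The mean SUV of the
heart VOI is SUV_H, the unweighted mean of the three aortic VOI means is
SUV_Ao, and their ratio rSUV_H/Ao is the discriminator.  The classical
planar heart-to-contralateral-lung (H/CL) count ratio is computed from
equal-area circular ROIs, the lung ROI mirrored across the image midline at
the same height.

Voxel membership uses voxel-centre inclusion (no partial-volume weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .suv import SuvVolume
from .volume import PlanarImage


@dataclass
class EllipsoidVoi:
    """Ellipsoid in world mm; ``orientation`` rotates grid axes to VOI axes."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    orientation: np.ndarray | None = None  # 3x3 rotation, None = identity

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.radii_mm, float) <= 0):
            raise ValueError("ellipsoid radii must be positive")

    def contains(self, pts_mm: np.ndarray) -> np.ndarray:
        d = np.asarray(pts_mm, float) - np.asarray(self.center_mm, float)
        if self.orientation is not None:
            d = d @ np.asarray(self.orientation, float)
        r = np.asarray(self.radii_mm, float)
        return ((d / r) ** 2).sum(axis=-1) <= 1.0


@dataclass
class CylinderVoi:
    """Finite cylinder in world mm (default height 19.5 mm = five pixels)."""

    center_mm: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    diameter_mm: float = 20.0
    height_mm: float = 19.5

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.height_mm <= 0:
            raise ValueError("cylinder diameter and height must be positive")
        a = np.asarray(self.axis, float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("cylinder axis must be nonzero")
        self.axis = tuple(a / n)

    def contains(self, pts_mm: np.ndarray) -> np.ndarray:
        d = pts_mm - np.asarray(self.center_mm, float)
        a = np.asarray(self.axis, float)
        along = d @ a
        radial2 = (d * d).sum(-1) - along**2
        return (np.abs(along) <= self.height_mm / 2.0) & (
            radial2 <= (self.diameter_mm / 2.0) ** 2
        )


@dataclass
class CircularRoi:
    """Circular ROI on a planar image, in pixel coordinates."""

    center_px: tuple[float, float]
    radius_px: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return (ii - self.center_px[0]) ** 2 + (jj - self.center_px[1]) ** 2 <= self.radius_px**2

    def mirrored(self, shape: tuple[int, int], axis: int = 0) -> "CircularRoi":
        """Equal-area ROI mirrored across the image midline along ``axis``."""
        c = list(self.center_px)
        c[axis] = (shape[axis] - 1) - c[axis]
        return CircularRoi(tuple(c), self.radius_px)


@dataclass
class DifferentiationResult:
    suv_h: float
    suv_ao: float
    rsuv: float
    hcl: float | None = None


def voi_mask(volume: SuvVolume, voi: EllipsoidVoi | CylinderVoi) -> np.ndarray:
    shape = volume.values.shape
    ax = [np.arange(n) * vm for n, vm in zip(shape, volume.voxel_mm)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    return voi.contains(pts)


def voi_mean(volume: SuvVolume, voi: EllipsoidVoi | CylinderVoi) -> float:
    """Arithmetic mean SUV over voxels whose centres fall inside the VOI."""
    m = voi_mask(volume, voi)
    if not m.any():
        raise ValueError("VOI does not contain any voxel centre")
    return float(volume.values[m].mean())


def hcl_ratio(planar: PlanarImage, heart_roi: CircularRoi, lung_roi: CircularRoi | None = None) -> float:
    """Heart-to-contralateral-lung mean count ratio on an anterior image."""
    shape = planar.values.shape
    if lung_roi is None:
        lung_roi = heart_roi.mirrored(shape)
    hm, lm = heart_roi.mask(shape), lung_roi.mask(shape)
    if not hm.any() or not lm.any():
        raise ValueError("planar ROI contains no pixels")
    lung_mean = float(planar.values[lm].mean())
    if lung_mean <= 0:
        raise ZeroDivisionError("contralateral lung ROI has nonpositive mean counts")
    return float(planar.values[hm].mean()) / lung_mean


def differentiation_metrics(
    volume: SuvVolume,
    heart: EllipsoidVoi,
    aorta: list[CylinderVoi] | tuple[CylinderVoi, ...],
    planar: PlanarImage | None = None,
    heart_roi: CircularRoi | None = None,
    lung_roi: CircularRoi | None = None,
) -> DifferentiationResult:
    """SUV_H, SUV_Ao (mean of the three aortic VOI means), rSUV_H/Ao and H/CL."""
    if len(aorta) != 3:
        raise ValueError("exactly three aortic VOIs are required")
    suv_h = voi_mean(volume, heart)
    ao_means = [voi_mean(volume, c) for c in aorta]
    suv_ao = float(np.mean(ao_means))
    if suv_ao == 0:
        raise ZeroDivisionError("aortic mean SUV is zero")
    hcl = None
    if planar is not None:
        if heart_roi is None:
            raise ValueError("heart_roi is required when a planar image is given")
        hcl = hcl_ratio(planar, heart_roi, lung_roi)
    return DifferentiationResult(suv_h=suv_h, suv_ao=suv_ao, rsuv=suv_h / suv_ao, hcl=hcl)


def classify(
    result: DifferentiationResult,
    rsuv_cutoff: float,
    hcl_cutoff: float = 1.3,
) -> dict[str, bool]:
    """ATTR-positivity calls; a value exactly at the cutoff counts positive."""
    if rsuv_cutoff <= 0 or hcl_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    out = {"attr_positive_rsuv": bool(result.rsuv >= rsuv_cutoff)}
    if result.hcl is not None:
        out["attr_positive_hcl"] = bool(result.hcl >= hcl_cutoff)
    return out
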
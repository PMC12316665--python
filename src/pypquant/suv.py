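"""Cross-calibration and conversion of count volumes to body-weight SUV.

The body-weight SUV of a reconstructed SPECT voxel is

    SUV = counts [count/voxel] * CCF [(Bq/mL)/(count/voxel)]
          / (injected dose [Bq] / body weight [g])

The cross-calibration factor (CCF) is estimated from a uniform cylinder
phantom of known activity concentration; its interior mask is eroded by one
PSF FWHM before averaging so that partial-volume roll-off at the wall does
not bias the estimate.  No decay correction between injection and
acquisition is applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion

from .volume import ActivityVolume

log = logging.getLogger(__name__)

#: Protocol dose rule: 555 MBq standardized to 60 kg body weight, capped.
MAX_DOSE_MBQ = 555.0


def protocol_dose_mbq(weight_kg: float) -> float:
    """Weight-standardized injected dose, 555 x weight/60 MBq, max 555 MBq."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return min(MAX_DOSE_MBQ * weight_kg / 60.0, MAX_DOSE_MBQ)


@dataclass(frozen=True)
class CrossCalibration:
    """(Bq/mL) per (count/voxel) conversion factor."""

    ccf: float
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.ccf) or self.ccf <= 0:
            raise ValueError("ccf must be positive and finite")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self) | {"units": "(Bq/mL)/(count/voxel)"}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CrossCalibration":
        d = json.loads(Path(path).read_text())
        return cls(ccf=float(d["ccf"]), source=d.get("source", ""))


@dataclass
class SuvVolume:
    """Body-weight SUV per voxel (dimensionless)."""

    values: np.ndarray
    voxel_mm: tuple[float, float, float]
    dose_bq: float
    weight_g: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dose_bq <= 0 or self.weight_g <= 0:
            raise ValueError("dose and weight must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def erode_mask_by_mm(mask: np.ndarray, margin_mm: float, voxel_mm: float) -> np.ndarray:
    """Shrink a boolean mask inward by ``margin_mm``."""
    if margin_mm <= 0:
        return mask.astype(bool)
    iters = int(np.ceil(margin_mm / voxel_mm))
    return binary_erosion(mask.astype(bool), iterations=iters)


def estimate_ccf(
    counts: ActivityVolume,
    true_concentration: float,
    mask: np.ndarray,
    erode_fwhm_mm: float = 8.0,
    source: str = "cylinder phantom",
) -> CrossCalibration:
    """CCF = known concentration / mean counts over the eroded interior."""
    if true_concentration <= 0:
        raise ValueError("true_concentration must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("calibration mask is empty")
    interior = erode_mask_by_mm(mask, erode_fwhm_mm, counts.voxel_mm[0])
    if not interior.any():
        raise ValueError("calibration mask vanished after interior erosion")
    mean_count = float(counts.values[interior].mean())
    if mean_count <= 0:
        raise ValueError("mean count in calibration region is not positive")
    ccf = true_concentration / mean_count
    log.info("estimated CCF %.6g from %d voxels", ccf, int(interior.sum()))
    return CrossCalibration(ccf=ccf, source=source)


def counts_to_suv(
    counts: ActivityVolume,
    cal: CrossCalibration,
    dose_bq: float,
    weight_g: float,
) -> SuvVolume:
    """Convert a count volume to body-weight SUV.

    Negative reconstructed counts (possible after filtered reconstruction)
    are clamped to zero; the number of clamped voxels is logged.
    """
    if dose_bq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be positive")
    vals = counts.values * cal.ccf / (dose_bq / weight_g)
    n_neg = int((vals < 0).sum())
    if n_neg:
        log.warning("clamped %d negative voxels to zero at SUV conversion", n_neg)
        vals = np.clip(vals, 0.0, None)
    return SuvVolume(vals, counts.voxel_mm, dose_bq=dose_bq, weight_g=weight_g)
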
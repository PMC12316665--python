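"""Digital phantoms standing in for the study's raw images.

Two generators are provided:

* a uniform cylindrical calibration phantom of known activity concentration
  (inner diameter 16 cm, height 15 cm, 3016 mL by default), used to estimate
  the SPECT cross-calibration factor; and
* a cardiac phantom: an ellipsoidal left-ventricular myocardial shell with
  per-AHA-segment uptake multipliers over a blood-pool + lung + descending-
  aorta background.

Both emit post-reconstruction count volumes directly: the noiseless activity
concentration map is blurred with a Gaussian point-spread function and then
Poisson-sampled (when a seed is set).  Acquisition physics (projections,
scatter, attenuation) is deliberately not simulated; the PSF blur and Poisson
noise emulate its net effect on reconstructed images.

The phantom also provides an anterior planar projection (for the H/CL ratio)
and a generator of echocardiographic parameters correlated with imaging
indices at requested strengths, for exercising the cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .aha import segment_of
from .volume import ActivityVolume, PlanarImage

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Geometry, uptake levels and acquisition settings of a phantom.

    Defaults model a hypertrophic ATTR-CM-like left ventricle on a
    128-cube grid of 3.9 mm voxels (the five-pixel / 19.5 mm anchor of the
    aortic VOI height fixes the pixel pitch) with an 8 mm FWHM
    reconstruction filter.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 3.9
    myo_outer_radii: tuple[float, float, float] = (35.0, 35.0, 55.0)
    myo_inner_radii: tuple[float, float, float] = (22.0, 22.0, 41.0)
    lv_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    segment_multipliers: tuple[float, ...] = (1.0,) * 17
    blood_pool_level: float = 1000.0   # Bq/mL
    lung_level: float = 200.0          # Bq/mL
    aorta_level: float = 1000.0        # Bq/mL
    myo_base_level: float = 1000.0     # Bq/mL
    psf_fwhm_mm: float = 8.0
    count_scale: float = 0.1           # expected counts/voxel per Bq/mL
    seed: int | None = None
    # ancillary geometry (world mm); None centres the heart in the grid
    heart_center_mm: tuple[float, float, float] | None = None
    anterior: tuple[float, float, float] = (0.0, 1.0, 0.0)
    aorta_offset_mm: float = 60.0      # posterior offset of the aorta axis
    aorta_diameter_mm: float = 28.0
    lung_gap_mm: float = 45.0          # medial lung-box face from heart centre
    lung_size_mm: tuple[float, float, float] = (55.0, 110.0, 130.0)

    def __post_init__(self) -> None:
        outer = np.asarray(self.myo_outer_radii, float)
        inner = np.asarray(self.myo_inner_radii, float)
        if np.any(outer <= 0) or np.any(inner <= 0):
            raise ValueError("ellipsoid semi-axes must be positive")
        if np.any(inner >= outer):
            raise ValueError("inner radii must be strictly inside outer radii")
        mult = np.asarray(self.segment_multipliers, float)
        if mult.shape != (17,):
            raise ValueError("segment_multipliers must have exactly 17 entries")
        if np.any(mult < 0):
            raise ValueError("segment multipliers must be nonnegative")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be nonnegative")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        axis = np.asarray(self.lv_axis, float)
        if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-6):
            raise ValueError("lv_axis must be a unit vector")

    @property
    def voxel_tuple(self) -> tuple[float, float, float]:
        return (self.voxel_mm,) * 3

    def center(self) -> np.ndarray:
        if self.heart_center_mm is not None:
            return np.asarray(self.heart_center_mm, float)
        return (np.asarray(self.grid_shape, float) - 1) / 2.0 * self.voxel_mm

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right-handed frame (u, v, w): u = anterior in-plane, w = long axis."""
        w = np.asarray(self.lv_axis, float)
        a = np.asarray(self.anterior, float)
        u = a - np.dot(a, w) * w
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            raise ValueError("anterior reference is parallel to lv_axis")
        u = u / nu
        v = np.cross(w, u)
        return u, v, w


@dataclass
class GroundTruth:
    """Noiseless truth shipped with every phantom realisation."""

    true_concentration: ActivityVolume
    segment_labels: np.ndarray  # per-voxel AHA id, 0 = non-myocardium
    true_indices: "object | None" = None  # RegionalIndexSet for cardiac phantoms


def _world_grid(spec: PhantomSpec):
    shape = spec.grid_shape
    ax = [np.arange(n) * spec.voxel_mm for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def _apply_acquisition(conc: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Concentration map -> expected counts -> (optional) Poisson sample."""
    blurred = conc
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * _SIGMA_PER_FWHM / spec.voxel_mm
        blurred = gaussian_filter(conc, sigma=sigma_vox, mode="constant")
    expected = blurred * spec.count_scale
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        return rng.poisson(expected).astype(float)
    return expected


def make_cylinder_phantom(
    concentration: float,
    diameter_mm: float = 160.0,
    height_mm: float = 150.0,
    spec: PhantomSpec | None = None,
) -> tuple[ActivityVolume, GroundTruth]:
    """Uniform cylinder of known activity concentration (Bq/mL).

    The cylinder axis follows the grid z axis through the grid centre.
    Raises a geometry error if the cylinder does not fit in the grid.
    """
    if spec is None:
        spec = PhantomSpec()
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    X, Y, Z = _world_grid(spec)
    c = (np.asarray(spec.grid_shape, float) - 1) / 2.0 * spec.voxel_mm
    extent = (np.asarray(spec.grid_shape, float) - 1) * spec.voxel_mm
    if diameter_mm > extent[0] or diameter_mm > extent[1] or height_mm > extent[2]:
        raise ValueError("cylinder exceeds grid bounds")
    r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2
    inside = (r2 <= (diameter_mm / 2.0) ** 2) & (np.abs(Z - c[2]) <= height_mm / 2.0)
    conc = np.where(inside, float(concentration), 0.0)
    counts = _apply_acquisition(conc, spec)
    truth = GroundTruth(
        true_concentration=ActivityVolume(conc, spec.voxel_tuple, units="Bq/mL"),
        segment_labels=inside.astype(np.int16),
    )
    return ActivityVolume(counts, spec.voxel_tuple), truth


def _cardiac_concentration(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless concentration map and per-voxel AHA segment labels."""
    X, Y, Z = _world_grid(spec)
    c = spec.center()
    u, v, w = spec.basis()
    dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
    du = dx * u[0] + dy * u[1] + dz * u[2]
    dv = dx * v[0] + dy * v[1] + dz * v[2]
    dw = dx * w[0] + dy * w[1] + dz * w[2]  # base (0) -> apex (+)

    ao, bo, co = spec.myo_outer_radii
    ai, bi, ci = spec.myo_inner_radii
    if min(ao - ai, bo - bi, co - ci) < spec.voxel_mm:
        raise ValueError("myocardial shell is thinner than one voxel")
    q_out = (du / ao) ** 2 + (dv / bo) ** 2 + (dw / co) ** 2
    q_in = (du / ai) ** 2 + (dv / bi) ** 2 + (dw / ci) ** 2
    in_heart = q_out <= 1.0
    apex_side = dw >= 0
    shell = in_heart & apex_side & (q_in >= 1.0)
    cavity_and_base = in_heart & ~shell  # LV cavity + basal blood pool

    theta = np.degrees(np.arctan2(dv, du)) % 360.0
    f = np.clip(dw / co, 0.0, 1.0)
    apex_cap = dw > ci  # solid tip beyond the inner ellipsoid
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[shell] = segment_of(f[shell], theta[shell], apex_cap[shell])

    conc = np.zeros(spec.grid_shape, dtype=float)
    conc[cavity_and_base] = spec.blood_pool_level

    mult = np.asarray(spec.segment_multipliers, float)
    conc[shell] = spec.myo_base_level * mult[labels[shell] - 1]

    # lungs: two boxes lateral (+/- v) of the heart
    lx, ly, lz = spec.lung_size_mm
    for side in (+1.0, -1.0):
        med = spec.lung_gap_mm
        lung = (
            (side * dv >= med) & (side * dv <= med + lx)
            & (np.abs(du) <= ly / 2.0) & (np.abs(dw) <= lz / 2.0)
        )
        conc[lung & ~in_heart] = spec.lung_level

    # descending aorta: cylinder along the long axis, posterior (-u) of the heart
    r2_ao = (du + spec.aorta_offset_mm) ** 2 + dv**2
    aorta = r2_ao <= (spec.aorta_diameter_mm / 2.0) ** 2
    conc[aorta & ~in_heart] = spec.aorta_level
    return conc, labels


def true_indices_from_labels(conc: np.ndarray, labels: np.ndarray):
    """RegionalIndexSet of a noiseless phantom, from its voxel labels.

    Per-segment mean and population SD are taken over the labelled voxels of
    the noiseless concentration map, then fed through the same index
    formulas applied to measured polar maps.
    """
    from .indices import compute_indices
    from .polarmap import SegmentStats

    mean = np.zeros(17)
    sd = np.zeros(17)
    n = np.zeros(17, dtype=int)
    for s in range(1, 18):
        vals = conc[labels == s]
        if vals.size == 0:
            raise ValueError(f"segment {s} has no voxels; shell too coarse")
        mean[s - 1] = vals.mean()
        sd[s - 1] = vals.std()
        n[s - 1] = vals.size
    return compute_indices(SegmentStats(mean_suv=mean, sd_suv=sd, n_cells=n))


def make_cardiac_phantom(spec: PhantomSpec) -> tuple[ActivityVolume, GroundTruth]:
    """Cardiac phantom realisation: counts volume plus exact ground truth."""
    conc, labels = _cardiac_concentration(spec)
    counts = _apply_acquisition(conc, spec)
    truth = GroundTruth(
        true_concentration=ActivityVolume(conc, spec.voxel_tuple, units="Bq/mL"),
        segment_labels=labels,
        true_indices=true_indices_from_labels(conc, labels),
    )
    return ActivityVolume(counts, spec.voxel_tuple), truth


_AXIS_NAMES = {"x": 0, "y": 1, "z": 2}


def project_planar(volume: ActivityVolume, axis: int | str = 1) -> PlanarImage:
    """Anterior-type planar image: column sums of counts along ``axis``.

    Total counts are conserved exactly: the planar pixel sum equals the
    volume voxel sum.
    """
    if isinstance(axis, str):
        try:
            axis = _AXIS_NAMES[axis.lower()]
        except KeyError:
            raise ValueError(f"axis must be one of x/y/z or 0/1/2, got {axis!r}")
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    data = volume.values.sum(axis=axis)
    spacing = tuple(vm for i, vm in enumerate(volume.voxel_mm) if i != axis)
    return PlanarImage(data, spacing)


def synth_echo(
    cohort: pd.DataFrame,
    targets: list[tuple[str, str, float, float]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Add synthetic echocardiographic columns correlated with indices.

    Each target is ``(index_column, echo_column, correlation, noise_sd)``.
    The echo column is an affine transform of the index plus Gaussian noise
    of the stated SD, with the slope chosen so the population Pearson
    correlation equals the target.  ``correlation`` of +/-1 requires
    ``noise_sd = 0`` and yields an exact affine copy.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for index_col, echo_col, r, noise_sd in targets:
        if abs(r) > 1:
            raise ValueError(f"|correlation| must be <= 1, got {r}")
        if index_col not in out.columns:
            raise KeyError(f"unknown index column {index_col!r}")
        x = out[index_col].to_numpy(dtype=float)
        sx = x.std()
        if sx == 0:
            raise ValueError(f"index column {index_col!r} has zero variance")
        if abs(r) == 1.0:
            if noise_sd != 0:
                raise ValueError("correlation +/-1 requires zero noise SD")
            out[echo_col] = np.sign(r) * x
            continue
        if noise_sd <= 0:
            raise ValueError("noise_sd must be positive for |correlation| < 1")
        slope = np.sign(r) * (noise_sd / sx) * abs(r) / np.sqrt(1.0 - r * r)
        out[echo_col] = slope * x + rng.normal(0.0, noise_sd, size=x.size)
    return out
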
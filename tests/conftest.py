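import numpy as np
import pytest

from pypquant.phantom import PhantomSpec
from pypquant.polarmap import PolarMap, SegmentStats
from pypquant.suv import SuvVolume


@pytest.fixture
def small_spec():
    """Small noiseless, blur-free cardiac phantom spec for fast geometry tests."""
    return PhantomSpec(
        grid_shape=(96, 96, 96), voxel_mm=3.9,
        psf_fwhm_mm=0.0, seed=None, count_scale=1.0,
    )


def septal_spec(multiplier, **kw):
    mult = [1.0] * 17
    for s in (2, 3, 8, 9, 14):
        mult[s - 1] = multiplier
    return PhantomSpec(
        grid_shape=(96, 96, 96), voxel_mm=3.9, psf_fwhm_mm=0.0, seed=None,
        count_scale=1.0, segment_multipliers=tuple(mult), **kw,
    )


def uniform_polar_map(value=2.0, n_rings=15, n_rays=60):
    """Constant polar map with the standard parcellation."""
    from pypquant.polarmap import ShortAxisStack, build_polar_map

    slices = np.full((n_rings, 21, 21), value)
    centers = np.full((n_rings, 2), 10.0)
    stack = ShortAxisStack(slices=slices, center_px=centers, slice_spacing_mm=4.0)
    return build_polar_map(stack, n_rays=n_rays)


def uniform_suv(shape=(20, 20, 20), value=1.0, voxel_mm=2.0):
    return SuvVolume(np.full(shape, value), (voxel_mm,) * 3, dose_bq=1e6, weight_g=1e3)


def stats_from_means(means, sds=None):
    means = np.asarray(means, float)
    sds = np.zeros(17) if sds is None else np.asarray(sds, float)
    return SegmentStats(mean_suv=means, sd_suv=sds, n_cells=np.full(17, 10))
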
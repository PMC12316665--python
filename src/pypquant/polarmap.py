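"""Left-ventricular polar map by radial-maximum sampling.

The polar (bullseye) map is built slice by slice: the SUV volume is resliced
orthogonally to the LV long axis, the maximum interpolated SUV along radial
rays from each slice's LV centre is extracted, and the per-slice profiles are
arranged concentrically with the base outermost and the apex at the centre.
Cells are parcellated into the AHA 17-segment model: rings are split into
basal/mid/apical thirds by slice count, basal and mid rings into six
60-degree sectors, apical rings into four 90-degree sectors, and an apex-cap
disk (segment 17) covers the innermost rings (ceil of 10% of the ring
count).  Populating all 17 segments therefore requires the apical third to
hold at least one ring beyond the cap (in practice stacks of >= 7 slices;
clinical stacks have 10-20).

The display ceiling metadata defaults to SUV 4.0, the conventional upper
limit used when rendering these maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .aha import sector_of
from .suv import SuvVolume


@dataclass
class ShortAxisStack:
    """Ordered short-axis SUV slices, base first, apex last."""

    slices: np.ndarray            # (n_slices, nu, nv)
    center_px: np.ndarray         # (n_slices, 2) per-slice LV centre
    slice_spacing_mm: float
    pixel_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        self.center_px = np.asarray(self.center_px, dtype=float)
        if self.slices.ndim != 3 or self.slices.shape[0] < 3:
            raise ValueError("a short-axis stack needs at least 3 slices")
        if self.center_px.shape != (self.slices.shape[0], 2):
            raise ValueError("center_px must be (n_slices, 2)")
        nu, nv = self.slices.shape[1:]
        if np.any(self.center_px < 0) or np.any(self.center_px[:, 0] > nu - 1) or np.any(
            self.center_px[:, 1] > nv - 1
        ):
            raise ValueError("slice centres must lie inside the slice bounds")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass
class PolarMap:
    """Concentric radial-maximum map with per-cell AHA segment labels.

    Ring 0 is the base (outermost); the last ring is the apex (centre of the
    displayed bullseye).  Angle 0 is the anterior wall, increasing
    counterclockwise viewed from the apex.
    """

    grid: np.ndarray            # (n_rings, n_rays)
    segment_of: np.ndarray      # same shape, values 1..17
    angle_deg: np.ndarray       # (n_rays,)
    display_ceiling: float = 4.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.segment_of = np.asarray(self.segment_of, dtype=int)
        if self.grid.shape != self.segment_of.shape:
            raise ValueError("grid and segment_of shapes differ")
        if self.segment_of.min() < 1 or self.segment_of.max() > 17:
            raise ValueError("segment ids must lie in 1..17")

    @property
    def n_rings(self) -> int:
        return self.grid.shape[0]

    @property
    def n_rays(self) -> int:
        return self.grid.shape[1]


@dataclass
class SegmentStats:
    """Per-segment mean, SD and cell count (segments 1..17 in order)."""

    mean_suv: np.ndarray
    sd_suv: np.ndarray
    n_cells: np.ndarray

    def __post_init__(self) -> None:
        self.mean_suv = np.asarray(self.mean_suv, dtype=float)
        self.sd_suv = np.asarray(self.sd_suv, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        for a in (self.mean_suv, self.sd_suv, self.n_cells):
            if a.shape != (17,):
                raise ValueError("segment statistics must have 17 entries")
        if np.any(self.sd_suv < 0):
            raise ValueError("segment SDs must be nonnegative")
        if np.any(self.n_cells < 1):
            raise ValueError("every segment must contain at least one cell")


def _orthonormal_basis(axis, anterior=(0.0, 1.0, 0.0)):
    w = np.asarray(axis, float)
    if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-6):
        raise ValueError("lv_axis must be a unit vector")
    a = np.asarray(anterior, float)
    u = a - np.dot(a, w) * w
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise ValueError("anterior reference parallel to the long axis")
    u /= nu
    return u, np.cross(w, u), w


def slice_center(slice2d: np.ndarray, threshold_frac: float = 0.5) -> np.ndarray:
    """LV centre of one slice: centroid of supra-threshold pixels.

    Pixels at or above ``threshold_frac`` of the slice maximum contribute;
    an all-nonpositive slice falls back to the geometric centre.
    """
    s = np.asarray(slice2d, float)
    mx = s.max()
    if mx <= 0:
        return (np.asarray(s.shape, float) - 1) / 2.0
    mask = s >= threshold_frac * mx
    idx = np.argwhere(mask)
    return idx.mean(axis=0)


def reslice_short_axis(
    volume: SuvVolume,
    lv_axis,
    lv_center_mm,
    extent_mm: float,
    in_plane_half_mm: float | None = None,
    anterior=(0.0, 1.0, 0.0),
    centers_px: np.ndarray | None = None,
) -> ShortAxisStack:
    """Resample the SUV volume into short-axis planes, base to apex.

    Planes are orthogonal to ``lv_axis``, spaced at the voxel pitch starting
    at ``lv_center_mm`` (the base plane, offset 0) and marching towards the
    apex up to ``extent_mm``.  Values are trilinearly interpolated at the
    volume's in-plane resolution.  Slice row axis = anterior direction,
    column axis completes a right-handed frame with the long axis.
    """
    if extent_mm <= 0:
        raise ValueError("extent must be positive")
    u, v, w = _orthonormal_basis(lv_axis, anterior)
    pitch = float(volume.voxel_mm[0])
    if in_plane_half_mm is None:
        in_plane_half_mm = extent_mm
    n_slices = int(np.floor(extent_mm / pitch)) + 1
    if n_slices < 3:
        raise ValueError("extent spans fewer than 3 slices")
    half_n = int(np.floor(in_plane_half_mm / pitch))
    offs = (np.arange(2 * half_n + 1) - half_n) * pitch
    c0 = np.asarray(lv_center_mm, float)

    extent_world = (np.asarray(volume.values.shape, float) - 1) * np.asarray(volume.voxel_mm)
    depth = np.arange(n_slices) * pitch
    corners = (
        c0[None, :]
        + depth[[0, -1]][:, None] * w[None, :]
    )
    for corner in corners:
        for du in (offs[0], offs[-1]):
            for dv in (offs[0], offs[-1]):
                p = corner + du * u + dv * v
                if np.any(p < -pitch) or np.any(p > extent_world + pitch):
                    raise ValueError("requested reslice extent exceeds the grid")

    UU, VV = np.meshgrid(offs, offs, indexing="ij")
    slices = np.empty((n_slices, offs.size, offs.size))
    for k, d in enumerate(depth):
        pts = (
            c0[None, None, :]
            + UU[..., None] * u[None, None, :]
            + VV[..., None] * v[None, None, :]
            + d * w[None, None, :]
        )
        coords = pts / np.asarray(volume.voxel_mm)[None, None, :]
        slices[k] = map_coordinates(
            volume.values, [coords[..., 0], coords[..., 1], coords[..., 2]],
            order=1, mode="constant", cval=0.0,
        )
    if centers_px is None:
        centers_px = np.array([slice_center(s) for s in slices])
    return ShortAxisStack(
        slices=slices, center_px=np.asarray(centers_px, float),
        slice_spacing_mm=pitch, pixel_mm=(pitch, pitch),
    )


def radial_max_profile(
    slice2d: np.ndarray,
    center_px,
    n_rays: int = 60,
    r_max_px: float | None = None,
    step_px: float = 0.5,
) -> np.ndarray:
    """Maximum of bilinearly interpolated values along each radial ray.

    Ray ``k`` points at angle ``2*pi*k/n_rays`` from the slice row axis
    (anterior), rotating towards the column axis; samples run from the
    centre out to ``r_max_px`` in sub-pixel steps.
    """
    s = np.asarray(slice2d, float)
    if n_rays < 8:
        raise ValueError("need at least 8 rays")
    c = np.asarray(center_px, float)
    if np.any(c < 0) or c[0] > s.shape[0] - 1 or c[1] > s.shape[1] - 1:
        raise ValueError("centre lies outside the slice")
    if r_max_px is None:
        r_max_px = min(c[0], c[1], s.shape[0] - 1 - c[0], s.shape[1] - 1 - c[1])
    if r_max_px <= 0:
        raise ValueError("r_max must be positive")
    radii = np.arange(0.0, r_max_px + step_px / 2, step_px)
    theta = 2.0 * np.pi * np.arange(n_rays) / n_rays
    ii = c[0] + radii[None, :] * np.cos(theta)[:, None]
    jj = c[1] + radii[None, :] * np.sin(theta)[:, None]
    samples = map_coordinates(s, [ii, jj], order=1, mode="constant", cval=0.0)
    return samples.max(axis=1)


def _ring_levels(n_rings: int) -> tuple[np.ndarray, int]:
    """Per-ring level (0 basal, 1 mid, 2 apical) and apex-cap ring count."""
    thirds = np.array_split(np.arange(n_rings), 3)
    levels = np.empty(n_rings, dtype=int)
    for lev, idx in enumerate(thirds):
        levels[idx] = lev
    cap_n = min(int(np.ceil(0.1 * n_rings)), len(thirds[2]))
    return levels, cap_n


def build_polar_map(
    stack: ShortAxisStack,
    n_rays: int = 60,
    r_max_px: float | None = None,
    display_ceiling: float = 4.0,
) -> PolarMap:
    """Arrange per-slice radial-maximum profiles concentrically."""
    n = stack.n_slices
    grid = np.stack([
        radial_max_profile(stack.slices[i], stack.center_px[i], n_rays, r_max_px)
        for i in range(n)
    ])
    angle_deg = 360.0 * np.arange(n_rays) / n_rays
    levels, cap_n = _ring_levels(n)
    level_names = {0: "basal", 1: "mid", 2: "apical"}
    seg = np.empty((n, n_rays), dtype=int)
    for i in range(n):
        seg[i] = sector_of(angle_deg, level_names[levels[i]])
    if cap_n > 0:
        seg[n - cap_n:, :] = 17
    return PolarMap(grid=grid, segment_of=seg, angle_deg=angle_deg,
                    display_ceiling=display_ceiling)


def segment_stats(pm: PolarMap, ddof: int = 0) -> SegmentStats:
    """Mean and SD of polar-map cells per AHA segment.

    The SD is the population SD (``ddof=0``) by default, treating the
    segment's cells as the full set of samples describing its dispersion;
    pass ``ddof=1`` for the sample convention.
    """
    mean = np.zeros(17)
    sd = np.zeros(17)
    n = np.zeros(17, dtype=int)
    for s in range(1, 18):
        cells = pm.grid[pm.segment_of == s]
        if cells.size == 0:
            raise ValueError(
                f"segment {s} has no polar-map cells (stack too short to "
                "populate all 17 segments)"
            )
        mean[s - 1] = cells.mean()
        sd[s - 1] = cells.std(ddof=ddof) if cells.size > ddof else 0.0
        n[s - 1] = cells.size
    return SegmentStats(mean_suv=mean, sd_suv=sd, n_cells=n)


def save_polar_map(pm: PolarMap, path: str | Path) -> None:
    np.savez(
        Path(path), grid=pm.grid, segment_of=pm.segment_of,
        angle_deg=pm.angle_deg, display_ceiling=np.array([pm.display_ceiling]),
    )


def load_polar_map(path: str | Path) -> PolarMap:
    with np.load(Path(path)) as z:
        return PolarMap(
            grid=z["grid"], segment_of=z["segment_of"], angle_deg=z["angle_deg"],
            display_ceiling=float(z["display_ceiling"][0]),
        )


def render_polar_map(pm: PolarMap, path: str | Path, title: str | None = None) -> None:
    """Write a bullseye PNG with the conventional SUV ceiling."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rings, n_rays = pm.grid.shape
    # base outermost: ring i spans radius [1 - (i+1)/n, 1 - i/n]
    theta_edges = np.linspace(0, 2 * np.pi, n_rays + 1)
    r_edges = 1.0 - np.arange(n_rings + 1) / n_rings
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    T, R = np.meshgrid(theta_edges, r_edges)
    ax.pcolormesh(T, R, pm.grid, vmin=0.0, vmax=pm.display_ceiling, cmap="inferno")
    ax.set_xticks([]), ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
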
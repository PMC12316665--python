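"""AHA 17-segment geometry shared by the phantom and the polar map.

Convention used throughout the package:

* The LV long axis points from base towards apex; the normalised long-axis
  position ``f`` runs from 0 at the base plane to 1 at the epicardial apex.
* In the short-axis plane the angle ``theta`` (degrees, [0, 360)) is measured
  from the anterior wall, increasing counterclockwise when viewed from the
  apex.
* Rings/levels: basal ``f < 1/3`` (segments 1-6), mid ``1/3 <= f < 2/3``
  (segments 7-12), apical ``f >= 2/3`` (segments 13-16), with the apex cap
  (segment 17) overriding the innermost portion.
* Basal and mid levels split into six 60-degree sectors with the anterior
  sector spanning [60, 120); apical level into four 90-degree sectors with
  the anterior sector spanning [45, 135).
"""

from __future__ import annotations

import numpy as np

#: Region definitions used by the heterogeneity indices.
REGIONS: dict[str, tuple[int, ...]] = {
    "anterior": (1, 7, 13),
    "septal": (2, 3, 8, 9, 14),
    "inferior": (4, 10, 15),
    "lateral": (5, 6, 11, 12, 16),
    "apical": (17,),  # apex segment in the five-region scheme
    "basal12": tuple(range(1, 13)),
    "apical5": (13, 14, 15, 16, 17),
    "all": tuple(range(1, 18)),
}

SEGMENT_NAMES = {
    1: "basal anterior", 2: "basal anteroseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal anterolateral",
    7: "mid anterior", 8: "mid anteroseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid anterolateral",
    13: "apical anterior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apex",
}


def sector_of(theta_deg: np.ndarray, level: str) -> np.ndarray:
    """Map angles (degrees from anterior, CCW from apex) to segment ids.

    ``level`` is one of ``"basal"``, ``"mid"``, ``"apical"``.
    """
    theta = np.asarray(theta_deg, dtype=float) % 360.0
    if level in ("basal", "mid"):
        # sextants: anterior [60,120), then anteroseptal, inferoseptal,
        # inferior, inferolateral; anterolateral wraps [0,60)
        idx = np.floor((theta - 60.0) % 360.0 / 60.0).astype(int)  # 0..5
        seg = idx + 1
        if level == "mid":
            seg = seg + 6
        return seg
    if level == "apical":
        idx = np.floor((theta - 45.0) % 360.0 / 90.0).astype(int)  # 0..3
        return idx + 13
    raise ValueError(f"unknown level {level!r}")


def level_of(f: np.ndarray) -> np.ndarray:
    """Long-axis thirds: 0 = basal, 1 = mid, 2 = apical for ``f`` in [0, 1]."""
    f = np.asarray(f, dtype=float)
    return np.minimum((f * 3).astype(int), 2)


def segment_of(f: np.ndarray, theta_deg: np.ndarray, apex_mask: np.ndarray | None = None) -> np.ndarray:
    """Segment id (1-17) from long-axis fraction and angle.

    ``apex_mask`` marks positions belonging to the solid apex cap
    (segment 17) regardless of angle.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    lev = level_of(f)
    seg = np.where(
        lev == 0, sector_of(theta, "basal"),
        np.where(lev == 1, sector_of(theta, "mid"), sector_of(theta, "apical")),
    )
    if apex_mask is not None:
        seg = np.where(np.atleast_1d(apex_mask), 17, seg)
    return seg
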
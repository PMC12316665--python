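"""Regional heterogeneity and burden indices from 17-segment statistics.

Working from the per-segment mean and SD of the polar map:

* ``Summed SUV_region`` — sum of segment mean SUVs over a named region
  (anterior 1/7/13, septal 2/3/8/9/14, inferior 4/10/15, lateral
  5/6/11/12/16, apical 17; alternatively basal 1-12 vs apical 13-17).
* ``total cardiac SUV`` — sum over all 17 segment means (disease burden).
* ``COV`` — sum over the 17 segments of within-segment SD / mean x 100
  (uptake heterogeneity / disease extent).
* ``%DS`` — (septal - lateral summed SUV) / total x 100 (septal
  predominance).
* ``%BA`` — (basal - apical summed SUV) / total x 100 (base-to-apex
  variability).  Note that a perfectly uniform heart has %BA = 700/17
  (about 41.2) because the basal region holds 12 segments and the apical
  region 5.

Indices operate on unweighted segment means, matching the summed-SUV
definition; cell counts do not enter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aha import REGIONS
from .polarmap import SegmentStats

#: Region aliases accepted by :func:`summed_region`.
_REGION_ALIASES = {
    "basal": "basal12",
    "apical5": "apical5",
    "apex": "apical",
    "all": "all",
}


@dataclass
class RegionalIndexSet:
    """Per-patient derived indices."""

    summed_suv: dict[str, float]
    total_cardiac_suv: float
    cov: float
    pct_ds: float
    pct_ba: float

    def as_row(self) -> dict[str, float]:
        """Flat dict for CSV export (2-decimal display is left to writers)."""
        row = {
            "total_cardiac_suv": self.total_cardiac_suv,
            "cov": self.cov,
            "pct_ds": self.pct_ds,
            "pct_ba": self.pct_ba,
        }
        for k, v in self.summed_suv.items():
            row[f"summed_{k}"] = v
        return row


def _region_segments(region: str) -> tuple[int, ...]:
    key = _REGION_ALIASES.get(region, region)
    try:
        return REGIONS[key]
    except KeyError:
        raise ValueError(f"unknown region {region!r}; valid: {sorted(REGIONS)}")


def summed_region(stats: SegmentStats, region: str) -> float:
    """Sum of segment mean SUVs over the named region."""
    segs = _region_segments(region)
    return float(sum(stats.mean_suv[s - 1] for s in segs))


def total_cov(stats: SegmentStats) -> float:
    """Sum of the 17 segmental COVs (SD/mean x 100)."""
    if np.any(stats.mean_suv <= 0):
        bad = int(np.argmax(stats.mean_suv <= 0)) + 1
        raise ZeroDivisionError(f"segment {bad} has nonpositive mean SUV")
    return float(np.sum(stats.sd_suv / stats.mean_suv) * 100.0)


def percent_ds(stats: SegmentStats) -> float:
    """(septal - lateral) / all x 100."""
    total = summed_region(stats, "all")
    if total == 0:
        raise ZeroDivisionError("total summed SUV is zero")
    return (summed_region(stats, "septal") - summed_region(stats, "lateral")) / total * 100.0


def percent_ba(stats: SegmentStats) -> float:
    """(basal - apical) / all x 100, basal = segments 1-12, apical = 13-17."""
    total = summed_region(stats, "all")
    if total == 0:
        raise ZeroDivisionError("total summed SUV is zero")
    return (summed_region(stats, "basal12") - summed_region(stats, "apical5")) / total * 100.0


def compute_indices(stats: SegmentStats) -> RegionalIndexSet:
    """All indices; the regional sums partition the total exactly."""
    summed = {name: summed_region(stats, name) for name in
              ("anterior", "septal", "inferior", "lateral", "apical", "basal12", "apical5")}
    return RegionalIndexSet(
        summed_suv=summed,
        total_cardiac_suv=summed_region(stats, "all"),
        cov=total_cov(stats),
        pct_ds=percent_ds(stats),
        pct_ba=percent_ba(stats),
    )
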
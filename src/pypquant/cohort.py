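"""Cohort tables: the packaged 20-patient ATTR-CM regional-index table,
derived heterogeneity indices, and the correlation matrix of the regional
indices against total cardiac SUV by genotype subset.

The packaged table lists, for each of the 20 biopsy-proven ATTR-CM patients
(15 wild-type, 5 hereditary-variant), the total cardiac SUV, the summed
COV, and the summed regional SUVs (basal, apical, septal, lateral), ordered
by ascending total cardiac SUV.  %DS and %BA are derivable from the printed
columns; the per-row identity basal + apical = total holds to the printed
2-decimal precision and is validated on load.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import pearson

log = logging.getLogger(__name__)

_TABLE2_SHA256 = "101fce411095e245bb1d54e3ea994b4dad39a30a71d19dac73df8b58e1587e89"

GROUPS = ("ATTRwt", "ATTRv", "AL", "non-amyloidosis")

#: Imaging-index columns of a cohort table.
INDEX_COLUMNS = ("cov", "pct_ds", "pct_ba", "total_cardiac_suv")

#: Optional echocardiographic columns.
ECHO_COLUMNS = ("awt", "rwt", "gls", "e_septal", "e_lateral", "e_over_eprime")


@dataclass
class Table2Fixture:
    """The packaged per-patient regional measurement table."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if len(df) != 20:
            raise ValueError("fixture must contain exactly 20 patients")
        counts = df["genotype"].value_counts()
        if counts.get("wt", 0) != 15 or counts.get("v", 0) != 5:
            raise ValueError("fixture must contain 15 wild-type and 5 variant rows")
        resid = (df["summed_basal"] + df["summed_apical"] - df["total_cardiac_suv"]).abs()
        if (resid > 0.02).any():
            raise ValueError("basal + apical does not reproduce total cardiac SUV")


def load_table2() -> Table2Fixture:
    """Load and validate the packaged fixture (checksum-verified)."""
    ref = resources.files("pypquant.data").joinpath("table2.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE2_SHA256:
        raise RuntimeError(
            f"packaged table2.csv failed its integrity check ({digest})"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    return Table2Fixture(frame=df)


def derive_table2_indices(fix: Table2Fixture) -> pd.DataFrame:
    """Cohort table with %DS and %BA derived from the printed columns."""
    df = fix.frame.copy()
    df.insert(0, "id", [f"attr{i+1:02d}" for i in range(len(df))])
    df["group"] = np.where(df["genotype"] == "wt", "ATTRwt", "ATTRv")
    df["pct_ds"] = (df["summed_septal"] - df["summed_lateral"]) / df["total_cardiac_suv"] * 100.0
    df["pct_ba"] = (df["summed_basal"] - df["summed_apical"]) / df["total_cardiac_suv"] * 100.0
    return df


def reproduce_table4(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and p) of COV/%DS/%BA against total cardiac SUV.

    Computed for the full ATTR cohort and for the wild-type-only and
    variant-only subsets; rows are (subset, index) with columns r, p, n.
    """
    subsets = {
        "ATTRwt+ATTRv": cohort,
        "ATTRwt only": cohort[cohort["group"] == "ATTRwt"],
        "ATTRv only": cohort[cohort["group"] == "ATTRv"],
    }
    rows = []
    for subset_name, sub in subsets.items():
        if len(sub) < 3:
            raise ValueError(f"subset {subset_name!r} has fewer than 3 patients")
        for index in ("cov", "pct_ds", "pct_ba"):
            res = pearson(sub[index].to_numpy(), sub["total_cardiac_suv"].to_numpy())
            rows.append({"subset": subset_name, "index": index,
                         "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path, header_note: str = "") -> None:
    """Write a cohort table as UTF-8 comma-separated CSV.

    ``header_note`` (e.g. seed and configuration hash) is stored in leading
    ``#`` comment lines so outputs are self-describing.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in header_note.splitlines():
            fh.write(f"# {line}\n")
        cohort.to_csv(fh, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "group" in df.columns:
        bad = set(df["group"].dropna()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
    return df
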
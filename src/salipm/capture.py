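"""Capture-history data: container, validation, and CSV round-trip.

The on-disk dialect is a plain CSV with one row per detection:

    id,site,occasion,month_offset,size_mm,eggs

``occasion`` is the within-site occasion index (0-based), ``month_offset``
the occasion's time in months from the study start (a multiple of 0.5), and
``eggs`` the egg count carried by a gravid female (empty when absent).
Seasons are derived per site by splitting the occasion times at the largest
gap (the summer break); within-season sizes are averaged per individual to
give the seasonal size covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CaptureData", "read_capture_csv", "ValidationError"]

REQUIRED_COLUMNS = ["id", "site", "occasion", "month_offset", "size_mm", "eggs"]

_GRID_TOL = 1e-6


class ValidationError(ValueError):
    """Raised with an itemized report when a capture table is malformed."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid capture data:\n- " + "\n- ".join(problems))


@dataclass
class CaptureData:
    """Detections of marked individuals across occasions, sites, and seasons.

    ``records`` holds one row per detection. ``season`` is derived on
    construction. Undetected occasions are implicit: an individual's history
    at its site is reconstructed from the site's occasion grid.
    """

    records: pd.DataFrame
    season_break: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        problems: list[str] = []
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError([f"missing columns: {missing}"])
        df = df.copy()
        df["occasion"] = df["occasion"].astype(int)
        df["month_offset"] = df["month_offset"].astype(float)
        df["size_mm"] = df["size_mm"].astype(float)
        df["eggs"] = pd.to_numeric(df["eggs"], errors="coerce")

        off = df["month_offset"].to_numpy()
        bad_grid = np.abs(off / 0.5 - np.round(off / 0.5)) > _GRID_TOL
        if bad_grid.any():
            problems.append(
                f"{int(bad_grid.sum())} record(s) with month_offset off the 0.5-month grid "
                f"(e.g. {off[bad_grid][0]})"
            )
        bad_size = ~np.isfinite(df["size_mm"].to_numpy()) | (df["size_mm"].to_numpy() <= 0)
        if bad_size.any():
            problems.append(f"{int(bad_size.sum())} record(s) with non-positive or missing size")
        big = df["size_mm"].to_numpy() >= 80
        if big.any():
            problems.append(f"{int(big.sum())} record(s) with size >= 80 mm (implausible SVL)")

        # occasion index must map one-to-one onto month_offset within a site
        for site, g in df.groupby("site", sort=False):
            tbl = g.drop_duplicates(["occasion"])[["occasion", "month_offset"]]
            m = g.merge(tbl, on="occasion", suffixes=("", "_ref"))
            if not np.allclose(m["month_offset"], m["month_offset_ref"]):
                problems.append(f"{site}: inconsistent occasion -> month_offset mapping")
                continue
            t = tbl.sort_values("occasion")["month_offset"].to_numpy()
            if np.any(np.diff(t) <= 0):
                problems.append(f"{site}: occasion times not strictly increasing")
        dup = df.duplicated(["id", "site", "occasion"])
        if dup.any():
            problems.append(f"{int(dup.sum())} duplicate (id, site, occasion) record(s)")
        if problems:
            raise ValidationError(problems)

        if not self.season_break:
            self.season_break = {}
            for site, g in df.groupby("site", sort=False):
                t = np.sort(g["month_offset"].unique())
                if len(t) >= 2:
                    self.season_break[site] = int(np.argmax(np.diff(t)) + 1)
                else:
                    self.season_break[site] = 1

        season = np.empty(len(df), dtype=int)
        for site, g in df.groupby("site", sort=False):
            t = np.sort(g["month_offset"].unique())
            brk = self.season_break[site]
            boundary = t[brk] if brk < len(t) else np.inf
            season[g.index] = np.where(g["month_offset"].to_numpy() < boundary, 1, 2)
        df["season"] = season
        self.records = df.sort_values(["site", "id", "occasion"]).reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.records.groupby(["site", "id"]).ngroups

    def occasion_times(self, site: str) -> np.ndarray:
        g = self.records[self.records["site"] == site]
        return np.sort(g["month_offset"].unique())

    def seasonal_sizes(self) -> pd.DataFrame:
        """Per (site, id, season) mean observed size — the size covariate."""
        out = (self.records.groupby(["site", "id", "season"], sort=False)["size_mm"]
               .mean().rename("size").reset_index())
        return out

    def egg_records(self) -> pd.DataFrame:
        """One egg count per (site, id, season), with the seasonal mean size."""
        g = self.records.dropna(subset=["eggs"])
        eggs = (g.groupby(["site", "id", "season"], sort=False)["eggs"]
                .mean().rename("eggs").reset_index())
        return eggs.merge(self.seasonal_sizes(), on=["site", "id", "season"])

    # ------------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        df = self.records[REQUIRED_COLUMNS].copy()
        df.to_csv(path, index=False, float_format="%.6g")

    def equals(self, other: "CaptureData") -> bool:
        a = self.records[REQUIRED_COLUMNS].reset_index(drop=True)
        b = other.records[REQUIRED_COLUMNS].reset_index(drop=True)
        if a.shape != b.shape:
            return False
        num = a.select_dtypes("number")
        return bool(
            np.allclose(num, b[num.columns], equal_nan=True)
            and (a["site"] == b["site"]).all() and (a["id"] == b["id"]).all()
        )


def read_capture_csv(path: str | Path) -> CaptureData:
    """Read and validate a capture-history CSV (see module docstring)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError([f"missing columns: {missing}"])
    return CaptureData(records=df)
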
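"""Reading, quality-screening, and regularizing GPS relocation data.

A relocation table has columns ``animal_id, timestamp, x, y, fix_dim,
hdop`` with hourly fixes in projected meters. Screening censors inaccurate
fixes by horizontal dilution of precision (HDOP), with separate thresholds
for 2D and 3D fixes; timestamps are snapped to the hourly schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningReport",
    "read_relocations",
    "write_relocations",
    "screen_relocations",
    "assign_season",
]

REQUIRED_COLUMNS = ["animal_id", "timestamp", "x", "y", "fix_dim", "hdop"]


@dataclass
class ScreeningReport:
    n_input: int
    removed_2d: int
    removed_3d: int
    removed_offschedule: int
    removed_duplicate: int

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.removed_2d - self.removed_3d
                - self.removed_offschedule - self.removed_duplicate)


def read_relocations(path) -> pd.DataFrame:
    """Read a relocation CSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"relocation CSV missing columns: {missing}")
    bad = []
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    for idx in df.index[ts.isna()]:
        bad.append(idx + 2)  # +2: header line + 1-based
    xy_ok = np.isfinite(df["x"]) & np.isfinite(df["y"])
    bad.extend((df.index[~xy_ok] + 2).tolist())
    if bad:
        raise ValueError(f"malformed relocation rows at lines {sorted(set(bad))}")
    df = df.assign(timestamp=ts)
    return df


def write_relocations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out[REQUIRED_COLUMNS].to_csv(path, index=False)


def screen_relocations(raw: pd.DataFrame, threshold_2d: float = 5.0,
                       threshold_3d: float = 6.0, retain_low_hdop: bool = True,
                       snap_tolerance_min: float = 5.0):
    """Screen relocations by HDOP and regularize to the hourly schedule.

    The default convention retains accurate fixes: a 2D fix is kept iff
    ``hdop < threshold_2d`` and a 3D fix iff ``hdop < threshold_3d``
    (censoring the inaccurate, high-HDOP fixes). Setting
    ``retain_low_hdop=False`` inverts the comparison and instead removes
    fixes *below* the thresholds.

    Timestamps within ``snap_tolerance_min`` minutes of the hour are
    snapped onto it; others are off-schedule and removed (step construction
    requires regular 1-h intervals). Duplicate timestamps keep the first
    fix.

    Returns ``(trajectory, report)`` with the input ordering preserved.
    """
    if threshold_2d <= 0 or threshold_3d <= 0:
        raise ValueError("thresholds must be positive")
    if raw.empty:
        empty = raw.copy()
        return empty, ScreeningReport(0, 0, 0, 0, 0)
    df = raw.copy()
    dim = df["fix_dim"].astype(str).str.upper()
    if not dim.isin(["2D", "3D"]).all():
        bad = sorted(set(dim[~dim.isin(["2D", "3D"])]))
        raise ValueError(f"unknown fix_dim value(s): {bad}")
    hdop = pd.to_numeric(df["hdop"])
    if (hdop <= 0).any():
        raise ValueError("nonpositive hdop")

    if retain_low_hdop:
        keep = np.where(dim == "2D", hdop < threshold_2d, hdop < threshold_3d)
    else:
        keep = np.where(dim == "2D", hdop >= threshold_2d, hdop >= threshold_3d)
    removed_2d = int(((~keep) & (dim == "2D")).sum())
    removed_3d = int(((~keep) & (dim == "3D")).sum())
    df = df[keep]

    ts = pd.to_datetime(df["timestamp"], utc=True)
    snapped = ts.dt.round("h")
    offset_min = (ts - snapped).abs().dt.total_seconds() / 60.0
    on_schedule = offset_min <= snap_tolerance_min
    removed_off = int((~on_schedule).sum())
    df = df[on_schedule].assign(timestamp=snapped[on_schedule])

    df = df.sort_values(["animal_id", "timestamp"], kind="stable")
    dup = df.duplicated(subset=["animal_id", "timestamp"])
    removed_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)
    report = ScreeningReport(len(raw), removed_2d, removed_3d, removed_off, removed_dup)
    return df, report


def assign_season(timestamp) -> str:
    """Season label by month: Mar–May spring, Jun–Aug summer, Sep–Nov fall,
    Dec–Feb winter."""
    month = pd.Timestamp(timestamp).month
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    if month in (9, 10, 11):
        return "fall"
    return "winter"
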
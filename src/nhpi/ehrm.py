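"""Detection and classification of extra-home-range movements (EHRMs).

A 30-day "pre-EHRM home range" window slides along each trajectory in
24-h increments, a BBMM 95% isopleth is fit to the window, and the fixes
in the 2 days immediately following are tested against it. An EHRM
candidate requires at least ``min_far`` fixes more than
``dist_threshold_m`` outside the isopleth and at least
``min_consecutive`` consecutive fixes outside it. Candidates are extended
forward until the animal re-enters the isopleth (excursion) or settles in
a new, spatially restricted area (dispersal); events still open at the end
of the data are labeled unresolved and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bbmm import HomeRangePolygon, compute_bbmm_ud, estimate_bm_variance, extract_isopleth
from .telemetry import assign_season

__all__ = ["EHRMEvent", "DetectorConfig", "detect_ehrms", "classify_ehrm", "summarize_ehrms"]


@dataclass
class EHRMEvent:
    animal_id: str
    kind: str  # "excursion" | "dispersal" | "unresolved"
    season: str
    start_index: int
    end_index: int
    window: tuple  # (window start, window end) timestamps of the pre-EHRM period
    pre_polygon: HomeRangePolygon
    max_distance_m: float = np.nan
    duration_h: float | None = None  # defaults to n_steps (gap-free hourly data)
    pre_indices: np.ndarray | None = None  # trajectory rows of the pre-EHRM window
    span_ts: tuple | None = None  # (first, last) timestamps of the event

    @property
    def n_fixes(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def n_steps(self) -> int:
        return self.n_fixes - 1


@dataclass
class DetectorConfig:
    hr_window_days: int = 30
    analysis_window_days: int = 2
    advance_hours: int = 24
    dist_threshold_m: float = 500.0
    min_consecutive: int = 4  # ">3 consecutive relocations outside"
    min_far: int = 2  # ">1 relocation >500 m outside"
    isopleth_level: float = 0.95
    completeness: float = 0.5  # fraction of expected hourly fixes in the window
    location_error_m: float = 20.0
    ud_cellsize_m: float = 30.0
    settle_window_h: float = 168.0
    settle_radius_m: float = 1000.0
    reentry_min_consecutive: int = 1


def _max_pairwise_spread_ok(xy: np.ndarray, limit: float) -> bool:
    """True iff the maximum pairwise distance is <= limit (bbox shortcuts)."""
    w = xy[:, 0].max() - xy[:, 0].min()
    h = xy[:, 1].max() - xy[:, 1].min()
    if np.hypot(w, h) <= limit:
        return True
    if max(w, h) > limit:
        return False
    from scipy.spatial import ConvexHull

    try:
        hull = xy[ConvexHull(xy).vertices]
    except Exception:  # degenerate (collinear) point sets
        hull = xy
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    return bool(np.sqrt(d2.max()) <= limit)


def classify_ehrm(start_index: int, xy: np.ndarray, t_hours: np.ndarray,
                  pre_polygon: HomeRangePolygon, settle_window_h: float = 168.0,
                  settle_radius_m: float = 1000.0,
                  reentry_min_consecutive: int = 1):
    """Classify the event beginning at ``start_index``.

    Returns ``(kind, end_index)``. Excursion: the first post-exit return
    inside the pre-EHRM polygon closes the event at the previous fix; a
    return requires ``reentry_min_consecutive`` consecutive inside fixes
    (raise above 1 to ignore single-fix clips of the isopleth edge by a
    passing animal). Dispersal: a fully observed ``settle_window_h`` run
    of fixes, all outside the polygon with maximum pairwise spread at
    most ``2 * settle_radius_m``, declares settlement; the event ends at
    the run's first fix. Settlement only counts if declared (run
    completed) before any re-entry. Otherwise the event is unresolved.
    """
    n = len(xy)
    inside = pre_polygon.contains_points(xy[start_index:, 0], xy[start_index:, 1])
    reentry = None
    run = 0
    for r, flag in enumerate(inside):
        run = run + 1 if flag else 0
        if run >= reentry_min_consecutive:
            reentry = start_index + r - reentry_min_consecutive + 1
            break
    reentry_time = t_hours[reentry] if reentry is not None else np.inf

    last = reentry if reentry is not None else n
    for j in range(start_index, last):
        declared_at = t_hours[j] + settle_window_h
        if declared_at > reentry_time or declared_at > t_hours[-1]:
            break
        in_run = np.nonzero(
            (t_hours >= t_hours[j]) & (t_hours < declared_at))[0]
        run = in_run[in_run >= start_index]
        if len(run) < 2:
            continue
        if inside[run - start_index].any():
            continue
        if _max_pairwise_spread_ok(xy[run], 2.0 * settle_radius_m):
            return "dispersal", j
    if reentry is not None:
        return "excursion", reentry - 1
    return "unresolved", n - 1


def detect_ehrms(traj: pd.DataFrame, config: DetectorConfig | None = None,
                 return_unresolved: bool = False):
    """Detect and classify EHRMs in one animal's screened trajectory.

    Fixes belonging to previously detected events are excluded from later
    pre-EHRM windows before the BBMM is fit. Window placements whose
    30-day segment holds fewer than ``completeness`` of the expected
    hourly fixes are skipped.
    """
    cfg = config or DetectorConfig()
    traj = traj.sort_values("timestamp").reset_index(drop=True)
    ts = pd.to_datetime(traj["timestamp"], utc=True)
    t_hours = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    xy = traj[["x", "y"]].to_numpy(dtype=float)
    animal = str(traj["animal_id"].iloc[0]) if "animal_id" in traj else ""
    n = len(traj)
    hr_h = cfg.hr_window_days * 24.0
    ana_h = cfg.analysis_window_days * 24.0
    if t_hours[-1] < hr_h + ana_h:
        raise ValueError("trajectory shorter than one window placement")

    in_event = np.zeros(n, dtype=bool)
    events: list[EHRMEvent] = []
    unresolved: list[EHRMEvent] = []

    w_start = 0.0
    while w_start + hr_h < t_hours[-1]:
        pre = np.nonzero((t_hours >= w_start) & (t_hours < w_start + hr_h)
                         & ~in_event)[0]
        ana = np.nonzero((t_hours >= w_start + hr_h)
                         & (t_hours < w_start + hr_h + ana_h) & ~in_event)[0]
        if len(pre) < cfg.completeness * hr_h or len(ana) == 0:
            w_start += cfg.advance_hours
            continue
        sigma2 = estimate_bm_variance(xy[pre], t_hours[pre], cfg.location_error_m)
        ud = compute_bbmm_ud(
            xy[pre], t_hours[pre], sigma2,
            location_error=cfg.location_error_m, cellsize=cfg.ud_cellsize_m,
        )
        poly = extract_isopleth(
            ud, cfg.isopleth_level,
            window=(ts.iloc[pre[0]], ts.iloc[pre[-1]]),
        )
        outside = ~poly.contains_points(xy[ana, 0], xy[ana, 1])
        if not outside.any():
            w_start += cfg.advance_hours
            continue
        dist_out = poly.distance_outside(xy[ana, 0], xy[ana, 1])
        far = dist_out > cfg.dist_threshold_m
        far_ok = int(far.sum()) >= cfg.min_far
        # the event starts at the first long-enough outside run that itself
        # reaches beyond the distance threshold; brief boundary runs
        # elsewhere in the window are not the movement the far fixes belong to
        start_rel = _first_long_run(outside, cfg.min_consecutive, must_include=far)
        if not far_ok or start_rel is None:
            w_start += cfg.advance_hours
            continue
        start_index = int(ana[start_rel])
        kind, end_index = classify_ehrm(
            start_index, xy, t_hours, poly,
            settle_window_h=cfg.settle_window_h,
            settle_radius_m=cfg.settle_radius_m,
            reentry_min_consecutive=cfg.reentry_min_consecutive,
        )
        in_event[start_index:end_index + 1] = True
        seg = xy[start_index:end_index + 1]
        event = EHRMEvent(
            animal_id=animal,
            kind=kind,
            season=assign_season(ts.iloc[start_index]),
            start_index=start_index,
            end_index=int(end_index),
            window=(ts.iloc[pre[0]], ts.iloc[pre[-1]]),
            pre_polygon=poly,
            max_distance_m=float(np.hypot(*(seg - seg[0]).T).max()),
            duration_h=float(t_hours[end_index] - t_hours[start_index]),
            pre_indices=pre.copy(),
            span_ts=(ts.iloc[start_index], ts.iloc[end_index]),
        )
        (events if kind != "unresolved" else unresolved).append(event)
        if kind == "dispersal":
            # residence has moved: restart the scan with the first
            # pre-EHRM window beginning at the settlement
            w_start = t_hours[end_index]
        else:
            # resume with the next analysis window starting right after
            # the event so no fix is skipped from analysis coverage
            w_start = max(w_start + cfg.advance_hours,
                          t_hours[end_index] + 1.0 - hr_h)
    if return_unresolved:
        return events, unresolved
    return events


def _first_long_run(outside: np.ndarray, min_len: int, must_include=None):
    """Start of the first maximal run of True with length >= min_len (and,
    if ``must_include`` is given, containing a True of that mask); None if
    there is none."""
    n = len(outside)
    i = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j < n and outside[j]:
            j += 1
        if j - i >= min_len and (
                must_include is None or must_include[i:j].any()):
            return i
        i = j
    return None


def _stats(v: np.ndarray) -> dict:
    v = np.asarray(v, dtype=float)
    se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return {
        "mean": float(v.mean()),
        "se": float(se),
        "min": float(v.min()),
        "max": float(v.max()),
        "median": float(np.median(v)),
    }


def summarize_ehrms(events) -> pd.DataFrame:
    """Descriptive summary per movement type (counts, steps, duration,
    maximum displacement, seasonal breakdown)."""
    if not events:
        raise ValueError("no events to summarize")
    rows = []
    for kind in sorted({e.kind for e in events}):
        evs = [e for e in events if e.kind == kind]
        steps = np.array([e.n_steps for e in evs])
        dur = np.array([
            float(e.n_steps) if e.duration_h is None else e.duration_h for e in evs
        ])
        dist = np.array([e.max_distance_m for e in evs])
        row = {"kind": kind, "n_events": len(evs),
               "n_animals": len({e.animal_id for e in evs})}
        row.update({f"steps_{k}": v for k, v in _stats(steps).items()})
        row.update({f"duration_h_{k}": v for k, v in _stats(dur).items()})
        row.update({f"max_dist_m_{k}": v for k, v in _stats(dist).items()})
        for season in ("spring", "summer", "fall", "winter"):
            row[f"n_{season}"] = sum(e.season == season for e in evs)
        rows.append(row)
    return pd.DataFrame(rows)
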
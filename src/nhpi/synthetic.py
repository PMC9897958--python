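"""Synthetic landscapes, GPS trajectories, and step-selection data.

Everything downstream (home-range estimation, movement detection, covariate
attribution, model fitting) is exercised against data generated here, where
the ground truth — planted movements and true selection coefficients — is
known exactly.

Land-cover class codes (7 classes, mirroring a reclassified land-cover
product): 1 open water, 2 wetland, 3 forest, 4 agriculture, 5 open
(grass/shrub/pasture), 6 developed, 7 other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Raster

__all__ = [
    "CLASS_NAMES",
    "LandscapeConfig",
    "TrackConfig",
    "PlantedEvent",
    "SimTruth",
    "generate_landscape",
    "generate_linear_feature",
    "simulate_track",
    "simulate_ssf_steps",
]

CLASS_NAMES = {
    1: "open water",
    2: "wetland",
    3: "forest",
    4: "agriculture",
    5: "open",
    6: "developed",
    7: "other",
}


@dataclass
class LandscapeConfig:
    """Configuration for the patch-mosaic landscape generator."""

    extent_cells: int = 200
    resolution: float = 30.0
    class_proportions: tuple = (0.05, 0.10, 0.18, 0.45, 0.18, 0.03, 0.01)
    clumping: float = 0.5
    gradient: float = 0.0  # strength of large-scale compositional trends
    gradient_scale: float = 0.2  # trend field correlation length, fraction of extent
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (7,) or np.any(p < 0):
            raise ValueError("class_proportions must be 7 nonnegative fractions")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if not (0 <= self.clumping < 1):
            raise ValueError("clumping must be in [0, 1)")
        if self.extent_cells < 50:
            raise ValueError("extent must be at least 50 cells per side")


def generate_landscape(config: LandscapeConfig) -> Raster:
    """Generate a categorical patch-mosaic raster.

    Modified-random-clusters style: a percolation mask at density
    ``clumping`` is labelled into 4-connected clusters, clusters are
    assigned whole to classes chasing the target composition, and the
    remaining cells take the class of the nearest assigned cell. With
    ``clumping = 0`` cells are drawn independently (no spatial structure).

    ``gradient > 0`` modulates cluster-to-class assignment with smooth
    per-class random fields, producing regional compositional trends
    (forest-rich vs. crop-dominated districts) while the deficit-chasing
    assignment keeps the global composition near the target. Regional
    trends are what make individual home ranges differ in habitat
    character, which the individual-vs-pooled dissimilarity contrast
    needs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.extent_cells
    props = np.asarray(config.class_proportions, dtype=float)
    classes = np.arange(1, 8)

    if config.clumping == 0:
        values = rng.choice(classes, size=(n, n), p=props)
        return Raster(values.astype(np.int16), 0.0, 0.0, config.resolution)

    mask = rng.random((n, n)) < config.clumping
    labels, n_clusters = ndimage.label(mask)  # rook connectivity
    values = np.zeros((n, n), dtype=np.int16)
    if n_clusters > 0:
        sizes = np.bincount(labels.ravel())[1:]
        order = rng.permutation(n_clusters)
        target = props * mask.sum()
        assigned = np.zeros(7)
        cluster_class = np.zeros(n_clusters + 1, dtype=np.int16)
        if config.gradient > 0:
            s = config.gradient_scale * n
            fields = ndimage.gaussian_filter(
                rng.standard_normal((7, n, n)), sigma=(0, s, s))
            fields /= fields.std(axis=(1, 2), keepdims=True)
            # one representative cell per cluster
            flat = labels.ravel()
            first = np.full(n_clusters + 1, -1, dtype=int)
            seen = np.unique(flat, return_index=True)
            first[seen[0]] = seen[1]
        for lab in order + 1:
            deficit = np.maximum(target - assigned, 0.0)
            prob = deficit / deficit.sum() if deficit.sum() > 0 else props.copy()
            if config.gradient > 0:
                ci, cj = divmod(first[lab], n)
                prob = prob * np.exp(config.gradient * fields[:, ci, cj])
                prob = prob / prob.sum()
            c = rng.choice(7, p=prob)
            cluster_class[lab] = c + 1
            assigned[c] += sizes[lab - 1]
        values = cluster_class[labels]

    # fill unassigned cells from the nearest assigned cell
    unassigned = values == 0
    if unassigned.any():
        if (~unassigned).any():
            _, (ri, ci) = ndimage.distance_transform_edt(
                unassigned, return_indices=True
            )
            values = values[ri, ci]
        else:
            values = rng.choice(classes, size=(n, n), p=props).astype(np.int16)

    # guarantee presence of every configured class
    for c in classes[props > 0]:
        if not np.any(values == c):
            values[rng.integers(n), rng.integers(n)] = c
    return Raster(values, 0.0, 0.0, config.resolution)


def generate_linear_feature(landscape: Raster, seed: int, step_m: float = 200.0,
                            wander_sd: float = 0.35) -> np.ndarray:
    """A random-walk polyline crossing the extent (synthetic stream or road).

    Returns an (n, 2) vertex array. Starts on the west edge at a random
    northing and wanders eastward until it leaves the extent.
    """
    rng = np.random.default_rng(seed)
    x = landscape.xmin
    y = rng.uniform(landscape.ymin, landscape.ymax)
    heading = rng.normal(0.0, 0.2)  # roughly eastward
    pts = [(x, y)]
    while True:
        heading += rng.normal(0.0, wander_sd)
        heading = float(np.clip(heading, -1.2, 1.2))
        x += step_m * np.cos(heading)
        y += step_m * np.sin(heading)
        pts.append((x, y))
        if not (landscape.xmin <= x <= landscape.xmax and
                landscape.ymin <= y <= landscape.ymax):
            break
    return np.asarray(pts)


@dataclass
class PlantedEvent:
    """A planted extra-home-range movement."""

    kind: str  # "excursion" | "dispersal"
    start_index: int
    distance_m: float = 2500.0
    dwell_h: int = 8
    speed_m_per_h: float = 450.0
    bearing: float | None = None  # radians; None -> drawn at random
    kappa: float = 2.0  # von Mises concentration of travel-step proposals
    direction_weight: float | None = None  # waypoint pull; None -> TrackConfig's


@dataclass
class SimTruth:
    """Ground truth attached to a simulated trajectory or step design."""

    planted_events: list = field(default_factory=list)  # (kind, start, end)
    true_beta: np.ndarray | None = None
    kernel_params: dict | None = None
    hr_center: tuple | None = None
    hr_sigma: float | None = None
    settle_center: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "planted_events": [
                {"kind": k, "start_index": int(s), "end_index": int(e)}
                for k, s, e in self.planted_events
            ],
            "true_beta": None if self.true_beta is None else list(map(float, self.true_beta)),
            "kernel_params": self.kernel_params,
            "hr_center": None if self.hr_center is None else list(map(float, self.hr_center)),
            "hr_sigma": self.hr_sigma,
            "settle_center": None if self.settle_center is None
            else list(map(float, self.settle_center)),
        }


@dataclass
class TrackConfig:
    """Configuration for the trajectory simulator.

    Resident movement is a discrete-time mean-reverting (OU-like) walk:
    hourly steps pull back toward the current home-range center with rate
    ``theta`` and Gaussian noise scaled so the stationary spread is
    ``hr_sigma`` meters. The walk is reflected at ``range_limit_sigma``
    standard deviations from the center — home ranges have finite extent,
    and an unbounded Gaussian tail would let rare multi-hour forays mimic
    genuine extra-home-range movements.
    """

    hr_center: tuple = (3000.0, 3000.0)
    hr_sigma: float = 250.0
    theta: float = 0.15
    range_limit_sigma: float = 2.5
    travel_direction_weight: float = 0.8  # waypoint attraction in the travel SSF
    emigration_radius_m: float = 700.0  # decisive departure zone around the origin
    emigration_direction_weight: float = 1.4
    travel_max_h: int = 200  # failsafe: settle / turn back after this long
    n_fixes: int = 24 * 40
    start_time: str = "2012-06-01T00:00:00"
    animal_id: str = "deer01"
    events: list = field(default_factory=list)
    poor_fix_fraction: float = 0.05
    seed: int = 0


def _ou_step(rng, xy, center, theta, step_sd):
    drift = theta * (np.asarray(center) - xy)
    return xy + drift + rng.normal(0.0, step_sd, size=2)


def simulate_track(landscape: Raster | None, config: TrackConfig,
                   step_chooser=None, chooser_candidates: int = 20):
    """Simulate an hourly GPS trajectory with planted EHRMs.

    Parameters
    ----------
    landscape : Raster or None
        If given, travel waypoints are kept inside its extent.
    config : TrackConfig
    step_chooser : callable, optional
        ``f(endpoints (k,2) array, event_kind) -> utility vector``. When
        given, travel steps follow a step-selection process built on the
        same structure the analysis fits: ``chooser_candidates``
        candidates are proposed from a movement kernel around the
        *previous bearing* (von Mises concentration ``PlantedEvent.kappa``,
        gamma lengths), and one is used with probability proportional to
        ``exp(direction_weight * cos(angle to waypoint) + utility)``.
        Habitat selection (e.g. avoidance of natal-dissimilar habitat) is
        planted through the utility and can differ between excursions and
        dispersals; the waypoint attraction lives in the utility, not the
        proposal, so the generating availability matches what a fitted
        kernel describes. When None, travel is a plain biased walk toward
        the waypoint (fast, deterministic-shaped events for detector
        tests).

    Returns
    -------
    (DataFrame, SimTruth)
        Relocation table with columns animal_id, timestamp, x, y, fix_dim,
        hdop; and the planted-event ledger.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fixes
    if n < 24 * 35:
        raise ValueError("need at least 35 days of hourly fixes")
    theta = config.theta
    step_sd = config.hr_sigma * np.sqrt(1.0 - (1.0 - theta) ** 2)

    events = sorted(config.events, key=lambda e: e.start_index)
    starts = [e.start_index for e in events]
    if any(s2 - s1 < 24 for s1, s2 in zip(starts, starts[1:])):
        raise ValueError("planted events must start at least 24 h apart")

    center = np.asarray(config.hr_center, dtype=float)
    xy = center + rng.normal(0.0, config.hr_sigma, size=2)
    positions = np.zeros((n, 2))
    truth = SimTruth(hr_center=tuple(config.hr_center), hr_sigma=config.hr_sigma)

    mode = "resident"
    event = None
    event_i = 0
    waypoint = None
    dwell_left = 0
    event_start = None
    travel_h = 0
    prev_bearing = np.nan

    def _travel_step(xy, target, speed, kappa, kind, prev_bearing, dir_w,
                     origin=None):
        to_target = np.arctan2(target[1] - xy[1], target[0] - xy[0])
        if step_chooser is None:
            ang = to_target + rng.vonmises(0.0, kappa)
            length = rng.gamma(4.0, speed / 4.0)
            return xy + length * np.array([np.cos(ang), np.sin(ang)])
        base = prev_bearing if np.isfinite(prev_bearing) else to_target
        angs = base + rng.vonmises(0.0, kappa, size=chooser_candidates)
        lens = rng.gamma(2.0, speed / 2.0, size=chooser_candidates)
        cand = xy + np.column_stack([lens * np.cos(angs), lens * np.sin(angs)])
        if landscape is not None:
            inside = landscape.contains(cand[:, 0], cand[:, 1])
            if inside.any():
                cand, angs = cand[inside], angs[inside]
        if dir_w is None:
            dir_w = config.travel_direction_weight
        if (origin is not None
                and np.hypot(*(xy - origin)) < config.emigration_radius_m):
            # departures (outbound only) are decisive near the origin: a
            # hesitant disperser dipping back into the old range would read
            # as a return, and the decisive exit mirrors the aligned
            # homeward approach of returning excursions
            dir_w = max(dir_w, config.emigration_direction_weight)
        util = dir_w * np.cos(angs - to_target)
        util = util + np.asarray(step_chooser(cand, kind), dtype=float)
        util = util - util.max()
        p = np.exp(util)
        p /= p.sum()
        return cand[rng.choice(len(cand), p=p)]

    for i in range(n):
        if event_i < len(events) and i == events[event_i].start_index:
            event = events[event_i]
            event_i += 1
            event_start = i
            mode = "outbound"
            brg = event.bearing if event.bearing is not None else rng.uniform(0, 2 * np.pi)
            waypoint = center + event.distance_m * np.array([np.cos(brg), np.sin(brg)])
            if landscape is not None:
                pad = 200.0
                waypoint[0] = np.clip(waypoint[0], landscape.xmin + pad, landscape.xmax - pad)
                waypoint[1] = np.clip(waypoint[1], landscape.ymin + pad, landscape.ymax - pad)
                if np.hypot(*(waypoint - center)) < event.distance_m * 0.8:
                    # re-aim through the middle of the extent
                    mid = np.array([(landscape.xmin + landscape.xmax) / 2,
                                    (landscape.ymin + landscape.ymax) / 2])
                    d = mid - center
                    d = d / max(np.hypot(*d), 1.0)
                    waypoint = center + event.distance_m * d
                    waypoint[0] = np.clip(waypoint[0], landscape.xmin + pad,
                                          landscape.xmax - pad)
                    waypoint[1] = np.clip(waypoint[1], landscape.ymin + pad,
                                          landscape.ymax - pad)
                    if np.hypot(*(waypoint - center)) < event.distance_m * 0.8:
                        raise ValueError(
                            "landscape too small to place the planted event")
            dwell_left = event.dwell_h
            travel_h = 0
            event_origin = xy.copy()

        if mode == "resident":
            xy = _ou_step(rng, xy, center, theta, step_sd)
            r = float(np.hypot(*(xy - center)))
            r_max = config.range_limit_sigma * config.hr_sigma
            if r > r_max:  # radial reflection at the home-range boundary
                xy = center + (xy - center) * (2 * r_max - r) / r
        elif mode == "outbound":
            xy = _travel_step(xy, waypoint, event.speed_m_per_h, event.kappa,
                              event.kind, prev_bearing, event.direction_weight,
                              origin=event_origin)
            travel_h += 1
            arrived = np.hypot(*(xy - waypoint)) < 1.5 * event.speed_m_per_h
            timed_out = travel_h >= config.travel_max_h
            if arrived or timed_out:
                if event.kind == "dispersal":
                    center = waypoint.copy() if arrived else xy.copy()
                    truth.settle_center = tuple(center)
                    truth.planted_events.append(("dispersal", event_start, i))
                    mode = "resident"
                    event = None
                else:
                    mode = "dwell" if arrived else "inbound"
                    waypoint = waypoint if arrived else center
        elif mode == "dwell":
            xy = _ou_step(rng, xy, waypoint, theta, step_sd * 0.7)
            dwell_left -= 1
            if dwell_left <= 0:
                mode = "inbound"
                travel_h = 0
        elif mode == "inbound":
            xy = _travel_step(xy, center, event.speed_m_per_h, event.kappa,
                              event.kind, prev_bearing, event.direction_weight)
            travel_h += 1
            if np.hypot(*(xy - center)) < 2.0 * config.hr_sigma:
                truth.planted_events.append(("excursion", event_start, i))
                mode = "resident"
                event = None
        if i > 0:
            d = xy - positions[i - 1]
            if np.hypot(*d) > 1e-9:
                prev_bearing = float(np.arctan2(d[1], d[0]))
        positions[i] = xy

    if event is not None:  # ran out of fixes mid-event
        truth.planted_events.append((event.kind + "_truncated", event_start, n - 1))

    times = pd.date_range(config.start_time, periods=n, freq="h", tz="UTC")
    hdop = rng.uniform(0.5, 4.0, size=n).round(1)
    poor = rng.random(n) < config.poor_fix_fraction
    hdop[poor] = rng.uniform(7.0, 12.0, size=poor.sum()).round(1)
    fix_dim = np.where(rng.random(n) < 0.5, "2D", "3D")
    traj = pd.DataFrame(
        {
            "animal_id": config.animal_id,
            "timestamp": times,
            "x": positions[:, 0],
            "y": positions[:, 1],
            "fix_dim": fix_dim,
            "hdop": hdop,
        }
    )
    return traj, truth


def simulate_ssf_steps(true_beta, kernel, covariates, n_strata: int, J: int,
                       seed: int, extent: Raster | None = None):
    """Generate step-selection strata with a known coefficient vector.

    For each stratum, ``J + 1`` candidate steps are proposed from the
    movement kernel (gamma step lengths, von Mises turn angles) around a
    shared start point, covariates are evaluated at the candidate
    endpoints, and the used step is drawn with probability proportional to
    ``exp(beta . x)`` — the relative-intensity model the estimator assumes.

    Parameters
    ----------
    true_beta : sequence of float
        One coefficient per covariate.
    kernel : MovementKernel or tuple (shape, scale, mu, kappa)
    covariates : dict name -> (Raster | callable(x, y) -> values)
    extent : Raster, optional
        If given, candidate endpoints falling off this raster are rejected
        and resampled (up to 100 attempts each).

    Returns
    -------
    (DataFrame, SimTruth)
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    rng = np.random.default_rng(seed)
    beta = np.asarray(true_beta, dtype=float)
    names = list(covariates)
    if beta.shape != (len(names),):
        raise ValueError("true_beta length must match number of covariates")
    try:
        shape, scale, mu, kappa = (kernel.shape, kernel.scale, kernel.mu, kernel.kappa)
    except AttributeError:
        shape, scale, mu, kappa = kernel

    if extent is not None:
        lo = np.array([extent.xmin, extent.ymin]) + 0.25 * np.array(
            [extent.xmax - extent.xmin, extent.ymax - extent.ymin])
        hi = np.array([extent.xmax, extent.ymax]) - 0.25 * np.array(
            [extent.xmax - extent.xmin, extent.ymax - extent.ymin])
    else:
        lo, hi = np.zeros(2), np.full(2, 1e4)

    def cov_at(pts):
        cols = {}
        for nm, c in covariates.items():
            if isinstance(c, Raster):
                cols[nm] = np.asarray(c.sample(pts[:, 0], pts[:, 1]), dtype=float)
            else:
                cols[nm] = np.asarray(c(pts[:, 0], pts[:, 1]), dtype=float)
        return cols

    rows = []
    for s in range(n_strata):
        start = rng.uniform(lo, hi)
        prev_bearing = rng.uniform(-np.pi, np.pi)
        k = J + 1
        lens = rng.gamma(shape, scale, size=k)
        turns = rng.vonmises(mu, kappa, size=k)
        angs = prev_bearing + turns
        ends = start + np.column_stack([lens * np.cos(angs), lens * np.sin(angs)])
        if extent is not None:
            for j in range(k):
                attempts = 0
                while not extent.contains(ends[j, 0], ends[j, 1]):
                    attempts += 1
                    if attempts > 100:
                        raise RuntimeError("off-raster resampling limit exhausted")
                    ln = rng.gamma(shape, scale)
                    an = prev_bearing + rng.vonmises(mu, kappa)
                    ends[j] = start + [ln * np.cos(an), ln * np.sin(an)]
                    lens[j], turns[j] = ln, an - prev_bearing
        covs = cov_at(ends)
        x = np.column_stack([covs[nm] for nm in names])
        eta = x @ beta
        eta -= eta.max()
        p = np.exp(eta)
        p /= p.sum()
        used = rng.choice(k, p=p)
        for j in range(k):
            rows.append(
                {
                    "stratum": s,
                    "case": int(j == used),
                    "x_start": start[0],
                    "y_start": start[1],
                    "x_end": ends[j, 0],
                    "y_end": ends[j, 1],
                    "step_length": lens[j],
                    "turn_angle": turns[j],
                    **{nm: covs[nm][j] for nm in names},
                }
            )
    design = pd.DataFrame(rows)
    truth = SimTruth(
        true_beta=beta,
        kernel_params={"shape": shape, "scale": scale, "mu": mu, "kappa": kappa},
    )
    return design, truth
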
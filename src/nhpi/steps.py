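"""Empirical movement kernel and matched random (available) steps.

EHRM steps pooled across individuals define the kernel: a gamma
distribution of hourly step lengths and a von Mises distribution of turn
angles. Each used step is matched with J random steps sharing its start
point, drawn from the kernel relative to the previous bearing — the
"available" sample the conditional-logistic step-selection function
conditions on.

Turn-angle convention: angle between successive displacement vectors,
counterclockwise positive, in (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Raster

__all__ = ["MovementKernel", "steps_from_trajectory", "fit_movement_kernel",
           "generate_random_steps"]

MIN_STEP_LENGTH_M = 1.0


@dataclass
class MovementKernel:
    shape: float  # gamma shape (step length)
    scale: float  # gamma scale, meters
    mu: float  # von Mises mean turn angle, radians
    kappa: float  # von Mises concentration

    def validate(self) -> None:
        if self.shape <= 0 or self.scale <= 0 or self.kappa <= 0:
            raise ValueError("gamma and von Mises parameters must be positive")
        if not (-np.pi < self.mu <= np.pi):
            raise ValueError("mean turn angle must be in (-pi, pi]")

    @property
    def mean_step_m(self) -> float:
        return self.shape * self.scale


def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)
    return out


def steps_from_trajectory(traj: pd.DataFrame, start: int | None = None,
                          end: int | None = None,
                          interval_h: float = 1.0) -> pd.DataFrame:
    """Regular steps (consecutive-fix displacements) from a trajectory.

    Steps spanning a gap (interval other than ``interval_h``) are
    excluded. ``bearing_prev`` is the absolute bearing of the preceding
    regular step (NaN if unavailable), so the first usable step of a
    segment keeps directional context from what came before it.
    """
    traj = traj.reset_index(drop=True)
    ts = pd.to_datetime(traj["timestamp"], utc=True)
    t_h = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    xy = traj[["x", "y"]].to_numpy(dtype=float)
    d = np.diff(xy, axis=0)
    dt = np.diff(t_h)
    bearing = np.arctan2(d[:, 1], d[:, 0])
    length = np.hypot(d[:, 0], d[:, 1])
    regular = np.isclose(dt, interval_h)
    prev_bearing = np.concatenate([[np.nan], bearing[:-1]])
    prev_regular = np.concatenate([[False], regular[:-1]])
    prev_bearing[~prev_regular] = np.nan
    turn = wrap_angle(bearing - prev_bearing)
    steps = pd.DataFrame(
        {
            "index_start": np.arange(len(d)),
            "x_start": xy[:-1, 0],
            "y_start": xy[:-1, 1],
            "x_end": xy[1:, 0],
            "y_end": xy[1:, 1],
            "step_length": length,
            "bearing": bearing,
            "bearing_prev": prev_bearing,
            "turn_angle": turn,
        }
    )
    steps = steps[regular]
    if start is not None or end is not None:
        s = start if start is not None else 0
        e = end if end is not None else len(traj) - 1
        steps = steps[(steps["index_start"] >= s) & (steps["index_start"] < e)]
    return steps.reset_index(drop=True)


def fit_movement_kernel(steps: pd.DataFrame, min_steps: int = 30) -> MovementKernel:
    """Maximum-likelihood gamma (lengths) and von Mises (turn angles) fit.

    Lengths below 1 m are floored at 1 m before fitting; steps without a
    defined turn angle are used for the gamma fit only.
    """
    lengths = np.maximum(steps["step_length"].to_numpy(dtype=float), MIN_STEP_LENGTH_M)
    turns = steps["turn_angle"].to_numpy(dtype=float)
    turns = turns[np.isfinite(turns)]
    if len(turns) < min_steps:
        raise ValueError(f"need >= {min_steps} steps with defined turn angles")
    if np.ptp(lengths) == 0:
        raise ValueError("all step lengths identical: degenerate gamma MLE")
    shape, _, scale = stats.gamma.fit(lengths, floc=0.0)
    kappa, mu, _ = stats.vonmises.fit(turns, fscale=1.0)
    mu = float(wrap_angle(mu))
    return MovementKernel(shape=float(shape), scale=float(scale),
                          mu=mu, kappa=float(kappa))


def generate_random_steps(used_step: pd.Series, previous_bearing: float,
                          kernel: MovementKernel, J: int = 50, seed: int = 0,
                          extent: Raster | None = None,
                          rng: np.random.Generator | None = None):
    """One stratum: the used step plus J random steps from its start point.

    Random endpoints are start + length * (cos a, sin a) with length ~
    gamma, turn ~ von Mises, absolute bearing a = previous_bearing + turn.
    If ``previous_bearing`` is NaN it is drawn uniformly. Endpoints off
    the ``extent`` raster are resampled up to 100 times each; a stratum
    where more than J/2 candidates exhaust the limit raises.

    Returns ``(DataFrame, flagged)`` where ``flagged`` counts candidates
    that hit the resampling limit (kept at their last draw).
    """
    kernel.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    if not np.isfinite(previous_bearing):
        previous_bearing = rng.uniform(-np.pi, np.pi)
    start = np.array([used_step["x_start"], used_step["y_start"]], dtype=float)
    rows = [
        {
            "case": 1,
            "x_start": start[0],
            "y_start": start[1],
            "x_end": float(used_step["x_end"]),
            "y_end": float(used_step["y_end"]),
            "step_length": float(used_step["step_length"]),
            "turn_angle": float(
                wrap_angle(np.arctan2(used_step["y_end"] - start[1],
                                      used_step["x_end"] - start[0])
                           - previous_bearing)),
        }
    ]
    flagged = 0
    for _ in range(J):
        attempts = 0
        while True:
            length = rng.gamma(kernel.shape, kernel.scale)
            turn = rng.vonmises(kernel.mu, kernel.kappa)
            ang = previous_bearing + turn
            end = start + length * np.array([np.cos(ang), np.sin(ang)])
            attempts += 1
            if extent is None or extent.contains(end[0], end[1]):
                break
            if attempts > 100:
                flagged += 1
                break
        rows.append(
            {
                "case": 0,
                "x_start": start[0],
                "y_start": start[1],
                "x_end": end[0],
                "y_end": end[1],
                "step_length": float(length),
                "turn_angle": float(wrap_angle(turn)),
            }
        )
    if flagged > J / 2:
        raise RuntimeError("off-raster resampling limit exhausted for most candidates")
    return pd.DataFrame(rows), flagged
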
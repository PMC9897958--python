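"""Natal-habitat dissimilarity: reference distributions and Mahalanobis D².

For each movement, the relocations of its 30-day pre-EHRM window (minus
any earlier EHRM fixes) define a reference distribution of the seven
landscape metrics at a given grain: mean vector ``mu`` and sample
covariance ``C``. The squared Mahalanobis distance

    D2(x) = (x - mu)' C^{-1} (x - mu)

measures how dissimilar a location's landscape-metric vector ``x`` is
from that reference. Two scopes are used: IND (one movement's own
pre-EHRM relocations) and ALL (every animal's pre-EHRM relocations
pooled). Near-collinear metrics can make ``C`` ill-conditioned, in which
case an escalating ridge is added before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES

__all__ = ["ReferenceDistribution", "build_reference", "mahalanobis_d2",
           "dissimilarity_profile"]

MIN_REFERENCE_N = 30
CONDITION_LIMIT = 1e8


@dataclass
class ReferenceDistribution:
    scope: str  # "IND" | "ALL"
    grain_m: float
    mu: np.ndarray
    cov: np.ndarray
    cov_inv: np.ndarray
    n: int
    excluded_count: int = 0
    ridge: float = 0.0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "grain_m": self.grain_m,
            "metrics": METRIC_NAMES,
            "mu": self.mu.tolist(),
            "cov": self.cov.tolist(),
            "n": self.n,
            "excluded_count": self.excluded_count,
            "ridge": self.ridge,
            "degenerate": self.degenerate,
        }


def build_reference(metric_rows: pd.DataFrame, grain_m: float, scope: str = "IND",
                    exclude_mask=None) -> ReferenceDistribution:
    """Reference distribution from metric values at reference relocations.

    ``metric_rows`` holds one row per relocation with the seven metric
    columns. Rows under ``exclude_mask`` (e.g. fixes of earlier EHRMs) and
    rows with undefined metrics (NaN, notably IJI in near-uniform windows)
    are dropped and counted.
    """
    cols = [c for c in METRIC_NAMES if c in metric_rows.columns]
    if len(cols) != len(METRIC_NAMES):
        missing = set(METRIC_NAMES) - set(cols)
        raise ValueError(f"metric columns missing: {sorted(missing)}")
    rows = metric_rows[METRIC_NAMES]
    n_in = len(rows)
    if exclude_mask is not None:
        rows = rows[~np.asarray(exclude_mask, dtype=bool)]
    rows = rows.dropna()
    excluded = n_in - len(rows)
    if len(rows) < MIN_REFERENCE_N:
        raise ValueError(
            f"reference needs >= {MIN_REFERENCE_N} usable relocations, "
            f"got {len(rows)}")
    x = rows.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)

    degenerate = bool(np.any(np.diag(cov) <= 0))
    ridge = 0.0
    cov_reg = cov
    lam = 1e-6 * np.trace(cov) / cov.shape[0]
    if lam <= 0:
        lam = 1e-12
    while np.linalg.cond(cov_reg) > CONDITION_LIMIT:
        ridge = lam
        cov_reg = cov + ridge * np.eye(cov.shape[0])
        lam *= 10.0
        degenerate = True if ridge > 0 and np.linalg.cond(cov) > 1e12 else degenerate
    cov_inv = np.linalg.inv(cov_reg)
    return ReferenceDistribution(
        scope=scope, grain_m=grain_m, mu=mu, cov=cov, cov_inv=cov_inv,
        n=len(rows), excluded_count=excluded, ridge=ridge, degenerate=degenerate,
    )


def mahalanobis_d2(x, ref: ReferenceDistribution) -> np.ndarray | float:
    """Squared Mahalanobis distance of observation vector(s) from the
    reference; vectorized over rows of a 2-D input."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != ref.mu.shape[0]:
        raise ValueError("dimension mismatch with reference")
    d = x2 - ref.mu
    d2 = np.einsum("ij,jk,ik->i", d, ref.cov_inv, d)
    d2 = np.maximum(d2, 0.0)
    return float(d2[0]) if single else d2


def dissimilarity_profile(event_xy: np.ndarray, d2_by_grain: dict,
                          n_grid: int = 100):
    """D² of EHRM locations vs. straight-line distance from the first fix.

    Returns ``(table, trends)``: the per-location table and, per grain, a
    cubic smoothing-spline trend evaluated on a distance grid — the
    diagnostic for whether dissimilar habitat becomes more available
    further from the pre-EHRM range.
    """
    from scipy.interpolate import make_smoothing_spline

    xy = np.asarray(event_xy, dtype=float)
    if len(xy) < 4:
        raise ValueError("event needs at least 4 fixes")
    dist = np.hypot(*(xy - xy[0]).T)
    table = pd.DataFrame({"distance_m": dist})
    trends = {}
    for grain, d2 in d2_by_grain.items():
        d2 = np.asarray(d2, dtype=float)
        table[f"d2_{grain}"] = d2
        ok = np.isfinite(d2)
        order = np.argsort(dist[ok])
        xs, ys = dist[ok][order], d2[ok][order]
        xs_u, idx = np.unique(xs, return_index=True)
        grid = np.linspace(xs_u.min(), xs_u.max(), n_grid)
        if len(xs_u) < 5:  # smoothing spline needs at least 5 sites
            trends[grain] = pd.DataFrame(
                {"distance_m": grid, "d2_trend": np.full(n_grid, ys.mean())})
            continue
        # average duplicate distances for the spline
        ys_u = np.array([ys[xs == v].mean() for v in xs_u])
        spl = make_smoothing_spline(xs_u, ys_u)
        trends[grain] = pd.DataFrame({"distance_m": grid, "d2_trend": spl(grid)})
    return table, trends
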
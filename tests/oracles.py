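"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or brute force,
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import collections

import numpy as np


def window_metrics_oracle(values: np.ndarray, i: int, j: int, radius_m: float,
                          cellsize: float, groups: dict) -> dict:
    """All seven landscape metrics for the window centered on cell (i, j),
    by direct per-cell enumeration."""
    n0, n1 = values.shape
    k = int(np.floor(radius_m / cellsize))
    cells = []
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            if (di * di + dj * dj) * cellsize**2 <= radius_m**2:
                ii, jj = i + di, j + dj
                if 0 <= ii < n0 and 0 <= jj < n1:
                    cells.append((ii, jj))
    member = set(cells)
    n = len(cells)
    area = n * cellsize**2
    cnt = collections.Counter(values[c] for c in cells)
    classes = sorted(cnt)
    m = len(classes)
    out = {}
    for name, grp in groups.items():
        out[name] = 100.0 * sum(cnt[c] for c in grp if c in cnt) / n

    like = collections.Counter()
    unlike = collections.Counter()
    total_adj = 0
    for (ii, jj) in cells:
        for (di, dj) in ((0, 1), (1, 0)):
            nb = (ii + di, jj + dj)
            if nb in member:
                total_adj += 1
                a, b = values[ii, jj], values[nb]
                if a == b:
                    like[a] += 1
                else:
                    unlike[tuple(sorted((a, b)))] += 1
    e_total = sum(unlike.values())
    out["ED"] = 1e4 * (e_total * cellsize) / area
    out["PRD"] = 1e6 * m / area

    ai = 0.0
    for c in classes:
        a_c = cnt[c]
        ns = int(np.floor(np.sqrt(a_c)))
        rem = a_c - ns * ns
        max_g = 2 * ns * (ns - 1) + (
            0 if rem == 0 else (2 * rem - 1 if rem <= ns else 2 * rem - 2))
        max_g = min(max_g, total_adj)
        if max_g > 0:
            ai += (a_c / n) * (like[c] / max_g)
    out["AI"] = 100.0 * ai

    if m >= 3 and e_total > 0:
        acc = -sum((e / e_total) * np.log(e / e_total)
                   for e in unlike.values() if e > 0)
        out["IJI"] = 100.0 * acc / np.log(0.5 * m * (m - 1))
    else:
        out["IJI"] = np.nan
    return out


def window_metrics_oracle_full(values: np.ndarray, radius_m: float,
                               cellsize: float, groups: dict) -> dict:
    """Per-window enumeration of all seven metrics at every focal cell.

    Still a direct enumeration (each window counted on its own), but with
    precomputed offset lists so a whole raster is feasible.
    """
    n0, n1 = values.shape
    k = int(np.floor(radius_m / cellsize))
    offs = np.array([(di, dj) for di in range(-k, k + 1)
                     for dj in range(-k, k + 1)
                     if (di * di + dj * dj) * cellsize**2 <= radius_m**2])
    in_k = {tuple(o) for o in offs}
    pair_offs = []
    for di, dj in offs:
        for ddi, ddj in ((0, 1), (1, 0)):
            if (di + ddi, dj + ddj) in in_k:
                pair_offs.append((di, dj, di + ddi, dj + ddj))
    pair_offs = np.array(pair_offs)

    out = {name: np.zeros((n0, n1)) for name in
           list(groups) + ["ED", "PRD", "AI", "IJI"]}
    group_items = list(groups.items())
    for i in range(n0):
        rows_c = offs[:, 0] + i
        ok_r = (rows_c >= 0) & (rows_c < n0)
        prows1 = pair_offs[:, 0] + i
        prows2 = pair_offs[:, 2] + i
        ok_pr = (prows1 >= 0) & (prows1 < n0) & (prows2 >= 0) & (prows2 < n0)
        for j in range(n1):
            cols_c = offs[:, 1] + j
            ok = ok_r & (cols_c >= 0) & (cols_c < n1)
            cells = values[rows_c[ok], cols_c[ok]]
            n = len(cells)
            area = n * cellsize**2
            counts = np.bincount(cells, minlength=8)
            m = int((counts > 0).sum())
            for name, grp in group_items:
                out[name][i, j] = 100.0 * sum(counts[c] for c in grp) / n

            pc1 = pair_offs[:, 1] + j
            pc2 = pair_offs[:, 3] + j
            okp = ok_pr & (pc1 >= 0) & (pc1 < n1) & (pc2 >= 0) & (pc2 < n1)
            a = values[prows1[okp], pc1[okp]]
            b = values[prows2[okp], pc2[okp]]
            total_adj = len(a)
            unlike = a != b
            e_total = int(unlike.sum())
            out["ED"][i, j] = 1e4 * (e_total * cellsize) / area
            out["PRD"][i, j] = 1e6 * m / area

            like_counts = np.bincount(a[~unlike], minlength=8)
            ai = 0.0
            for c in range(1, 8):
                a_c = counts[c]
                if a_c == 0:
                    continue
                ns = int(np.floor(np.sqrt(a_c)))
                rem = a_c - ns * ns
                max_g = 2 * ns * (ns - 1) + (
                    0 if rem == 0 else
                    (2 * rem - 1 if rem <= ns else 2 * rem - 2))
                max_g = min(max_g, total_adj)
                if max_g > 0:
                    ai += (a_c / n) * (like_counts[c] / max_g)
            out["AI"][i, j] = 100.0 * ai

            if m >= 3 and e_total > 0:
                lo = np.minimum(a[unlike], b[unlike])
                hi = np.maximum(a[unlike], b[unlike])
                e = np.bincount(lo * 8 + hi)
                e = e[e > 0]
                frac = e / e_total
                acc = float(-(frac * np.log(frac)).sum())
                out["IJI"][i, j] = 100.0 * acc / np.log(0.5 * m * (m - 1))
            else:
                out["IJI"][i, j] = np.nan
    return out


def clr_grid_search_oracle(design, column, grid=(-5.0, 5.0), step=1e-4):
    """Grid-search maximizer of the one-coefficient conditional logistic
    likelihood, evaluated stratum by stratum over the whole beta grid."""
    betas = np.arange(grid[0], grid[1] + step / 2, step)
    ll = np.zeros_like(betas)
    for _, g in design.groupby("stratum"):
        x = g[column].to_numpy(dtype=float)
        used = x[g["case"].to_numpy() == 1][0]
        eta = np.outer(betas, x)  # (n_beta, n_candidates)
        m = eta.max(axis=1)
        ll += betas * used - (m + np.log(np.exp(eta - m[:, None]).sum(axis=1)))
    i = int(np.argmax(ll))
    return float(betas[i]), float(ll[i])


def conditional_loglik_direct(design, columns, beta):
    """Direct per-stratum evaluation of the conditional log-likelihood."""
    x = design[list(columns)].to_numpy(dtype=float)
    eta = x @ np.asarray(beta, dtype=float)
    ll = 0.0
    for s in np.unique(design["stratum"]):
        m = (design["stratum"] == s).to_numpy()
        e = eta[m]
        used = e[design.loc[m, "case"].to_numpy() == 1][0]
        ll += used - (np.max(e) + np.log(np.exp(e - np.max(e)).sum()))
    return ll


def dense_bbmm_ud_oracle(xy, t_hours, sigma2_m, location_error, grid, n_quad):
    """Full-grid (no stamping) evaluation of the bridge-mixture density."""
    nrows, ncols = grid.nrows, grid.ncols
    xc = grid.xmin + (np.arange(ncols) + 0.5) * grid.cellsize
    yc = grid.ymax - (np.arange(nrows) + 0.5) * grid.cellsize
    X, Y = np.meshgrid(xc, yc)
    T = np.diff(t_hours)
    bw = T / T.sum()
    alphas = np.linspace(0, 1, n_quad + 1)
    qw = np.ones(n_quad + 1)
    qw[0] = qw[-1] = 0.5
    dens = np.zeros_like(X)
    for b in range(len(T)):
        for a, w in zip(alphas, qw):
            mu = xy[b] * (1 - a) + xy[b + 1] * a
            var = T[b] * a * (1 - a) * sigma2_m + (
                (1 - a) ** 2 + a**2) * location_error**2
            g = np.exp(-((X - mu[0]) ** 2 + (Y - mu[1]) ** 2) / (2 * var))
            dens += bw[b] * w * g * (grid.cellsize**2 / (2 * np.pi * var))
    return dens / dens.sum()


def mahalanobis_linear_solve_oracle(x, mu, cov):
    """D² via a linear solve instead of an explicit inverse."""
    d = np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)
    z = np.linalg.solve(cov, d)
    return float(d @ z)
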
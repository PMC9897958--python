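"""Diagnostics and figures.

Produces the distance-dissimilarity diagnostic (is dissimilar habitat
simply farther away?), the density plot of maximum displacement per
movement type, and the model-averaged ln(RSS) curves written by the
model-fitting step. Figures go to results/figures/.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from nhpi.dissim import dissimilarity_profile
from nhpi.telemetry import read_relocations

ROOT = Path(__file__).resolve().parents[1]
GRAINS = (175, 250, 350, 500)


def main(detdir: Path, covdir: Path, modeldir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    events = pd.read_csv(detdir / "events.csv")
    design = pd.read_csv(covdir / "design.csv")

    # Fig: displacement densities by movement type
    fig, ax = plt.subplots(figsize=(5, 4))
    for kind, style in (("excursion", "--"), ("dispersal", "-")):
        d = events.loc[events["kind"] == kind, "max_distance_m"]
        if len(d) > 1:
            ax.hist(np.log(d), bins=12, histtype="step", linestyle=style,
                    density=True, label=f"{kind} (n={len(d)})")
    ax.set_xlabel("ln(max displacement, m)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "displacement_density.png", dpi=150)
    plt.close(fig)

    # Fig: D2 vs distance from the first event fix (used steps only)
    used = design[design["case"] == 1].copy()
    relocs = read_relocations(detdir / "screened_relocations.csv")
    trajs = {a: t.reset_index(drop=True) for a, t in relocs.groupby("animal_id")}
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    rows_all = []
    for g, ax in zip(GRAINS, axes.ravel()):
        for ev_id, grp in used.groupby("event_id"):
            xy = grp[["x_end", "y_end"]].to_numpy()
            d2 = grp[f"d2_ind_{g}"].to_numpy()
            if len(xy) < 4 or np.isnan(d2).all():
                continue
            table, trends = dissimilarity_profile(xy, {g: d2})
            ax.plot(table["distance_m"], table[f"d2_{g}"], ".", ms=2,
                    alpha=0.25, color="gray")
            ax.plot(trends[g]["distance_m"], trends[g]["d2_trend"],
                    color="goldenrod", lw=1, alpha=0.8)
            t = table.assign(event_id=ev_id, grain=g)
            rows_all.append(t)
        ax.set_title(f"grain {g} m")
        ax.set_ylabel("D2 (IND)")
    for ax in axes[1]:
        ax.set_xlabel("distance from first event fix (m)")
    fig.tight_layout()
    fig.savefig(outdir / "dissimilarity_profiles.png", dpi=150)
    plt.close(fig)
    if rows_all:
        pd.concat(rows_all, ignore_index=True).to_csv(
            outdir / "dissimilarity_profiles.csv", index=False)

    # Fig: ln(RSS) curves from the model stage
    for path in sorted(Path(modeldir).glob("lnrss_dind_*.csv")):
        curve = pd.read_csv(path)
        label = path.stem.replace("lnrss_dind_", "")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.fill_between(curve["value"], curve["lo"], curve["hi"], alpha=0.3)
        ax.plot(curve["value"], curve["ln_rss"])
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("D2 from movement-specific pre-event range (D_IND)")
        ax.set_ylabel("ln(RSS) vs. mean location")
        ax.set_title(label)
        fig.tight_layout()
        fig.savefig(outdir / f"lnrss_{label}.png", dpi=150)
        plt.close(fig)
    print(f"figures -> {outdir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--det", type=Path, default=ROOT / "results" / "detection")
    ap.add_argument("--cov", type=Path, default=ROOT / "results" / "covariates")
    ap.add_argument("--models", type=Path, default=ROOT / "results" / "models")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "figures")
    args = ap.parse_args()
    main(args.det, args.cov, args.models, args.out)
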
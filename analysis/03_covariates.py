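"""Build the step-selection design: kernel, random steps, covariates, D².

Reads the landscape, linear features, screened relocations, and event
ledger; fits the pooled gamma / von Mises movement kernel from EHRM
steps; draws 50 random steps per used step; attributes distance
covariates, the four-grain landscape-metric stacks, and squared
Mahalanobis dissimilarity from both the movement-specific (D_IND) and
pooled (D_ALL) references. Writes the strata design table and the
serialized references.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nhpi import dissim, metrics, steps
from nhpi.grid import read_ascii_grid
from nhpi.telemetry import read_relocations

ROOT = Path(__file__).resolve().parents[1]
GRAINS = (175, 250, 350, 500)
J = 50


def main(seed: int, syndir: Path, detdir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    landscape = read_ascii_grid(syndir / "landscape.asc")
    landscape.values = landscape.values.astype(np.int16)
    features = json.loads((syndir / "features.json").read_text())
    relocs = read_relocations(detdir / "screened_relocations.csv")
    events = pd.read_csv(detdir / "events.csv")
    pre_windows = json.loads((detdir / "pre_windows.json").read_text())

    dist_rasters = {
        "dForest": metrics.distance_raster(landscape, target=3),
        "dAg": metrics.distance_raster(landscape, target=4),
        "dStream": metrics.distance_raster(
            landscape, lines=[np.array(v) for v in features["streams"]]),
        "dRoad": metrics.distance_raster(
            landscape, lines=[np.array(v) for v in features["roads"]]),
    }
    for name, r in dist_rasters.items():
        r.write_ascii(outdir / f"{name}.asc")
    stacks = {g: metrics.moving_window_metrics(landscape, g) for g in GRAINS}

    # pooled movement kernel from all EHRM steps
    trajs = {a: t.reset_index(drop=True) for a, t in relocs.groupby("animal_id")}
    pooled, strata, records = [], [], []
    for _, ev in events.iterrows():
        traj = trajs[ev["animal_id"]]
        st = steps.steps_from_trajectory(traj, start=ev["start_index"],
                                         end=ev["end_index"])
        pooled.append(st)
        records.append((ev, st))
    kernel = steps.fit_movement_kernel(pd.concat(pooled, ignore_index=True))
    print(f"movement kernel: gamma(shape={kernel.shape:.2f}, "
          f"scale={kernel.scale:.1f} m), von Mises(kappa={kernel.kappa:.2f})")

    stratum_id = 0
    for ev, st in records:
        subset = ("dispersal" if ev["kind"] == "dispersal"
                  else f"excursion_{ev['season']}")
        for _, used in st.iterrows():
            stratum, _ = steps.generate_random_steps(
                used, used["bearing_prev"], kernel, J=J, rng=rng,
                extent=landscape)
            stratum.insert(0, "stratum", stratum_id)
            stratum["animal_id"] = ev["animal_id"]
            stratum["event_id"] = ev["event_id"]
            stratum["subset"] = subset
            strata.append(stratum)
            stratum_id += 1
    design = pd.concat(strata, ignore_index=True)

    pts = design.rename(columns={"x_end": "x", "y_end": "y"})[["x", "y"]]
    cov = metrics.extract_covariates(pts, dist_rasters)
    design = pd.concat([design, cov.drop(columns="any_undefined")], axis=1)
    metric_rows = {g: stacks[g].sample(pts["x"].to_numpy(), pts["y"].to_numpy())
                   for g in GRAINS}

    refs_out = {}
    pooled_rows = {g: [] for g in GRAINS}
    for _, ev in events.iterrows():
        pre_xy = trajs[ev["animal_id"]].iloc[
            pre_windows[ev["event_id"]]][["x", "y"]].to_numpy()
        for g in GRAINS:
            pooled_rows[g].append(stacks[g].sample(pre_xy[:, 0], pre_xy[:, 1]))
    for g in GRAINS:
        ref = dissim.build_reference(
            pd.concat(pooled_rows[g], ignore_index=True), g, scope="ALL")
        refs_out[f"ALL_{g}"] = ref.to_dict()
        design[f"d2_all_{g}"] = dissim.mahalanobis_d2(
            metric_rows[g].to_numpy(), ref)
    for g in GRAINS:
        design[f"d2_ind_{g}"] = np.nan
    for (_, ev), rows in zip(events.iterrows(), pooled_rows[GRAINS[0]]):
        mask = (design["event_id"] == ev["event_id"]).to_numpy()
        pre_xy = trajs[ev["animal_id"]].iloc[
            pre_windows[ev["event_id"]]][["x", "y"]].to_numpy()
        for g in GRAINS:
            ref = dissim.build_reference(
                stacks[g].sample(pre_xy[:, 0], pre_xy[:, 1]), g, scope="IND")
            refs_out[f"IND_{g}_{ev['event_id']}"] = ref.to_dict()
            design.loc[mask, f"d2_ind_{g}"] = dissim.mahalanobis_d2(
                metric_rows[g].to_numpy()[mask], ref)

    for g in GRAINS:
        undef = metric_rows[g].isna().any(axis=1).to_numpy()
        design.loc[undef, [f"d2_all_{g}", f"d2_ind_{g}"]] = np.nan

    design.to_csv(outdir / "design.csv", index=False)
    with open(outdir / "references.json", "w") as fh:
        json.dump(refs_out, fh)
    print(f"{design['stratum'].nunique()} strata "
          f"({len(design)} rows) -> {outdir / 'design.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--syn", type=Path, default=ROOT / "results" / "synthetic")
    ap.add_argument("--det", type=Path, default=ROOT / "results" / "detection")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "covariates")
    args = ap.parse_args()
    main(args.seed, args.syn, args.det, args.out)
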
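"""Screen relocations and detect extra-home-range movements.

Reads results/synthetic/relocations.csv, screens fixes by HDOP,
slides the 30-day / 2-day window with BBMM 95% isopleths over each
animal, classifies events into excursions and dispersals, and writes the
event ledger, the pre-window fix indices (needed for dissimilarity
references), and the descriptive summary.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from nhpi.ehrm import DetectorConfig, detect_ehrms, summarize_ehrms
from nhpi.telemetry import read_relocations, screen_relocations

ROOT = Path(__file__).resolve().parents[1]

DETECTOR = DetectorConfig(settle_radius_m=750.0, reentry_min_consecutive=2)


def main(indir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    relocs = read_relocations(indir / "relocations.csv")

    rows, pre_windows, screening = [], {}, {}
    all_events = []
    screened_frames = {}
    for animal, raw in relocs.groupby("animal_id"):
        traj, report = screen_relocations(raw.reset_index(drop=True))
        screened_frames[animal] = traj
        screening[animal] = dataclasses.asdict(report)
        events, unresolved = detect_ehrms(traj, DETECTOR, return_unresolved=True)
        all_events.extend(events)
        for k, ev in enumerate(events):
            rows.append({
                "animal_id": animal, "event_id": f"{animal}:{k}",
                "kind": ev.kind, "season": ev.season,
                "start_index": ev.start_index, "end_index": ev.end_index,
                "start_ts": ev.span_ts[0], "end_ts": ev.span_ts[1],
                "n_steps": ev.n_steps, "duration_h": ev.duration_h,
                "max_distance_m": ev.max_distance_m,
            })
            pre_windows[f"{animal}:{k}"] = ev.pre_indices.tolist()
        if unresolved:
            print(f"{animal}: {len(unresolved)} unresolved event(s) excluded")

    events_df = pd.DataFrame(rows)
    events_df.to_csv(outdir / "events.csv", index=False)

    # event paths as GeoJSON linestrings
    features = []
    for animal, traj in screened_frames.items():
        for _, ev in events_df[events_df["animal_id"] == animal].iterrows():
            seg = traj.iloc[ev["start_index"]:ev["end_index"] + 1]
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": seg[["x", "y"]].round(1)
                             .to_numpy().tolist()},
                "properties": {"event_id": ev["event_id"], "kind": ev["kind"],
                               "season": ev["season"]},
            })
    with open(outdir / "events.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    with open(outdir / "pre_windows.json", "w") as fh:
        json.dump(pre_windows, fh)
    with open(outdir / "screening.json", "w") as fh:
        json.dump(screening, fh, indent=1)
    pd.concat(screened_frames.values(), ignore_index=True).pipe(
        lambda d: d.to_csv(outdir / "screened_relocations.csv", index=False))

    summary = summarize_ehrms(all_events)
    summary.to_csv(outdir / "ehrm_summary.csv", index=False)
    print(summary[["kind", "n_events", "steps_mean", "duration_h_mean",
                   "max_dist_m_median"]].to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path,
                    default=ROOT / "results" / "synthetic")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "detection")
    args = ap.parse_args()
    main(args.indir, args.out)
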
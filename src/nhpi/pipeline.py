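"""End-to-end study orchestration on synthetic populations.

``simulate_study`` builds a patch-mosaic landscape with linear features
and a population of hourly GPS trajectories with planted excursions and
dispersals; dispersal travel steps are chosen with a known selection
coefficient against natal-habitat dissimilarity (ln D², grain 175 m),
excursion travel is habitat-indifferent. ``analyze_study`` runs the full
analysis — screening, EHRM detection, movement-kernel fitting, random
steps, covariate attribution, dissimilarity references, and the tiered
model selection — exactly as it would run on field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dissim, metrics, ssf, steps, synthetic, telemetry
from .ehrm import DetectorConfig, detect_ehrms
from .grid import Raster

__all__ = ["StudyConfig", "StudyData", "simulate_study", "analyze_study",
           "match_events"]

GRAINS = (175, 250, 350, 500)


@dataclass
class StudyConfig:
    """Conditions of a synthetic study."""

    n_animals: int = 10
    n_dispersers: int = 10
    landscape: synthetic.LandscapeConfig = field(
        default_factory=lambda: synthetic.LandscapeConfig(
            extent_cells=300, clumping=0.3, gradient=1.5))
    n_streams: int = 3
    n_roads: int = 2
    track_days: int = 46
    hr_sigma_m: float = 250.0
    start_time: str = "2012-06-01T00:00:00"
    excursion_day: int = 31
    dispersal_day: int = 33
    excursion_distance_m: float = 2400.0
    dispersal_distance_m: float = 4800.0
    excursion_speed_m_h: float = 500.0
    dispersal_speed_m_h: float = 330.0
    # one waypoint pull shared by both movement kinds keeps the pooled
    # turn-angle kernel representative of every subset's availability
    excursion_direction_weight: float = 0.6
    dispersal_direction_weight: float = 0.8
    proposal_kappa: float = 0.6  # travel-SSF candidate spread around prev bearing
    beta_dind_dispersal: float = -0.3  # on ln(D2_IND, 175 m)
    beta_dind_excursion: float = 0.0
    J: int = 50
    grains: tuple = GRAINS
    plant_grain_m: float = 175.0
    # settlement spread tightened to the bounded home-range size so
    # settlement is not declared while the tail of a slow travel phase
    # still fits inside the window
    detector: DetectorConfig = field(
        default_factory=lambda: DetectorConfig(settle_radius_m=750.0,
                                               reentry_min_consecutive=2))


@dataclass
class StudyData:
    landscape: Raster
    streams: list
    roads: list
    trajectories: dict  # animal_id -> relocation DataFrame (raw, unscreened)
    truths: dict  # animal_id -> SimTruth
    plant_stack: metrics.MetricStack | None = None


def _natal_reference(stack: metrics.MetricStack, landscape, tc, upto_index: int):
    """Truth-side reference: metric distribution over the animal's own
    resident path (the same fixes the detector's pre-EHRM window will
    cover), so the planted covariate matches what the analysis computes.
    Used only to plant selection, never to fit."""
    prefix, _ = synthetic.simulate_track(landscape, replace(tc, events=[]))
    xy = prefix[["x", "y"]].to_numpy()[24:upto_index]
    rows = stack.sample(xy[:, 0], xy[:, 1])
    return dissim.build_reference(rows, stack.radius_m, scope="TRUTH")


def _d2_chooser(stack: metrics.MetricStack, ref, beta: float):
    """Utility callable planting selection on ln D² at candidate endpoints.

    Rows with undefined IJI (single-class windows) get a 6-dimensional D²
    over the defined metrics using the corresponding submatrix of the
    reference covariance.
    """
    iji = metrics.METRIC_NAMES.index("IJI")
    keep = [j for j in range(len(metrics.METRIC_NAMES)) if j != iji]
    cov_sub_inv = np.linalg.inv(
        (ref.cov + ref.ridge * np.eye(ref.cov.shape[0]))[np.ix_(keep, keep)])

    def utility(pts: np.ndarray) -> np.ndarray:
        rows = stack.sample(pts[:, 0], pts[:, 1]).to_numpy()
        nan_iji = np.isnan(rows[:, iji])
        d2 = np.empty(len(rows))
        if (~nan_iji).any():
            d2[~nan_iji] = dissim.mahalanobis_d2(rows[~nan_iji], ref)
        if nan_iji.any():
            d = rows[np.ix_(nan_iji, keep)] - ref.mu[keep]
            d2[nan_iji] = np.einsum("ij,jk,ik->i", d, cov_sub_inv, d)
        return beta * np.log(np.maximum(d2, ssf.LN_FLOOR))

    return utility


def simulate_study(config: StudyConfig, seed: int) -> StudyData:
    rng = np.random.default_rng(seed)
    lc = replace(config.landscape, seed=int(rng.integers(2**31)))
    landscape = synthetic.generate_landscape(lc)
    streams = [synthetic.generate_linear_feature(landscape, int(rng.integers(2**31)))
               for _ in range(config.n_streams)]
    roads = [synthetic.generate_linear_feature(landscape, int(rng.integers(2**31)),
                                               step_m=400.0, wander_sd=0.15)
             for _ in range(config.n_roads)]
    plant_stack = metrics.moving_window_metrics(landscape, config.plant_grain_m)

    cx = 0.5 * (landscape.xmin + landscape.xmax)
    cy = 0.5 * (landscape.ymin + landscape.ymax)
    half = 0.5 * (landscape.xmax - landscape.xmin)

    def _viable_center():
        """Home centers sit in mixed habitat (IJI defined around them), in
        the central third so long waypoints stay on-raster."""
        iji = plant_stack.bands["IJI"]
        for _ in range(200):
            c = np.array([rng.uniform(cx - half / 3, cx + half / 3),
                          rng.uniform(cy - half / 3, cy + half / 3)])
            probes_x = c[0] + np.array([0.0, 300.0, -300.0, 0.0, 0.0])
            probes_y = c[1] + np.array([0.0, 0.0, 0.0, 300.0, -300.0])
            if np.isfinite(iji.sample(probes_x, probes_y)).all():
                return tuple(c)
        raise ValueError("no mixed-habitat home-range location found")

    trajectories, truths = {}, {}
    dispersers = set(range(config.n_dispersers))
    for a in range(config.n_animals):
        animal = f"deer{a:02d}"
        center = _viable_center()
        events = [synthetic.PlantedEvent(
            kind="excursion",
            start_index=24 * config.excursion_day + int(rng.integers(0, 12)),
            distance_m=config.excursion_distance_m,
            speed_m_per_h=config.excursion_speed_m_h,
            dwell_h=int(rng.integers(3, 6)),
            kappa=config.proposal_kappa,
            direction_weight=config.excursion_direction_weight,
        )]
        if a in dispersers:
            # aim the dispersal through the landscape center so the
            # settlement fits on the raster
            to_center = np.arctan2(cy - center[1], cx - center[0])
            events.append(synthetic.PlantedEvent(
                kind="dispersal",
                start_index=24 * config.dispersal_day + int(rng.integers(0, 12)),
                distance_m=config.dispersal_distance_m,
                speed_m_per_h=config.dispersal_speed_m_h,
                bearing=float(to_center + rng.uniform(-0.35, 0.35)),
                kappa=config.proposal_kappa,
                direction_weight=config.dispersal_direction_weight,
            ))
        tc = synthetic.TrackConfig(
            hr_center=center,
            hr_sigma=config.hr_sigma_m,
            n_fixes=24 * config.track_days,
            start_time=config.start_time,
            animal_id=animal,
            events=events,
            seed=int(rng.integers(2**31)),
        )
        ref = _natal_reference(plant_stack, landscape, tc,
                               24 * config.excursion_day)
        ln_d2 = _d2_chooser(plant_stack, ref, 1.0)
        betas = {"excursion": config.beta_dind_excursion,
                 "dispersal": config.beta_dind_dispersal}

        def utility(pts, kind, _u=ln_d2, _b=betas):
            return _b[kind] * _u(pts)

        traj, truth = synthetic.simulate_track(landscape, tc, step_chooser=utility)
        trajectories[animal] = traj
        truths[animal] = truth
    return StudyData(landscape, streams, roads, trajectories, truths, plant_stack)


def match_events(truth, events, traj: pd.DataFrame, tol_h: float = 3.0):
    """Match detected events to the planted ledger by time overlap.

    A detected event belongs to a planted event when their time spans
    overlap within ``tol_h`` hours (detected boundaries differ from the
    planted departure/return by a fix or two, and one planted movement may
    be split into adjacent detections). Each planted event is matched to
    the detection overlapping it longest; a false positive is a detection
    overlapping no planted span.

    Returns ``(matches, false_positives)``: matches maps the planted
    ledger index to ``(kind, detected event or None)``.
    """
    ts = pd.to_datetime(traj["timestamp"], utc=True).reset_index(drop=True)
    tol = pd.Timedelta(hours=tol_h)
    unmatched = set(range(len(events)))
    matches = {}
    for i, (kind, s, e) in enumerate(truth.planted_events):
        t0, t1 = ts.iloc[s] - tol, ts.iloc[e] + tol
        best, best_overlap = None, pd.Timedelta(0)
        for j, ev in enumerate(events):
            lo = max(t0, ev.span_ts[0])
            hi = min(t1, ev.span_ts[1])
            if hi >= lo:
                unmatched.discard(j)
                if hi - lo >= best_overlap:
                    best, best_overlap = ev, hi - lo
        matches[i] = (kind, best)
    false_pos = [events[j] for j in sorted(unmatched)]
    return matches, false_pos


@dataclass
class SubsetResult:
    label: str
    design: pd.DataFrame
    forms: dict
    base_spec: ssf.ModelSpec
    tier2_table: pd.DataFrame
    tier3: ssf.Tier3Result
    vif: pd.Series | None = None


@dataclass
class StudyResult:
    screening: dict
    events: dict  # animal_id -> list[EHRMEvent]
    unresolved: dict
    kernel: steps.MovementKernel
    design: pd.DataFrame
    subsets: dict  # label -> SubsetResult
    d_all_refs: dict
    summary: pd.DataFrame | None = None


def analyze_study(data: StudyData, config: StudyConfig, seed: int,
                  subset_min_strata: int = 30) -> StudyResult:
    """Run the full analysis on a (synthetic or field) study dataset."""
    rng = np.random.default_rng(seed)
    landscape = data.landscape

    screening = {}
    screened = {}
    events = {}
    unresolved = {}
    for animal, raw in data.trajectories.items():
        traj, report = telemetry.screen_relocations(raw)
        screening[animal] = report
        screened[animal] = traj
        evs, unres = detect_ehrms(traj, config.detector, return_unresolved=True)
        events[animal] = evs
        unresolved[animal] = unres

    # ---- covariate rasters -------------------------------------------------
    dist_rasters = {
        "dForest": metrics.distance_raster(landscape, target=3),
        "dAg": metrics.distance_raster(landscape, target=4),
        "dStream": metrics.distance_raster(landscape, lines=data.streams),
        "dRoad": metrics.distance_raster(landscape, lines=data.roads),
    }
    stacks = {g: metrics.moving_window_metrics(landscape, g)
              for g in config.grains}

    # ---- movement kernel from pooled EHRM steps ---------------------------
    step_tables = {}
    pooled = []
    for animal, evs in events.items():
        traj = screened[animal]
        all_steps = steps.steps_from_trajectory(traj)
        step_tables[animal] = all_steps
        for ev in evs:
            seg = all_steps[(all_steps["index_start"] >= ev.start_index)
                            & (all_steps["index_start"] < ev.end_index)]
            pooled.append(seg)
    pooled_steps = pd.concat(pooled, ignore_index=True) if pooled else pd.DataFrame()
    kernel = steps.fit_movement_kernel(pooled_steps)

    # ---- strata ------------------------------------------------------------
    strata = []
    stratum_id = 0
    event_records = []
    for animal, evs in events.items():
        traj = screened[animal]
        all_steps = step_tables[animal].set_index("index_start")
        for ev_id, ev in enumerate(evs):
            seg = all_steps[(all_steps.index >= ev.start_index)
                            & (all_steps.index < ev.end_index)]
            subset = "dispersal" if ev.kind == "dispersal" else f"excursion_{ev.season}"
            for idx, used in seg.iterrows():
                prev = used["bearing_prev"]
                if not np.isfinite(prev) and idx - 1 in all_steps.index:
                    prev = all_steps.loc[idx - 1, "bearing"]
                stratum, flagged = steps.generate_random_steps(
                    used, prev, kernel, J=config.J,
                    rng=rng, extent=landscape)
                stratum.insert(0, "stratum", stratum_id)
                stratum["animal_id"] = animal
                stratum["event_id"] = f"{animal}:{ev_id}"
                stratum["subset"] = subset
                strata.append(stratum)
                stratum_id += 1
            event_records.append((animal, ev_id, ev))
    if not strata:
        raise ValueError("no EHRM steps available to build strata")
    design = pd.concat(strata, ignore_index=True)

    # ---- covariates at endpoints ------------------------------------------
    pts = design.rename(columns={"x_end": "x", "y_end": "y"})[["x", "y"]]
    cov = metrics.extract_covariates(pts, dist_rasters)
    design = pd.concat([design, cov.drop(columns="any_undefined")], axis=1)
    metric_rows = {g: stacks[g].sample(pts["x"].to_numpy(), pts["y"].to_numpy())
                   for g in config.grains}

    # ---- dissimilarity references -----------------------------------------
    d_all_refs = {}
    pre_rows_by_grain = {g: [] for g in config.grains}
    for animal, evs in events.items():
        traj = screened[animal]
        for ev in evs:
            pre_xy = traj.iloc[ev.pre_indices][["x", "y"]].to_numpy()
            for g in config.grains:
                pre_rows_by_grain[g].append(
                    stacks[g].sample(pre_xy[:, 0], pre_xy[:, 1]))
    for g in config.grains:
        pooled_rows = pd.concat(pre_rows_by_grain[g], ignore_index=True)
        d_all_refs[g] = dissim.build_reference(pooled_rows, g, scope="ALL")
        design[f"d2_all_{g}"] = dissim.mahalanobis_d2(
            metric_rows[g].to_numpy(), d_all_refs[g])

    for g in config.grains:
        design[f"d2_ind_{g}"] = np.nan
    i = 0
    for animal, ev_id, ev in event_records:
        traj = screened[animal]
        rows_mask = design["event_id"] == f"{animal}:{ev_id}"
        pre_xy = traj.iloc[ev.pre_indices][["x", "y"]].to_numpy()
        for g in config.grains:
            ref = dissim.build_reference(
                stacks[g].sample(pre_xy[:, 0], pre_xy[:, 1]), g, scope="IND")
            x = metric_rows[g].to_numpy()[rows_mask.to_numpy()]
            design.loc[rows_mask, f"d2_ind_{g}"] = dissim.mahalanobis_d2(x, ref)

    # NaN metric vectors (undefined IJI) leave D2 undefined at those points
    for g in config.grains:
        undef = metric_rows[g].isna().any(axis=1).to_numpy()
        design.loc[undef, [f"d2_all_{g}", f"d2_ind_{g}"]] = np.nan

    # complete cases across every candidate covariate: all tier fits within
    # a subset must score the same strata or their AICc are not comparable.
    # An available step with an undefined D2 (IJI-undefined window) is
    # removed from its stratum's choice set; a stratum is only lost when
    # its *used* step is undefined.
    d2_cols = [f"d2_{s}_{g}" for s in ("all", "ind") for g in config.grains]
    incomplete = design[d2_cols].isna().any(axis=1)
    n_strata_total = design["stratum"].nunique()
    design_full = design
    bad_used = design.loc[incomplete & (design["case"] == 1), "stratum"].unique()
    design = design[~design["stratum"].isin(bad_used)]
    design = design[~(design[d2_cols].isna().any(axis=1) & (design["case"] == 0))]
    n_strata_dropped = n_strata_total - design["stratum"].nunique()

    # ---- tiered model selection per subset --------------------------------
    subsets = {}
    distance_covs = {"dForest": "plus1", "dStream": "plus1",
                     "dAg": "plus1", "dRoad": "plus1"}
    for label in sorted(design["subset"].unique()):
        sub = design[design["subset"] == label]
        if sub["stratum"].nunique() < subset_min_strata:
            continue
        forms = ssf.tier1_select_forms(sub, distance_covs)
        base_spec, base_fits, t2 = ssf.tier2_select_base(sub, forms)
        tier3 = ssf.tier3_select_dissimilarity(
            sub, base_spec,
            ssf.dissimilarity_candidates("d2_all_", config.grains),
            ssf.dissimilarity_candidates("d2_ind_", config.grains),
        )
        final = tier3.fits.get("base+D_ALL+D_IND", tier3.fits["base+D_ALL"])
        main_cols = [t.name for t in final.spec.terms]
        v = ssf.vif(sub, main_cols) if len(main_cols) >= 2 else None
        subsets[label] = SubsetResult(
            label=label, design=sub, forms=forms, base_spec=base_spec,
            tier2_table=t2, tier3=tier3, vif=v)

    all_events = [e for evs in events.values() for e in evs]
    from .ehrm import summarize_ehrms

    summary = summarize_ehrms(all_events) if all_events else None
    result = StudyResult(
        screening=screening, events=events, unresolved=unresolved,
        kernel=kernel, design=design, subsets=subsets, d_all_refs=d_all_refs,
        summary=summary,
    )
    result.design_all_rows = design_full
    result.n_strata_dropped_incomplete = int(n_strata_dropped)
    return result
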
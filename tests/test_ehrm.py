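import numpy as np
import pandas as pd
import pytest

from nhpi.bbmm import HomeRangePolygon
from nhpi.ehrm import (DetectorConfig, EHRMEvent, classify_ehrm, detect_ehrms,
                       summarize_ehrms)
from nhpi.grid import Raster
from nhpi.synthetic import PlantedEvent, TrackConfig, simulate_track
from nhpi.telemetry import screen_relocations


def _detect_with_truth(events, n_days=45, seed=0, cfg=None):
    tc = TrackConfig(n_fixes=24 * n_days, events=events, seed=seed,
                     poor_fix_fraction=0.0)
    traj, truth = simulate_track(None, tc)
    detected = detect_ehrms(traj, cfg or DetectorConfig())
    return traj, truth, detected


class TestDetection:
    def test_resident_trajectory_yields_no_events(self):
        _, _, detected = _detect_with_truth([], n_days=40, seed=1)
        assert detected == []

    def test_planted_excursion_found_and_delimited(self):
        events = [PlantedEvent("excursion", 24 * 32, distance_m=2800.0,
                               dwell_h=8)]
        traj, truth, detected = _detect_with_truth(events, seed=2)
        assert len(detected) == 1
        ev = detected[0]
        kind, s, e = truth.planted_events[0]
        assert ev.kind == "excursion"
        # detected span lies within the planted range give or take the
        # fixes spent crossing the home-range boundary
        assert abs(ev.start_index - s) <= 4
        assert abs(ev.end_index - e) <= 4

    def test_planted_dispersal_classified(self):
        events = [PlantedEvent("dispersal", 24 * 33, distance_m=5000.0)]
        traj, truth, detected = _detect_with_truth(events, n_days=46, seed=3)
        assert [ev.kind for ev in detected] == ["dispersal"]

    def test_truncated_dispersal_is_unresolved(self):
        # the collar "drops" long before a 168 h settlement is observed
        events = [PlantedEvent("dispersal", 24 * 36, distance_m=5000.0)]
        tc = TrackConfig(n_fixes=24 * 39, events=events, seed=4,
                         poor_fix_fraction=0.0)
        traj, _ = simulate_track(None, tc)
        resolved, unresolved = detect_ehrms(traj, DetectorConfig(),
                                            return_unresolved=True)
        assert resolved == []
        assert len(unresolved) == 1 and unresolved[0].kind == "unresolved"

    def test_three_consecutive_outside_fixes_insufficient(self):
        # a 3-fix foray 2 km out fails the >3-consecutive rule even though
        # the >500 m rule is met twice over
        tc = TrackConfig(n_fixes=24 * 40, events=[], seed=11,
                         poor_fix_fraction=0.0)
        traj, _ = simulate_track(None, tc)
        # splice the foray where the surrounding fixes sit near the range
        # center, so the outside run is exactly the spliced fixes
        d = np.hypot(traj["x"] - tc.hr_center[0], traj["y"] - tc.hr_center[1])
        candidates = [i for i in range(24 * 33, 24 * 34)
                      if d.iloc[i - 2:i].max() < tc.hr_sigma
                      and d.iloc[i + 3:i + 7].max() < tc.hr_sigma]
        i = candidates[0]
        traj.loc[i:i + 2, "x"] = tc.hr_center[0] + 2000.0
        traj.loc[i:i + 2, "y"] = tc.hr_center[1] + np.array([0.0, 150.0, 300.0])

        def overlapping(events):
            return [e for e in events
                    if e.start_index <= i + 4 and e.end_index >= i - 1]

        assert overlapping(detect_ehrms(traj, DetectorConfig())) == []
        # the same foray two fixes longer satisfies the consecutive rule
        traj.loc[i + 3:i + 4, "x"] = tc.hr_center[0] + 2000.0
        traj.loc[i + 3:i + 4, "y"] = tc.hr_center[1] + np.array([450.0, 600.0])
        assert len(overlapping(detect_ehrms(traj, DetectorConfig()))) == 1

    def test_monotone_in_thresholds(self):
        events = [PlantedEvent("excursion", 24 * 32, distance_m=2800.0)]
        tc = TrackConfig(n_fixes=24 * 42, events=events, seed=5,
                         poor_fix_fraction=0.0)
        traj, _ = simulate_track(None, tc)
        n_default = len(detect_ehrms(traj, DetectorConfig()))
        n_strict_dist = len(detect_ehrms(
            traj, DetectorConfig(dist_threshold_m=4000.0)))
        n_strict_run = len(detect_ehrms(
            traj, DetectorConfig(min_consecutive=30)))
        assert n_strict_dist <= n_default
        assert n_strict_run <= n_default

    def test_deterministic(self):
        events = [PlantedEvent("excursion", 24 * 32)]
        tc = TrackConfig(n_fixes=24 * 40, events=events, seed=6)
        traj, _ = simulate_track(None, tc)
        traj, _ = screen_relocations(traj)
        e1 = detect_ehrms(traj, DetectorConfig())
        e2 = detect_ehrms(traj, DetectorConfig())
        assert [(e.start_index, e.end_index, e.kind) for e in e1] == \
               [(e.start_index, e.end_index, e.kind) for e in e2]

    def test_short_trajectory_rejected(self):
        ts = pd.date_range("2012-06-01", periods=48, freq="h", tz="UTC")
        traj = pd.DataFrame({"animal_id": "a", "timestamp": ts,
                             "x": 0.0, "y": 0.0})
        with pytest.raises(ValueError):
            detect_ehrms(traj)


def _disc_polygon(radius_m=500.0, cell=30.0):
    n = int(2 * radius_m / cell) + 10
    grid = Raster(np.zeros((n, n)), -n * cell / 2, -n * cell / 2, cell)
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    x, y = grid.cell_center(rows, cols)
    return HomeRangePolygon(level=0.95, mask=np.hypot(x, y) <= radius_m,
                            grid=grid)


class TestClassification:
    def test_return_is_excursion(self):
        poly = _disc_polygon()
        t = np.arange(30.0)
        # out at fix 5, back inside at fix 12
        xy = np.zeros((30, 2))
        xy[5:12, 0] = np.linspace(800, 2000, 7)
        kind, end = classify_ehrm(5, xy, t, poly)
        assert kind == "excursion" and end == 11

    def test_settlement_is_dispersal(self):
        poly = _disc_polygon()
        n = 250
        t = np.arange(float(n))
        xy = np.zeros((n, 2))
        xy[5:25, 0] = np.linspace(700, 5000, 20)  # travel out
        xy[25:, 0] = 5000.0
        xy[25:, 1] = 100 * np.sin(np.arange(n - 25))  # tight settled wiggle
        kind, end = classify_ehrm(5, xy, t, poly, settle_window_h=168,
                                  settle_radius_m=1000)
        assert kind == "dispersal"
        assert 5 <= end <= 30

    def test_end_of_data_is_unresolved(self):
        poly = _disc_polygon()
        n = 50  # far less than the 168 h needed to declare settlement
        t = np.arange(float(n))
        xy = np.zeros((n, 2))
        xy[5:, 0] = np.linspace(700, 4000, n - 5)
        kind, end = classify_ehrm(5, xy, t, poly)
        assert kind == "unresolved" and end == n - 1

    def test_single_fix_clip_ignored_when_configured(self):
        poly = _disc_polygon()
        n = 250
        t = np.arange(float(n))
        xy = np.zeros((n, 2))
        xy[5:25, 0] = np.linspace(700, 5000, 20)
        xy[10, 0] = 400.0  # one-fix dip back inside mid-travel
        xy[25:, 0] = 5000.0
        kind1, _ = classify_ehrm(5, xy, t, poly)  # literal rule
        kind2, _ = classify_ehrm(5, xy, t, poly, reentry_min_consecutive=2)
        assert kind1 == "excursion"
        assert kind2 == "dispersal"


class TestSummary:
    def _event(self, kind, n_fixes, season="summer", dist=1000.0):
        return EHRMEvent(animal_id="a", kind=kind, season=season,
                         start_index=0, end_index=n_fixes - 1,
                         window=(None, None), pre_polygon=None,
                         max_distance_m=dist)

    def test_single_event_stats(self):
        table = summarize_ehrms([self._event("excursion", 9)])
        row = table.iloc[0]
        assert row["n_events"] == 1
        assert row["steps_mean"] == 8 and row["duration_h_mean"] == 8

    def test_two_event_arithmetic(self):
        events = [self._event("excursion", 5), self._event("excursion", 13)]
        row = summarize_ehrms(events).iloc[0]
        assert row["steps_mean"] == 8 and row["steps_se"] == 4
        assert row["steps_median"] == 8
        assert (row["steps_min"], row["steps_max"]) == (4, 12)

    def test_types_summarized_separately(self):
        events = [self._event("excursion", 5), self._event("dispersal", 60)]
        table = summarize_ehrms(events).set_index("kind")
        assert table.loc["dispersal", "n_events"] == 1
        assert table.loc["excursion", "steps_mean"] == 4

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_ehrms([])
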
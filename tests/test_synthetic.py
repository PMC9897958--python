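import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nhpi.synthetic import (LandscapeConfig, PlantedEvent, TrackConfig,
                            generate_landscape, generate_linear_feature,
                            simulate_ssf_steps, simulate_track)


class TestLandscape:
    def test_degenerate_proportions_all_forest(self):
        cfg = LandscapeConfig(clumping=0.0,
                              class_proportions=(0, 0, 1, 0, 0, 0, 0), seed=1)
        r = generate_landscape(cfg)
        assert (r.values == 3).all()

    def test_deterministic_given_seed(self):
        cfg = LandscapeConfig(extent_cells=100, seed=9)
        assert np.array_equal(generate_landscape(cfg).values,
                              generate_landscape(cfg).values)

    def test_realized_proportions_close_to_target(self):
        target = (0.05, 0.10, 0.18, 0.45, 0.18, 0.03, 0.01)
        for seed in range(10):
            cfg = LandscapeConfig(extent_cells=300, clumping=0.5,
                                  class_proportions=target, seed=seed)
            r = generate_landscape(cfg)
            frac = (r.values == 3).mean()
            assert 0.13 <= frac <= 0.23

    def test_all_nonzero_classes_present(self):
        cfg = LandscapeConfig(extent_cells=200, clumping=0.6, seed=3)
        r = generate_landscape(cfg)
        assert set(np.unique(r.values)) == set(range(1, 8))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(class_proportions=(1, 1, 0, 0, 0, 0, 0)).validate()
        with pytest.raises(ValueError):
            LandscapeConfig(extent_cells=20).validate()

    def test_linear_feature_starts_on_west_edge_and_leaves(self, small_landscape):
        line = generate_linear_feature(small_landscape, seed=4)
        assert line.shape[1] == 2 and len(line) >= 2
        assert line[0, 0] == small_landscape.xmin
        assert not small_landscape.contains(line[-1, 0], line[-1, 1])


class TestTrack:
    def test_resident_track_stays_bounded(self):
        cfg = TrackConfig(n_fixes=24 * 40, events=[], seed=5)
        traj, truth = simulate_track(None, cfg)
        d = np.hypot(traj["x"] - cfg.hr_center[0], traj["y"] - cfg.hr_center[1])
        # reflected mean-reverting walk: never beyond the range limit
        assert (d < 4 * cfg.hr_sigma).all()
        assert truth.planted_events == []

    def test_dispersal_settles_at_new_center(self):
        cfg = TrackConfig(n_fixes=24 * 45, seed=6, events=[
            PlantedEvent("dispersal", 24 * 34, distance_m=5000.0)])
        traj, truth = simulate_track(None, cfg)
        assert truth.planted_events[0][0] == "dispersal"
        xy = traj[["x", "y"]].to_numpy()
        centroid = xy[-200:].mean(axis=0)
        assert np.hypot(*(centroid - np.array(truth.settle_center))) < 500.0

    def test_excursion_exits_and_returns(self):
        cfg = TrackConfig(n_fixes=24 * 40, seed=7, events=[
            PlantedEvent("excursion", 24 * 32, distance_m=2600.0)])
        traj, truth = simulate_track(None, cfg)
        kind, s, e = truth.planted_events[0]
        assert kind == "excursion"
        xy = traj[["x", "y"]].to_numpy()
        d = np.hypot(*(xy - np.array(cfg.hr_center)).T)
        assert d[s:e + 1].max() > 2000.0  # went far out
        assert d[e + 24:].max() < 4 * cfg.hr_sigma  # resident again

    def test_deterministic_given_seed(self):
        cfg = TrackConfig(n_fixes=24 * 36, seed=8,
                          events=[PlantedEvent("excursion", 24 * 31)])
        t1, _ = simulate_track(None, cfg)
        t2, _ = simulate_track(None, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            simulate_track(None, TrackConfig(n_fixes=100))


class TestSsfSteps:
    KERNEL = (2.0, 125.0, 0.0, 0.5)

    def test_null_beta_used_index_uniform(self):
        cov = {"c": lambda x, y: np.sin(x / 200.0)}
        design, _ = simulate_ssf_steps([0.0], self.KERNEL, cov,
                                       n_strata=2000, J=4, seed=3)
        pos = design.groupby("stratum", group_keys=False).apply(
            lambda g: int(np.nonzero(g["case"].to_numpy() == 1)[0][0]),
            include_groups=False)
        counts = np.bincount(pos, minlength=5)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_stratum_structure(self):
        cov = {"c": lambda x, y: x * 0.0}
        design, _ = simulate_ssf_steps([0.0], self.KERNEL, cov,
                                       n_strata=10, J=7, seed=4)
        sizes = design.groupby("stratum").size()
        assert (sizes == 8).all()
        assert (design.groupby("stratum")["case"].sum() == 1).all()
        for _, g in design.groupby("stratum"):
            assert g["x_start"].nunique() == 1 and g["y_start"].nunique() == 1

    def test_recovers_true_beta_within_3_se(self):
        from nhpi.ssf import ModelSpec, ModelTerm, clr_fit

        cov = {
            "c1": lambda x, y: np.sin(x / 300.0) + 0.001 * y,
            "c2": lambda x, y: np.cos(y / 250.0) + 0.0005 * x,
        }
        design, truth = simulate_ssf_steps([-0.5, 0.3], self.KERNEL, cov,
                                           n_strata=500, J=50, seed=42)
        spec = ModelSpec(terms=(ModelTerm("c1"), ModelTerm("c2")),
                         include_step_length=False)
        fit = clr_fit(design, spec)
        z = (fit.beta.to_numpy() - truth.true_beta) / fit.se.to_numpy()
        assert np.all(np.abs(z) < 3)
        assert np.sign(fit.beta["c1"]) < 0 < np.sign(fit.beta["c2"])

    def test_deterministic_given_seed(self):
        cov = {"c": lambda x, y: x / 1000.0}
        d1, _ = simulate_ssf_steps([0.2], self.KERNEL, cov, 20, 5, seed=11)
        d2, _ = simulate_ssf_steps([0.2], self.KERNEL, cov, 20, 5, seed=11)
        pd.testing.assert_frame_equal(d1, d2)

    def test_j_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_ssf_steps([0.0], self.KERNEL, {"c": lambda x, y: x}, 5, 1, 0)
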
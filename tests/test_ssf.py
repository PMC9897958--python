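import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nhpi.ssf import (BASE_HYPOTHESES, FitResult, ModelSpec, ModelTerm, aicc,
                      akaike_weights, clr_fit, comparison_table,
                      dissimilarity_candidates, model_average_rss,
                      tier1_select_forms, tier2_select_base,
                      tier3_select_dissimilarity, vif)
from nhpi.synthetic import simulate_ssf_steps
from oracles import clr_grid_search_oracle, conditional_loglik_direct

# A small printed design: 3 strata, 1 covariate, 1 used + 3 available each.
FIXTURE = pd.DataFrame({
    "stratum": [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2],
    "case":    [1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0],
    "z":       [1.2, 0.4, -0.3, 0.8,
                0.9, 1.5, 0.2, -0.6,
                -0.1, -1.0, 0.7, 0.3],
})
FIXTURE_SPEC = ModelSpec(terms=(ModelTerm("z"),), include_step_length=False)


def _fixture_design(n_copies=4):
    """Replicate the printed fixture so the 10-strata floor is met; copies
    share the likelihood maximizer with the original."""
    parts = []
    for k in range(n_copies):
        part = FIXTURE.copy()
        part["stratum"] = part["stratum"] + 3 * k
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


class TestClrFit:
    def test_matches_grid_search_oracle_on_printed_fixture(self):
        design = _fixture_design()
        fit = clr_fit(design, FIXTURE_SPEC)
        b_grid, ll_grid = clr_grid_search_oracle(design, "z")
        assert fit.beta["z"] == pytest.approx(b_grid, abs=1e-4)
        assert fit.loglik >= ll_grid - 1e-8

    def test_loglik_agrees_with_direct_evaluation(self):
        design = _fixture_design()
        fit = clr_fit(design, FIXTURE_SPEC)
        direct = conditional_loglik_direct(design, ["z"], [fit.beta["z"]])
        assert fit.loglik == pytest.approx(direct, abs=1e-10)

    def test_matches_r_survival_clogit(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH")
        design = _fixture_design()
        csv = tmp_path / "design.csv"
        design.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            m <- clogit(case ~ z + strata(stratum), data = d)
            cat(sprintf("%.10f %.10f", coef(m)["z"], sqrt(vcov(m)["z","z"])))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        r_beta, r_se = map(float, out.stdout.split())
        fit = clr_fit(design, FIXTURE_SPEC)
        assert fit.beta["z"] == pytest.approx(r_beta, abs=1e-6)
        assert fit.se["z"] == pytest.approx(r_se, rel=1e-4)

    def test_invariant_to_stratum_constant_shift(self, rng):
        design, _ = simulate_ssf_steps(
            [0.4], (2.0, 125.0, 0.0, 0.5),
            {"c": lambda x, y: np.sin(x / 200.0)}, 50, 10, seed=3)
        fit1 = clr_fit(design, ModelSpec(terms=(ModelTerm("c"),),
                                         include_step_length=False))
        shifted = design.copy()
        shifts = rng.normal(size=design["stratum"].nunique())
        shifted["c"] = shifted["c"] + shifts[shifted["stratum"].to_numpy()]
        fit2 = clr_fit(shifted, ModelSpec(terms=(ModelTerm("c"),),
                                          include_step_length=False))
        assert fit1.beta["c"] == pytest.approx(fit2.beta["c"], abs=1e-8)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_invariant_to_duplicating_candidate_sets(self):
        # appending a copy of every candidate as an extra available step
        # doubles each stratum's denominator: the likelihood shifts by a
        # constant and the maximizer is unchanged
        design = _fixture_design()
        dup = design.copy()
        dup["case"] = 0
        doubled = pd.concat([design, dup], ignore_index=True)
        f1 = clr_fit(design, FIXTURE_SPEC)
        f2 = clr_fit(doubled, FIXTURE_SPEC)
        assert f1.beta["z"] == pytest.approx(f2.beta["z"], abs=1e-6)
        n_strata = design["stratum"].nunique()
        assert f2.loglik == pytest.approx(f1.loglik - n_strata * np.log(2),
                                          abs=1e-6)

    def test_stratum_constant_covariate_flagged(self):
        design = _fixture_design()
        design["flat"] = design["stratum"].map(float)  # constant within strata
        spec = ModelSpec(terms=(ModelTerm("z"), ModelTerm("flat")),
                         include_step_length=False)
        fit = clr_fit(design, spec)
        assert "flat" in fit.flags["no_information"]
        assert np.isnan(fit.beta["flat"])
        assert np.isfinite(fit.beta["z"])

    def test_nan_strata_dropped_and_counted(self):
        design = _fixture_design()
        design.loc[design["stratum"] == 0, "z"] = np.nan
        fit = clr_fit(design, FIXTURE_SPEC)
        assert fit.n_strata_dropped == 1
        assert fit.n_strata == design["stratum"].nunique() - 1

    def test_too_few_strata_rejected(self):
        with pytest.raises(ValueError):
            clr_fit(FIXTURE, FIXTURE_SPEC)


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        assert aicc(-50.0, 2, 100) == pytest.approx(104.0 + 12 / 97)

    def test_null_model(self):
        assert aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_correction_always_positive(self):
        for k, n in [(1, 10), (3, 30), (5, 200)]:
            assert aicc(-10.0, k, n) > -2 * -10.0 + 2 * k

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_equal_aicc_gives_equal_weights(self):
        np.testing.assert_allclose(akaike_weights([10.0] * 4), 0.25)

    def test_delta_two_closed_form(self):
        w = akaike_weights([0.0, 2.0])
        expected = 1 / (1 + np.exp(-1))
        assert w[0] == pytest.approx(expected)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ordering_invariant_to_loglik_shift(self):
        lls = np.array([-100.0, -98.0, -103.0])
        a1 = [aicc(ll, 2, 50) for ll in lls]
        a2 = [aicc(ll + 7.0, 2, 50) for ll in lls]
        assert np.argsort(a1).tolist() == np.argsort(a2).tolist()


class TestVif:
    def test_orthogonal_covariates(self, rng):
        n = 500
        design = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n),
                               "c": rng.normal(size=n)})
        v = vif(design, ["a", "b", "c"])
        assert np.all(v < 1.1)

    def test_duplicated_covariate_is_infinite(self, rng):
        a = rng.normal(size=200)
        design = pd.DataFrame({"a": a, "b": a.copy()})
        v = vif(design, ["a", "b"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_half_shared_variance_gives_two(self, rng):
        n = 200000
        a = rng.normal(size=n)
        b = a + rng.normal(size=n)  # R^2 = 0.5
        v = vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert v["a"] == pytest.approx(2.0, rel=0.05)


def _design_with_named_covariates(beta, names, n_strata=300, seed=0,
                                  transform=None):
    fields = {}
    rng = np.random.default_rng(seed + 77)
    for i, nm in enumerate(names):
        fx, fy = rng.uniform(150, 400, 2)
        px, py = rng.uniform(0, 2 * np.pi, 2)

        def f(x, y, fx=fx, fy=fy, px=px, py=py):
            raw = 2.0 + np.sin(x / fx + px) + np.cos(y / fy + py)
            return raw

        fields[nm] = f
    design, _ = simulate_ssf_steps(beta, (2.0, 125.0, 0.0, 0.5), fields,
                                   n_strata, 20, seed=seed)
    return design


class TestTieredSelection:
    def test_tier1_tie_breaks_to_linear(self):
        # identical AICc across forms is constructed by a covariate with no
        # information: all forms collapse to flagged no-information fits is
        # not comparable, so instead verify the declared key ordering
        from nhpi.ssf import FORMS

        key = sorted(FORMS, key=lambda f: (0, ModelTerm("c", f).n_params,
                                           f != "linear"))
        assert key[0] == "linear"

    def test_tier1_prefers_true_log_form(self):
        rng = np.random.default_rng(5)
        wins = 0
        for rep in range(20):
            design = _design_with_named_covariates([0.0], ["d"], 200,
                                                   seed=rep)
            # effect truly on the ln scale of a distance-like covariate
            design = design.drop(columns="d").assign(
                d=np.exp(rng.uniform(0, 6, len(design))))
            util = -1.5 * np.log(design["d"] + 1)
            # rebuild the used flag per stratum from the ln utility
            for s, g in design.groupby("stratum"):
                p = np.exp(util[g.index] - util[g.index].max())
                p = p / p.sum()
                idx = rng.choice(g.index, p=p)
                design.loc[g.index, "case"] = 0
                design.loc[idx, "case"] = 1
            forms = tier1_select_forms(design, {"d": "plus1"})
            wins += forms["d"].form == "ln"
        assert wins >= 18  # >= 90% of replicates

    def test_tier2_identifies_the_generating_hypothesis(self):
        design = _design_with_named_covariates(
            [-0.8, -0.8, 0.0, 0.0], ["dForest", "dStream", "dAg", "dRoad"],
            n_strata=400, seed=9)
        forms = {n: ModelTerm(n, "linear") for n in BASE_HYPOTHESES["global"]}
        best, fits, table = tier2_select_base(design, forms)
        assert set(table.columns) == {"model", "k", "AICc", "dAICc", "w", "LL"}
        assert table["model"].iloc[0] in ("corridors", "global")
        # effects on all four favor the global hypothesis
        design2 = _design_with_named_covariates(
            [-0.6, -0.6, 0.6, 0.6], ["dForest", "dStream", "dAg", "dRoad"],
            n_strata=400, seed=10)
        _, _, table2 = tier2_select_base(design2, forms)
        assert table2["model"].iloc[0] == "global"

    def test_tier3_correlation_fallback(self):
        design = _design_with_named_covariates(
            [-0.5, -0.5], ["dForest", "dStream"], n_strata=200, seed=11)
        rng = np.random.default_rng(0)
        base_field = rng.uniform(1, 20, len(design))
        for g in (175, 250, 350, 500):
            design[f"d2_all_{g}"] = base_field * (1 + 0.001 * g)
            # d2_ind identical to d2_all up to scale -> r = 1.0 everywhere
            design[f"d2_ind_{g}"] = base_field * (2 + 0.001 * g)
        base_spec = ModelSpec(terms=(ModelTerm("dForest"), ModelTerm("dStream")))
        res = tier3_select_dissimilarity(
            design, base_spec,
            dissimilarity_candidates("d2_all_"),
            dissimilarity_candidates("d2_ind_"))
        assert res.d_ind_omitted and res.d_ind_term is None
        assert abs(res.correlation) > 0.70  # every fallback candidate failed
        assert set(res.fits) == {"base", "base+D_ALL"}

    def test_tier3_null_simulation_keeps_base_competitive(self):
        # with pure-noise D2 columns the base must stay competitive and
        # the selected D_IND coefficient must look null; note that picking
        # the best of 8 noise candidates by AICc lets the D_ALL model edge
        # out the base by chance fairly often, so topping the table is not
        # the right null check
        rng = np.random.default_rng(2)
        base_competitive = 0
        null_cis = 0
        for rep in range(10):
            design = _design_with_named_covariates(
                [-0.5, -0.5], ["dForest", "dStream"], n_strata=150,
                seed=100 + rep)
            for g in (175, 250, 350, 500):
                design[f"d2_all_{g}"] = rng.gamma(2.0, 3.0, len(design))
                design[f"d2_ind_{g}"] = rng.gamma(2.0, 3.0, len(design))
            base_spec = ModelSpec(terms=(ModelTerm("dForest"),
                                         ModelTerm("dStream")))
            res = tier3_select_dissimilarity(
                design, base_spec,
                dissimilarity_candidates("d2_all_"),
                dissimilarity_candidates("d2_ind_"))
            table = res.table.set_index("model")
            # two rounds of best-of-8 selection can harvest up to ~2 max-of-8
            # chi-square(1) draws (~5-7 each) minus the 2-per-term penalty
            # from noise alone, so the base can trail by several AICc units
            base_competitive += table.loc["base", "dAICc"] <= 8.0
            if res.d_ind_term is not None:
                ci = res.fits["base+D_ALL+D_IND"].ci().loc[
                    res.d_ind_term.columns()[0]]
                null_cis += ci["lo"] <= 0 <= ci["hi"]
            else:
                null_cis += 1
        assert base_competitive >= 8
        assert null_cis >= 7


class TestModelAverageRss:
    def _fit(self, beta, se, term, weight):
        spec = ModelSpec(terms=(term,), include_step_length=False)
        names = spec.column_names()
        return FitResult(
            spec=spec, beta=pd.Series([beta], index=names),
            se=pd.Series([se], index=names), vcov=np.array([[se**2]]),
            loglik=0.0, k=1, n_strata=100, aicc=0.0, converged=True,
            weight=weight)

    def test_zero_at_reference_value(self):
        fit = self._fit(-0.27, 0.05, ModelTerm("d"), 1.0)
        curve = model_average_rss([fit], "d", ref_value=2.0,
                                  values=[2.0], n_draws=200, seed=0)
        assert curve.loc[0, "ln_rss"] == 0.0

    def test_single_linear_model_closed_form(self):
        fit = self._fit(-0.27, 0.05, ModelTerm("d"), 1.0)
        curve = model_average_rss([fit], "d", ref_value=0.0, values=[1.0],
                                  n_draws=500, seed=1)
        assert curve.loc[0, "ln_rss"] == pytest.approx(-0.27)
        assert curve.loc[0, "lo"] < -0.27 < curve.loc[0, "hi"]

    def test_weighted_average_of_two_models(self):
        f1 = self._fit(0.0, 1e-9, ModelTerm("d"), 0.5)
        f2 = self._fit(-0.4, 1e-9, ModelTerm("d"), 0.5)
        curve = model_average_rss([f1, f2], "d", 0.0, [1.0], n_draws=100, seed=2)
        assert curve.loc[0, "ln_rss"] == pytest.approx(-0.2)

    def test_missing_focus_everywhere_raises(self):
        fit = self._fit(0.1, 0.1, ModelTerm("other"), 1.0)
        with pytest.raises(ValueError):
            model_average_rss([fit], "d", 0.0, [1.0])
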
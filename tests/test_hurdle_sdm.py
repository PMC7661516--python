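import numpy as np
import pandas as pd
import pytest

from abrolhos.hurdle_sdm import (HurdleSpec, build_design, fit_density,
                                 fit_hurdle, fit_presence, hotspot_cells,
                                 predict_grid)
from abrolhos.spatial import SpatialFieldParams
from abrolhos.synthetic_data import (SimConfig, simulate_covariates,
                                     simulate_surveys)

NOFRILLS = dict(include_observer_effect=False, include_year_factor=False,
                include_spatial_field=False)


class TestBuildDesign:
    def test_intercept_only(self):
        df = pd.DataFrame({"site_id": list("abcde")})
        X, info = build_design(df, HurdleSpec(terms=(), **NOFRILLS))
        assert X.shape == (5, 1)
        assert np.all(X == 1.0)

    def test_binary_covariate_untouched(self):
        df = pd.DataFrame({"site_id": list("abcd"),
                           "rugosity": [0, 1, 1, 0]})
        X, info = build_design(df, HurdleSpec(terms=("rugosity",),
                                              **NOFRILLS))
        assert np.array_equal(X[:, 1], [0, 1, 1, 0])

    def test_continuous_standardised(self):
        df = pd.DataFrame({"site_id": list("abc"),
                           "depth_m": [5.0, 10.0, 15.0]})
        X, _ = build_design(df, HurdleSpec(terms=("depth_m",), **NOFRILLS))
        assert X[:, 1].mean() == pytest.approx(0.0)
        assert X[:, 1].std() == pytest.approx(1.0)

    def test_interaction_is_product_of_transformed_columns(self):
        df = pd.DataFrame({"site_id": list("abc"),
                           "sst_c": [25.0, 26.0, 27.0],
                           "sss_psu": [36.5, 37.0, 37.5]})
        spec = HurdleSpec(terms=("sst_c", "sss_psu", "sst_c:sss_psu"),
                          **NOFRILLS)
        X, _ = build_design(df, spec)
        assert np.allclose(X[:, 3], X[:, 1] * X[:, 2])

    def test_year_factor_reference_level(self):
        df = pd.DataFrame({"site_id": list("abcd"),
                           "year": [2003, 2004, 2004, 2005]})
        spec = HurdleSpec(terms=(), include_year_factor=True,
                          include_observer_effect=False,
                          include_spatial_field=False)
        X, info = build_design(df, spec, years=[2003, 2004, 2005])
        assert info.colnames == ["intercept", "year_2004", "year_2005"]
        assert np.array_equal(X[:, 1], [0, 1, 1, 0])

    def test_missing_value_names_site_and_field(self):
        df = pd.DataFrame({"site_id": ["s1", "s2"],
                           "depth_m": [5.0, np.nan]})
        with pytest.raises(ValueError, match="depth_m.*s2"):
            build_design(df, HurdleSpec(terms=("depth_m",), **NOFRILLS))


class TestStageContracts:
    def test_all_equal_presence_rejected(self):
        X = np.ones((10, 1))
        spec = HurdleSpec(terms=(), **NOFRILLS)
        with pytest.raises(ValueError, match="separation"):
            fit_presence(np.ones(10), X, ["intercept"], spec)

    def test_nonpositive_density_rejected(self):
        X = np.ones((5, 1))
        spec = HurdleSpec(terms=(), **NOFRILLS)
        with pytest.raises(ValueError, match="positive"):
            fit_density(np.array([1.0, 0.0, 2.0, 3.0, 1.0]), X,
                        ["intercept"], spec)

    def test_intercept_only_presence_matches_empirical_logit(self, rng):
        y = (rng.random(400) < 0.5).astype(float)
        X = np.ones((400, 1))
        spec = HurdleSpec(terms=(), **NOFRILLS)
        fit = fit_presence(y, X, ["intercept"], spec, seed=1, draws=500,
                           warmup=700)
        logit = np.log(y.mean() / (1 - y.mean()))
        assert fit.summary.iloc[0]["mean"] == pytest.approx(logit, abs=0.25)

    def test_gamma_intercept_and_shape_recovery(self, rng):
        y = rng.gamma(2.0, np.exp(1.0) / 2.0, 500)
        X = np.ones((500, 1))
        spec = HurdleSpec(terms=(), **NOFRILLS)
        fit = fit_density(y, X, ["intercept"], spec, seed=2, draws=600,
                          warmup=800)
        s = fit.summary.set_index("term")
        assert s.at["intercept", "mean"] == pytest.approx(1.0, abs=0.15)
        assert 1.0 <= s.at["shape", "mean"] <= 3.0


class TestHurdleOrchestration:
    def test_no_presences_propagates_stage1_error(self, recovery_config,
                                                  recovery_spec):
        cfg = recovery_config
        cov = simulate_covariates(cfg, 1)
        rec, _ = simulate_surveys(cfg, cov, 1)
        rec = rec.copy()
        rec["count"] = 0
        with pytest.raises(ValueError, match="separation"):
            fit_hurdle(rec, cov, recovery_spec, seed=0, draws=50, warmup=50)

    def test_same_seed_identical_summaries(self, recovery_data,
                                           recovery_spec):
        rec, cov, _ = recovery_data
        f1 = fit_hurdle(rec, cov, recovery_spec, seed=9, draws=150,
                        warmup=200)
        f2 = fit_hurdle(rec, cov, recovery_spec, seed=9, draws=150,
                        warmup=200)
        pd.testing.assert_frame_equal(f1.presence.summary,
                                      f2.presence.summary)
        pd.testing.assert_frame_equal(f1.density.summary,
                                      f2.density.summary)

    def test_record_order_does_not_change_posterior(self, recovery_data,
                                                    recovery_spec):
        rec, cov, _ = recovery_data
        shuffled = rec.sample(frac=1, random_state=3).reset_index(drop=True)
        f1 = fit_hurdle(rec, cov, recovery_spec, seed=4, draws=120,
                        warmup=150)
        f2 = fit_hurdle(shuffled, cov, recovery_spec, seed=4, draws=120,
                        warmup=150)
        pd.testing.assert_frame_equal(f1.presence.summary,
                                      f2.presence.summary)

    def test_posterior_means_match_glm_mle(self, recovery_data,
                                           recovery_spec):
        """With the field off and vague priors, posterior means of the fixed
        effects agree with the corresponding GLM maximum likelihood."""
        import statsmodels.api as sm

        rec, cov, _ = recovery_data
        fit = fit_hurdle(rec, cov, recovery_spec, seed=6, draws=600,
                         warmup=800)
        X = fit.design.matrix(fit.data)
        y = (fit.data["count"] > 0).astype(float)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        s = fit.presence.summary
        for j in range(X.shape[1]):
            assert abs(s.iloc[j]["mean"] - glm.params.iloc[j]) \
                < 3 * s.iloc[j]["sd"]

        pos = fit.data["count"] > 0
        glm_g = sm.GLM(fit.data.loc[pos, "density"], X[pos.to_numpy()],
                       family=sm.families.Gamma(sm.families.links.Log())
                       ).fit()
        s2 = fit.density.summary
        for j in range(X.shape[1]):
            assert abs(s2.iloc[j]["mean"] - glm_g.params.iloc[j]) \
                < 3 * s2.iloc[j]["sd"]


class TestSpatialFieldRecovery:
    def test_field_hyperparameters_within_factor_two(self):
        """A simulated Matérn field (sd 1, range 15 km) on 80 spread-out
        sites is recovered with posterior medians within a factor of two
        (the accepted weak-identifiability tolerance for range)."""
        cfg = SimConfig(
            sites_per_location=(14, 14, 13, 13, 13, 13),
            censuses_per_site_year=10, years=(2003,),
            late_start_locations=(),
            beta_bin={"intercept": 3.0},
            beta_gam={"intercept": -1.0, "rugosity": 0.3},
            year_effects={}, observer_sd=0.0,
            spatial=SpatialFieldParams(1.0, 15.0), mode="continuous")
        cov = simulate_covariates(cfg, 21)
        layout = np.random.default_rng(99)
        cov["x_km"] = layout.uniform(0, 100, len(cov))
        cov["y_km"] = layout.uniform(0, 100, len(cov))
        rec, truth = simulate_surveys(cfg, cov, 21)
        spec = HurdleSpec(terms=("rugosity",),
                          include_observer_effect=False,
                          include_year_factor=False,
                          include_spatial_field=True)
        fit = fit_hurdle(rec, cov, spec, seed=4, draws=600, warmup=1500,
                         thin=3)
        sd_med = np.median(fit.density.draws["sigma_w"])
        rg_med = np.median(fit.density.draws["range_w"])
        assert 0.5 <= sd_med <= 2.0
        assert 7.5 <= rg_med <= 30.0
        w_true = np.array([truth.field_gam["juvenile"][s]
                           for s in fit.site_ids])
        w_post = fit.density.draws["w"].mean(axis=0)
        assert np.corrcoef(w_true, w_post)[0, 1] > 0.8


@pytest.fixture(scope="module")
def fitted_hurdle():
    cfg = SimConfig(
        sites_per_location=(4, 4, 4, 4, 5, 4), censuses_per_site_year=20,
        years=(2003,), late_start_locations=(),
        beta_bin={"intercept": -0.5, "rugosity": 0.8, "depth_m": -0.5,
                  "cca": 0.4},
        beta_gam={"intercept": -1.9, "rugosity": 0.4, "depth_m": -0.3,
                  "cca": 0.25},
        year_effects={}, observer_sd=0.0, spatial=None, mode="continuous")
    cov = simulate_covariates(cfg, 11)
    rec, _ = simulate_surveys(cfg, cov, 11)
    spec = HurdleSpec(terms=("rugosity", "depth_m", "cca"), **NOFRILLS)
    fit = fit_hurdle(rec, cov, spec, seed=7, draws=400, warmup=600)
    return fit, cov


class TestPrediction:
    def test_grid_probability_and_delta_inequality(self, fitted_hurdle):
        fit, cov = fitted_hurdle
        g = predict_grid(fit, cov, mode="period-mean")
        t = g.table
        assert ((t["p"] >= 0) & (t["p"] <= 1)).all()
        assert (t["expected"] <= t["mu"] + 1e-12).all()

    def test_covariate_monotonicity_through_link(self, fitted_hurdle):
        # raising a covariate with positive posterior-mean coefficient
        # (field off, everything else fixed) cannot lower presence
        fit, cov = fitted_hurdle
        lo = cov.copy()
        hi = cov.copy()
        lo["cca"], hi["cca"] = 0.05, 0.60
        p_lo = predict_grid(fit, lo, mode="period-mean").table["p"]
        p_hi = predict_grid(fit, hi, mode="period-mean").table["p"]
        b = fit.presence.summary.set_index("term").at["cca", "mean"]
        assert b > 0
        assert (p_hi >= p_lo - 1e-12).all()

    def test_missing_covariate_cell_flagged_not_imputed(self, fitted_hurdle):
        fit, cov = fitted_hurdle
        grid = cov.copy()
        grid.loc[grid.index[0], "cca"] = np.nan
        g = predict_grid(fit, grid, mode="period-mean")
        assert bool(g.table.loc[0, "missing"])
        assert np.isnan(g.table.loc[0, "expected"])
        assert g.table["missing"].sum() == 1

    def test_all_missing_grid_rejected(self, fitted_hurdle):
        fit, cov = fitted_hurdle
        grid = cov.copy()
        grid["cca"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            predict_grid(fit, grid, mode="period-mean")


class TestHotspots:
    def test_uniform_grid_all_tie(self, fitted_hurdle):
        fit, cov = fitted_hurdle
        g = predict_grid(fit, cov, mode="period-mean")
        g.table["expected"] = 1.0
        assert hotspot_cells(g, 0.9).all()

    def test_exact_top_decile_count(self, fitted_hurdle):
        fit, cov = fitted_hurdle
        g = predict_grid(fit, cov, mode="period-mean")
        vals = np.arange(100, dtype=float)
        g.table = pd.DataFrame({"x_km": vals, "y_km": vals,
                                "p": 0.5, "mu": vals, "expected": vals,
                                "missing": False})
        mask = hotspot_cells(g, 0.9)
        assert mask.sum() == 10

    def test_mask_shrinks_with_quantile(self, fitted_hurdle):
        fit, cov = fitted_hurdle
        g = predict_grid(fit, cov, mode="period-mean")
        m1 = hotspot_cells(g, 0.5)
        m2 = hotspot_cells(g, 0.9)
        assert m2.sum() <= m1.sum()
        assert np.all(m1[m2])   # higher-quantile cells nest in lower
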
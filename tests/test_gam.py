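"""Spline bases, penalized IRLS, smoothness selection, effects, diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from batnight import gam


def _pwls(X, S, y, lam):
    """Penalized least-squares oracle (Gaussian) for basis checks."""
    p = X.shape[1]
    Sfull = np.zeros((p, p))
    Sfull[1:, 1:] = lam * S
    return np.linalg.solve(X.T @ X + Sfull, X.T @ y)


class TestThinPlateBasis:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.x = rng.uniform(0, 1, 400)
        self.tab = pd.DataFrame({"x": self.x})
        self.block = gam.build_term(gam.SmoothSpec(("x",), "thin_plate", 8), self.tab)

    def test_penalty_rank_is_k_minus_2(self):
        ev = np.linalg.eigvalsh(self.block.penalties[0])
        assert int(np.sum(ev > ev.max() * 1e-9)) == 6

    @pytest.mark.parametrize("lam", [0.0, 1.0, 1e8])
    def test_line_recovered_exactly_for_any_lambda(self, lam):
        X = np.column_stack([np.ones_like(self.x), self.block.columns(self.tab)])
        y = 1.5 + 2.0 * self.x
        beta = _pwls(X, self.block.penalties[0], y, lam)
        assert np.abs(X @ beta - y).max() < 1e-8

    def test_infinite_smoothing_converges_to_least_squares_line(self):
        y = np.sin(6 * self.x)
        X = np.column_stack([np.ones_like(self.x), self.block.columns(self.tab)])
        beta = _pwls(X, self.block.penalties[0], y, 1e12)
        fit = X @ beta
        ols = sm.OLS(y, sm.add_constant(self.x)).fit().fittedvalues
        assert np.abs(fit - ols).max() < 1e-4

    def test_too_few_distinct_values_raises(self):
        tab = pd.DataFrame({"x": np.tile([0.0, 1.0, 2.0], 10)})
        with pytest.raises(gam.GamError, match="distinct"):
            gam.build_term(gam.SmoothSpec(("x",), "thin_plate", 5), tab)


class TestCyclicBasis:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.tab = pd.DataFrame({"p": rng.uniform(0, 360, 300)})
        self.block = gam.build_term(
            gam.SmoothSpec(("p",), "cyclic_cubic", 8, (0.0, 360.0)), self.tab)

    def _f(self, beta):
        def f(v):
            return float((self.block.columns(pd.DataFrame({"p": [v]})) @ beta)[0])
        return f

    def test_wraparound_continuity_of_value_slope_curvature(self):
        rng = np.random.default_rng(2)
        beta = rng.normal(size=self.block.ncols)
        f = self._f(beta)
        eps = 1e-4
        assert abs(f(0.0) - f(360.0)) < 1e-9
        d0 = (f(eps) - f(0.0)) / eps
        d1 = (f(360.0) - f(360.0 - eps)) / eps
        assert abs(d0 - d1) < 1e-5
        dd0 = (f(2 * eps) - 2 * f(eps) + f(0.0)) / eps ** 2
        dd1 = (f(360.0) - 2 * f(360.0 - eps) + f(360.0 - 2 * eps)) / eps ** 2
        assert abs(dd0 - dd1) < 1e-4

    def test_constant_function_has_zero_roughness(self):
        # in the uncentered parameterization a constant is gamma = 1
        _, F, S_raw = gam._cyclic_machinery(8, (0.0, 360.0))
        assert np.abs(S_raw @ np.ones(8)).max() < 1e-10
        assert np.abs(F @ np.ones(8)).max() < 1e-10   # zero second derivatives

    def test_k_below_4_rejected(self):
        with pytest.raises(gam.GamError, match="k >= 4"):
            gam.SmoothSpec(("p",), "cyclic_cubic", 3, (0.0, 360.0))

    def test_interpolation_error_shrinks_with_k(self):
        x = np.linspace(0, 360, 721)
        target = np.sin(np.radians(x)) + 0.3 * np.cos(2 * np.radians(x))
        errs = []
        for k in (5, 12, 24):
            tab = pd.DataFrame({"p": x})
            block = gam.build_term(
                gam.SmoothSpec(("p",), "cyclic_cubic", k, (0.0, 360.0)), tab)
            X = np.column_stack([np.ones_like(x), block.columns(tab)])
            beta, *_ = np.linalg.lstsq(X, target, rcond=None)
            errs.append(np.abs(X @ beta - target).max())
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-3


class TestTensorBasis:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.tab = pd.DataFrame({"lon": rng.uniform(2.5, 5.0, 300),
                                 "lat": rng.uniform(51.5, 53.5, 300)})
        self.block = gam.build_term(
            gam.SmoothSpec(("lon", "lat"), "tensor", (5, 5)), self.tab)

    def test_column_count_is_product_minus_constraint(self):
        assert self.block.ncols == 5 * 5 - 1
        assert len(self.block.penalties) == 2

    def test_bilinear_surface_recovered_for_any_lambda(self):
        lon = self.tab["lon"].to_numpy()
        lat = self.tab["lat"].to_numpy()
        y = 1.0 + 0.5 * lon - 0.3 * lat + 0.2 * lon * lat   # tensor null space
        X = np.column_stack([np.ones_like(lon), self.block.columns(self.tab)])
        p = X.shape[1]
        S = np.zeros((p, p))
        for lam, Sj in zip((50.0, 2000.0), self.block.penalties):
            S[1:, 1:] += lam * Sj
        beta = np.linalg.solve(X.T @ X + S, X.T @ y)
        assert np.abs(X @ beta - y).max() < 1e-6

    def test_non_finite_coordinates_rejected(self):
        bad = self.tab.copy()
        bad.loc[0, "lon"] = np.nan
        with pytest.raises(gam.GamError, match="non-finite"):
            gam.build_term(gam.SmoothSpec(("lon", "lat"), "tensor", (5, 5)), bad)


def _logistic_data(n=800, seed=1):
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    eta = -1 + 0.8 * tab.x1 - 0.5 * tab.x2
    tab["y"] = (rng.uniform(size=n) < expit(eta)).astype(float)
    return tab


LINEAR_SPEC = (gam.SmoothSpec(("x1",), "linear"), gam.SmoothSpec(("x2",), "linear"))


class TestFitPirls:
    def test_matches_unpenalized_logistic_oracle(self):
        tab = _logistic_data()
        design = gam.assemble_design(tab, LINEAR_SPEC)
        model = gam.fit_pirls(design, np.zeros(0))
        X = sm.add_constant(np.column_stack([tab.x1 - tab.x1.mean(),
                                             tab.x2 - tab.x2.mean()]))
        ref = sm.GLM(tab.y, X, family=sm.families.Binomial()).fit()
        assert np.abs(model.beta - ref.params).max() < 1e-6

    def test_all_zero_response_does_not_crash(self):
        tab = pd.DataFrame({"y": np.zeros(60)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = gam.fit_pirls(gam.assemble_design(tab, ()), np.zeros(0))
        assert model.beta[0] < -5
        assert gam.predict_probability(model, tab).max() < 1e-3

    def test_single_factor_level_contributes_no_columns(self):
        tab = _logistic_data(200)
        tab["year"] = 2019
        spec = LINEAR_SPEC + (gam.SmoothSpec(("year",), "factor"),)
        design = gam.assemble_design(tab, spec)
        assert design.X.shape[1] == 3  # intercept + two linear terms

    def test_wrong_number_of_lambdas_rejected(self):
        tab = _logistic_data(200)
        design = gam.assemble_design(tab, LINEAR_SPEC)
        with pytest.raises(gam.GamError, match="smoothing parameters"):
            gam.fit_pirls(design, np.ones(3))


class TestSelectLambda:
    @staticmethod
    def _smooth_design(f, n=600, seed=4, noise_logit=None):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-2, 2, n)
        eta = f(x)
        tab = pd.DataFrame({"x": x,
                            "y": (rng.uniform(size=n) < expit(eta)).astype(float)})
        return gam.assemble_design(tab, (gam.SmoothSpec(("x",), "thin_plate", 8),))

    def test_single_point_grid_returned(self):
        design = self._smooth_design(lambda x: 0.5 * x)
        lam = gam.select_lambda(design, grid=(3.7,))
        assert np.allclose(lam, 3.7)

    def test_pure_noise_gets_heavy_smoothing(self):
        design = self._smooth_design(lambda x: np.zeros_like(x), seed=5)
        lam = gam.select_lambda(design)
        assert lam[0] >= np.asarray(gam.DEFAULT_LAMBDA_GRID)[-3]

    def test_strong_curvature_gets_light_smoothing(self):
        design = self._smooth_design(lambda x: 2.5 * np.sin(2.5 * x), n=4000, seed=6)
        lam = gam.select_lambda(design)
        grid = np.asarray(gam.DEFAULT_LAMBDA_GRID)
        assert lam[0] < grid[len(grid) // 2]


class TestPredictAndEffects:
    def test_eta_zero_gives_half_and_alpha_shifts_up(self):
        tab = _logistic_data(300, seed=7)
        design = gam.assemble_design(tab, LINEAR_SPEC)
        model = gam.fit_pirls(design, np.zeros(0))
        model.beta[:] = 0.0
        p0 = gam.predict_probability(model, tab)
        assert np.allclose(p0, 0.5)
        model.alpha = 1.95
        p1 = gam.predict_probability(model, tab, use_alpha=True)
        assert np.allclose(p1, expit(1.95))
        assert float(expit(1.95)) == pytest.approx(0.8754, abs=5e-4)
        assert (p1 >= p0).all()

    def test_probabilities_in_open_unit_interval(self, fitted_default):
        _, model = fitted_default
        curve = gam.effect_curve(model, "tailwind", np.linspace(-6, 6, 61))
        assert ((curve["probability"] > 0) & (curve["probability"] < 1)).all()
        assert (curve["lower"] <= curve["probability"]).all()
        assert (curve["probability"] <= curve["upper"]).all()

    def test_cyclic_effect_curve_closes_at_boundaries(self, fitted_default):
        _, model = fitted_default
        curve = gam.effect_curve(model, "lunar_phase", np.array([0.0, 360.0]))
        assert abs(curve["eta"].iloc[0] - curve["eta"].iloc[1]) < 1e-6

    def test_bands_widen_toward_sparse_grid_ends(self, fitted_default):
        _, model = fitted_default
        curve = gam.effect_curve(model, "tailwind", np.linspace(-7, 7, 101))
        width = np.log(curve["upper"] / (1 - curve["upper"])) \
            - np.log(curve["lower"] / (1 - curve["lower"]))
        mid = width.iloc[45:55].mean()
        assert width.iloc[0] > mid and width.iloc[-1] > mid

    def test_affine_rescaling_of_linear_covariate_is_invisible(self):
        tab = _logistic_data(500, seed=8)
        design = gam.assemble_design(tab, LINEAR_SPEC)
        model = gam.fit_pirls(design, np.zeros(0))
        p_ref = gam.predict_probability(model, tab)
        tab2 = tab.copy()
        tab2["x1"] = tab2["x1"] * 100.0 + 7.0
        design2 = gam.assemble_design(tab2, LINEAR_SPEC)
        model2 = gam.fit_pirls(design2, np.zeros(0))
        p2 = gam.predict_probability(model2, tab2)
        assert np.abs(p_ref - p2).max() < 1e-8

    def test_unseen_factor_level_rejected(self, fitted_default):
        scenario, model = fitted_default
        rows = scenario.night_table.head(3).copy()
        rows["year"] = 1999
        with pytest.raises(gam.GamError, match="unseen"):
            gam.predict_probability(model, rows)

    def test_shrinkage_limit_reduces_smooth_to_null_space(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-2, 2, 1500)
        eta = 1.2 * np.sin(2 * x)
        tab = pd.DataFrame({"x": x,
                            "y": (rng.uniform(size=1500) < expit(eta)).astype(float)})
        spec = (gam.SmoothSpec(("x",), "thin_plate", 8),)
        design = gam.assemble_design(tab, spec)
        heavy = gam.fit_pirls(design, np.array([1e10]))
        # compare with a plain linear-logit fit: same null space
        lin = gam.fit_pirls(gam.assemble_design(tab, (gam.SmoothSpec(("x",), "linear"),)),
                            np.zeros(0))
        eta_heavy = heavy.linear_predictor(tab)
        eta_lin = lin.linear_predictor(tab)
        assert np.abs(eta_heavy - eta_lin).max() < 1e-3


class TestFactorContrasts:
    def test_two_levels_reduce_to_wald_interval(self):
        rng = np.random.default_rng(10)
        n = 1200
        year = np.where(rng.uniform(size=n) < 0.5, 2019, 2020)
        eta = -1.0 + 0.8 * (year == 2020)
        tab = pd.DataFrame({"year": year,
                            "y": (rng.uniform(size=n) < expit(eta)).astype(float)})
        model = gam.fit_pirls(gam.assemble_design(
            tab, (gam.SmoothSpec(("year",), "factor"),)), np.zeros(0))
        out = gam.factor_contrasts(model, "year", seed=1)
        assert len(out) == 1
        z = 1.959963984540054
        assert out["upper"].iloc[0] - out["estimate"].iloc[0] == \
            pytest.approx(z * out["se"].iloc[0], rel=1e-9)

    def test_strongly_shifted_level_flagged(self):
        rng = np.random.default_rng(11)
        n = 3000
        year = rng.choice([2018, 2019, 2020], size=n)
        eta = -1.0 - 1.5 * (year == 2020)
        tab = pd.DataFrame({"year": year,
                            "y": (rng.uniform(size=n) < expit(eta)).astype(float)})
        model = gam.fit_pirls(gam.assemble_design(
            tab, (gam.SmoothSpec(("year",), "factor"),)), np.zeros(0))
        out = gam.factor_contrasts(model, "year", seed=2)
        flagged = out.loc[out["significant"]]
        assert set(flagged["level_2"]) == {"2020"}
        assert len(flagged) == 2

    def test_single_level_rejected(self):
        tab = pd.DataFrame({"year": [2019] * 50, "y": [0.0, 1.0] * 25})
        model = gam.fit_pirls(gam.assemble_design(
            tab, (gam.SmoothSpec(("year",), "factor"),)), np.zeros(0))
        with pytest.raises(gam.GamError, match="levels"):
            gam.factor_contrasts(model, "year")


class TestDunnSmythResiduals:
    def test_same_seed_reproduces_and_respects_outcome_side(self):
        tab = _logistic_data(400, seed=12)
        model = gam.fit_pirls(gam.assemble_design(tab, LINEAR_SPEC), np.zeros(0))
        r1 = gam.dunn_smyth_residuals(model, tab, rng_seed=5)
        r2 = gam.dunn_smyth_residuals(model, tab, rng_seed=5)
        assert np.array_equal(r1, r2)
        # at p-hat = 0.5 a positive outcome yields a positive residual
        model.beta[:] = 0.0
        r = gam.dunn_smyth_residuals(model, tab, rng_seed=6)
        assert (r[tab["y"].to_numpy() == 1] > 0).all()
        assert (r[tab["y"].to_numpy() == 0] < 0).all()


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, fitted_default, tmp_path):
        scenario, model = fitted_default
        model.alpha = 1.2
        path = tmp_path / "model.json"
        model.to_json(path)
        back = gam.GamModel.from_json(path)
        tab = model.complete_cases(scenario.night_table)
        p1 = gam.predict_probability(model, tab, use_alpha=True)
        p2 = gam.predict_probability(back, tab, use_alpha=True)
        assert np.abs(p1 - p2).max() < 1e-12
        assert back.alpha == 1.2
        model.alpha = 0.0
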
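"""CCD generation, quadratic OLS fit, ANOVA bookkeeping, optimum location."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fermopt import (
    FactorMapping,
    QuadraticModel,
    ResponseSurfaceRegressor,
    constrained_optimum,
    datasets,
    fit_quadratic,
    generate_ccd,
    infer_steps,
    stationary_point,
    surface_grid,
)
from fermopt.rsm import DEFAULT_FACTORS, quadratic_design_matrix, quadratic_terms


class TestGenerateCCD:
    def test_k3_matches_published_design(self):
        design = generate_ccd(3, alpha=1.682, n_center=6)
        assert design.n_runs == 20
        assert design.roles.count("factorial") == 8
        assert design.roles.count("axial") == 6
        assert design.roles.count("center") == 6
        table = datasets.load_ccd_runs(exact_alpha=False)
        got = np.array(sorted(map(tuple, np.round(design.coded, 3))))
        want = np.array(sorted(map(tuple, table[["x1", "x2", "x3"]].to_numpy())))
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_k2_run_count(self):
        assert generate_ccd(2, alpha=1.414, n_center=1).n_runs == 9

    def test_axial_rows_have_norm_alpha(self):
        design = generate_ccd(3, n_center=2)
        axial = design.coded[[r == "axial" for r in design.roles]]
        np.testing.assert_allclose(np.linalg.norm(axial, axis=1),
                                   design.alpha, atol=1e-12)
        assert design.alpha == pytest.approx(2 ** 0.75)

    def test_shuffle_is_seeded_and_complete(self):
        a = generate_ccd(3, n_center=6, shuffle_seed=5)
        b = generate_ccd(3, n_center=6, shuffle_seed=5)
        c = generate_ccd(3, n_center=6)
        np.testing.assert_array_equal(a.coded, b.coded)
        assert sorted(map(tuple, a.coded)) == sorted(map(tuple, c.coded))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_ccd(1)
        with pytest.raises(ValueError):
            generate_ccd(3, n_center=0)
        with pytest.raises(ValueError):
            generate_ccd(3, alpha=-1.0)


class TestFactorMapping:
    def test_roundtrip_identity(self):
        fm = FactorMapping("lactose", 5.0, 2.0)
        x = np.array([-1.682, -1.0, 0.0, 1.0, 1.682])
        np.testing.assert_allclose(fm.code(fm.uncode(x)), x, atol=1e-12)

    def test_step_must_be_positive(self):
        with pytest.raises(ValueError):
            FactorMapping("f", 0.0, 0.0)


class TestFit:
    def test_noiseless_beta_recovered(self):
        design = generate_ccd(3, n_center=6)
        beta = np.array([1.0, 0.5, -0.2, 0.3, 0.1, -0.4, 0.25, -0.6, 0.7, -0.1])
        y = quadratic_design_matrix(design.coded) @ beta
        fit = fit_quadratic(design.coded, y)
        np.testing.assert_allclose(fit.model_.coef, beta, atol=1e-10)
        assert fit.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, ccd_fit, ccd_table):
        X = ccd_table[["x1", "x2", "x3"]].to_numpy()
        y = ccd_table["response"].to_numpy()
        M = quadratic_design_matrix(X)
        oracle = np.linalg.inv(M.T @ M) @ M.T @ y
        np.testing.assert_allclose(ccd_fit.model_.coef, oracle, atol=1e-8)

    def test_matches_statsmodels_oracle(self, ccd_fit, ccd_table):
        sm = pytest.importorskip("statsmodels.api")
        M = quadratic_design_matrix(ccd_table[["x1", "x2", "x3"]].to_numpy())
        res = sm.OLS(ccd_table["response"].to_numpy(), M).fit()
        np.testing.assert_allclose(ccd_fit.model_.coef, res.params, atol=1e-8)
        assert ccd_fit.r2_ == pytest.approx(res.rsquared, abs=1e-10)
        assert ccd_fit.r2_adj_ == pytest.approx(res.rsquared_adj, abs=1e-10)

    def test_residuals_orthogonal_to_model_columns(self, ccd_fit):
        proj = ccd_fit.model_matrix_.T @ ccd_fit.residuals_
        np.testing.assert_allclose(proj, 0.0, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        design = generate_ccd(3, n_center=6).coded.copy()
        design[:, 2] = design[:, 1]  # x3 duplicates x2
        with pytest.raises(ValueError, match="collinear"):
            fit_quadratic(design, np.arange(20.0))

    def test_too_few_runs(self):
        with pytest.raises(ValueError, match="runs"):
            fit_quadratic(np.zeros((5, 3)), np.zeros(5))


class TestAnova:
    def test_published_table_reproduced(self, ccd_fit):
        """Full refit of the 20-run design reproduces the published ANOVA."""
        t = ccd_fit.anova_.set_index("source")
        assert round(float(t.loc["model", "F"]), 2) == 35.35
        assert round(float(t.loc["x2", "F"]), 2) == 233.93
        assert round(float(t.loc["x3", "F"]), 2) == 38.93
        assert round(float(t.loc["lack_of_fit", "F"]), 2) == 11.15
        assert float(t.loc["pure_error", "SS"]) == pytest.approx(1.15e-5,
                                                                 abs=5e-8)
        assert int(t.loc["pure_error", "df"]) == 5
        assert round(ccd_fit.r2_, 4) == 0.9695
        assert round(ccd_fit.r2_adj_, 4) == 0.9421
        assert round(ccd_fit.r2_pred_, 4) == 0.7826

    def test_pure_error_matches_center_replicates(self, ccd_fit, ccd_table):
        centers = ccd_table[(ccd_table[["x1", "x2", "x3"]] == 0).all(axis=1)]
        y = centers["response"].to_numpy()
        ss_pe = float(((y - y.mean()) ** 2).sum())
        t = ccd_fit.anova_.set_index("source")
        assert float(t.loc["pure_error", "SS"]) == pytest.approx(ss_pe,
                                                                 rel=1e-12)

    def test_sum_of_squares_additivity(self, ccd_fit):
        t = ccd_fit.anova_.set_index("source")
        assert (float(t.loc["model", "SS"]) + float(t.loc["residual", "SS"])
                == pytest.approx(float(t.loc["total", "SS"]), rel=1e-10))
        assert (float(t.loc["lack_of_fit", "SS"])
                + float(t.loc["pure_error", "SS"])
                == pytest.approx(float(t.loc["residual", "SS"]), rel=1e-10))
        assert int(t.loc["model", "df"]) == 9
        assert int(t.loc["residual", "df"]) == 10

    def test_press_equals_explicit_leave_one_out(self, ccd_fit, ccd_table):
        X = ccd_table[["x1", "x2", "x3"]].to_numpy()
        y = ccd_table["response"].to_numpy()
        press = 0.0
        for i in range(len(y)):  # brute-force LOO refits
            keep = np.ones(len(y), bool)
            keep[i] = False
            M = quadratic_design_matrix(X[keep])
            c, *_ = np.linalg.lstsq(M, y[keep], rcond=None)
            pred = quadratic_design_matrix(X[i:i + 1]) @ c
            press += float((y[i] - pred[0]) ** 2)
        assert ccd_fit.press_ == pytest.approx(press, abs=1e-8)

    def test_affine_recoding_invariance(self, ccd_fit, ccd_table):
        """R2, model F and predictions are unchanged by recoding factors."""
        X = ccd_table[["x1", "x2", "x3"]].to_numpy()
        y = ccd_table["response"].to_numpy()
        actual = np.column_stack([f.uncode(X[:, i])
                                  for i, f in enumerate(DEFAULT_FACTORS)])
        fit_a = fit_quadratic(actual, y, coded=False)
        assert fit_a.r2_ == pytest.approx(ccd_fit.r2_, abs=1e-8)
        assert fit_a.r2_pred_ == pytest.approx(ccd_fit.r2_pred_, abs=1e-8)
        ta = fit_a.anova_.set_index("source")
        tc = ccd_fit.anova_.set_index("source")
        assert float(ta.loc["model", "F"]) == pytest.approx(
            float(tc.loc["model", "F"]), rel=1e-8)
        np.testing.assert_allclose(fit_a.fitted_values_,
                                   ccd_fit.fitted_values_, atol=1e-8)

    def test_exact_surface_gives_zero_residual(self):
        design = generate_ccd(3, n_center=3)
        beta = np.arange(10.0) / 10
        y = quadratic_design_matrix(design.coded) @ beta
        fit = fit_quadratic(design.coded, y)
        assert fit.ss_res_ == pytest.approx(0.0, abs=1e-20)
        assert fit.r2_ == pytest.approx(1.0, abs=1e-12)


class TestPredictAndOptimum:
    def test_origin_predicts_intercept(self, ccd_fit):
        assert ccd_fit.model_.predict([0, 0, 0]) == pytest.approx(
            ccd_fit.intercept_, abs=1e-12)

    def test_pure_square_model(self):
        m = QuadraticModel(k=1, coef=[0.0, 0.0, 1.0])
        assert m.predict([[2.0]]) == pytest.approx(4.0, abs=1e-12)

    def test_published_actual_units_equation_vs_horner(self, actual_units_coef):
        m = QuadraticModel(k=3, coef=actual_units_coef, coded=False)
        x1, x2, x3 = 5.0, 6.0, 20.0
        c = actual_units_coef
        horner = (c[0] + x1 * (c[1] + c[4] * x2 + c[5] * x3 + c[7] * x1)
                  + x2 * (c[2] + c[6] * x3 + c[8] * x2)
                  + x3 * (c[3] + c[9] * x3))
        assert m.predict([x1, x2, x3]) == pytest.approx(horner, abs=1e-12)

    def test_dimension_mismatch(self, ccd_fit):
        with pytest.raises(ValueError, match="dimension"):
            ccd_fit.model_.predict([1.0, 2.0])

    def test_concave_bowl_stationary_maximum(self):
        # Y = -(x^2 + y^2 + z^2)
        m = QuadraticModel(k=3, coef=[0, 0, 0, 0, 0, 0, 0, -1, -1, -1])
        point, kind = stationary_point(m)
        np.testing.assert_allclose(point, 0.0, atol=1e-12)
        assert kind == "maximum"

    def test_frozen_yeast_extract_optimum(self, actual_units_coef):
        """With lactose at 5 and NaCl at 20 g/L the yeast-extract optimum
        of the published equation sits near 11.9 g/L."""
        m = QuadraticModel(k=3, coef=actual_units_coef, coded=False)
        point, kind = stationary_point(m, frozen={0: 5.0, 2: 20.0})
        c = actual_units_coef
        oracle = (c[2] + c[4] * 5.0 + c[6] * 20.0) / (-2 * c[8])  # 1-D solve
        assert point[1] == pytest.approx(oracle, abs=1e-10)
        assert round(point[1], 1) == 11.9
        assert kind == "maximum"

    def test_singular_hessian_raises(self):
        m = QuadraticModel(k=2, coef=[0.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            stationary_point(m)

    def test_interior_concave_optimum_found_exactly(self):
        m = QuadraticModel(k=2, coef=[1.0, 0.4, -0.6, 0.0, -1.0, -1.0])
        point, value = constrained_optimum(m)
        expect, _ = stationary_point(m)
        np.testing.assert_allclose(point, expect, atol=1e-12)
        assert value == pytest.approx(float(m.predict(expect)), abs=1e-12)

    def test_linear_model_optimum_at_vertex(self):
        m = QuadraticModel(k=2, coef=[0.0, 1.0, -2.0, 0.0, 0.0, 0.0])
        point, _ = constrained_optimum(m, bounds=[(-1, 1), (-1, 1)])
        np.testing.assert_allclose(point, [1.0, -1.0], atol=1e-6)

    def test_boundary_optimum_agrees_with_dense_grid(self, ccd_fit):
        point, value = constrained_optimum(ccd_fit, grid=41)
        axes = [np.linspace(-1.682, 1.682, 201)] * 3
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([g.ravel() for g in mesh])
        vals = quadratic_design_matrix(pts) @ ccd_fit.model_.coef
        cell = (1.682 * 2) / 200
        assert value >= vals.max() - 1e-12
        np.testing.assert_allclose(point, pts[int(np.argmax(vals))],
                                   atol=cell + 1e-9)


class TestStepRecoveryAndGrids:
    def test_steps_recovered_from_published_equation(self, ccd_fit,
                                                     actual_units_coef):
        actual = QuadraticModel(k=3, coef=actual_units_coef, coded=False)
        steps = infer_steps(ccd_fit, actual)
        np.testing.assert_allclose(steps, [2.0, 3.0, 10.0], rtol=0.01)

    def test_coded_refit_matches_published_equation_recoded(
            self, ccd_fit, actual_units_coef):
        # push the coded fit through the default factor mapping and compare
        # with the published actual-units coefficients at printed precision
        X = np.column_stack([f.uncode(ccd_fit.design_[:, i])
                             for i, f in enumerate(DEFAULT_FACTORS)])
        refit = fit_quadratic(X, ccd_fit.response_, coded=False)
        np.testing.assert_allclose(refit.model_.coef, actual_units_coef,
                                   rtol=5e-4, atol=1e-6)

    def test_surface_grid_matches_predict(self, ccd_fit):
        grid = surface_grid(ccd_fit, 0, 1, frozen={2: 0.0}, num=5)
        assert len(grid) == 25
        pts = np.column_stack([grid["x1"], grid["x2"], np.zeros(len(grid))])
        np.testing.assert_allclose(grid["predicted"],
                                   ccd_fit.predict(pts), atol=1e-12)

    def test_quadratic_terms_order(self):
        assert quadratic_terms(2) == ["intercept", "x1", "x2", "x1:x2",
                                      "x1^2", "x2^2"]

    def test_model_json_roundtrip(self, ccd_fit):
        m = QuadraticModel.from_json(ccd_fit.model_.to_json())
        pts = np.array([[0.3, -1.2, 0.8], [1.682, 0, -1.682]])
        np.testing.assert_allclose(m.predict(pts),
                                   ccd_fit.model_.predict(pts), atol=1e-12)
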
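import numpy as np
import pytest

from formuopt.design import ResponseTable, generate_plackett_burman
from formuopt.oracle import EQ3_Y1, EQ4_Y2, generate_doe_dataset, load_fixture
from formuopt.rsm import (
    QuadraticModel,
    anova,
    fit_quadratic,
    quadratic_design_matrix,
    screen_effects,
)


def _normal_equations_solve(M, y):
    """Independent oracle: explicit normal-equations least squares."""
    return np.linalg.solve(M.T @ M, M.T @ y)


class TestPredict:
    def test_eq3_at_optimum_setting(self):
        assert EQ3_Y1.predict([1.5, 0.2, 0.5]) == pytest.approx(83.1, abs=0.05)

    def test_eq3_at_center(self):
        # hand evaluation of the printed polynomial at (1, 0.1, 1)
        assert EQ3_Y1.predict([1, 0.1, 1]) == pytest.approx(30.459, abs=1e-9)

    def test_zero_model(self):
        zero = QuadraticModel.from_coefficients(np.zeros(10))
        assert zero.predict([3.0, -2.0, 7.5]) == 0.0

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError):
            EQ3_Y1.predict([1.0, 2.0])

    def test_vectorized_matches_scalar(self, rng):
        X = rng.uniform(0, 2, size=(7, 3))
        vec = EQ4_Y2.predict(X)
        for i in range(7):
            assert vec[i] == pytest.approx(EQ4_Y2.predict(X[i]))


class TestFitQuadratic:
    def test_noise_free_recovery(self, ccd_design):
        resp = generate_doe_dataset(ccd_design, EQ4_Y2, noise_sd=0.0)
        model = fit_quadratic(ccd_design, resp, "Y", block_handling="ignore")
        np.testing.assert_allclose(model.coefficients, EQ4_Y2.coefficients, atol=1e-6)

    def test_recovery_matches_normal_equations_oracle(self, ccd_design, rng):
        resp = generate_doe_dataset(ccd_design, EQ3_Y1, noise_sd=3.0, seed=11)
        model = fit_quadratic(ccd_design, resp, "Y", block_handling="ignore")
        M = quadratic_design_matrix(ccd_design.actual_array())
        y = resp.aligned_values(ccd_design, "Y")
        np.testing.assert_allclose(model.coefficients, _normal_equations_solve(M, y), atol=1e-8)

    def test_constant_response(self, ccd_design):
        codes = [p.code for p in ccd_design.points]
        resp = ResponseTable.from_arrays(codes, Y=np.full(20, 7.25))
        model = fit_quadratic(ccd_design, resp, "Y", block_handling="ignore")
        assert model.intercept == pytest.approx(7.25, abs=1e-9)
        np.testing.assert_allclose(model.coefficients[1:], 0.0, atol=1e-9)

    def test_unbiased_under_noise(self, ccd_design):
        reps, sd = 500, 5.0
        estimates = np.empty((reps, 10))
        for r in range(reps):
            resp = generate_doe_dataset(ccd_design, EQ4_Y2, noise_sd=sd, seed=r)
            estimates[r] = fit_quadratic(
                ccd_design, resp, "Y", block_handling="ignore"
            ).coefficients
        mean = estimates.mean(axis=0)
        se = estimates.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - EQ4_Y2.coefficients) < 3 * se + 1e-12)

    def test_convergence_as_noise_vanishes(self, ccd_design):
        errs = []
        for sd in (1.0, 0.1, 0.01):
            resp = generate_doe_dataset(ccd_design, EQ4_Y2, noise_sd=sd, seed=5)
            m = fit_quadratic(ccd_design, resp, "Y", block_handling="ignore")
            errs.append(np.abs(m.coefficients - EQ4_Y2.coefficients).max())
        assert errs[0] > errs[1] > errs[2]

    def test_coded_and_actual_scale_agree(self, ccd_design):
        resp = generate_doe_dataset(ccd_design, EQ4_Y2, noise_sd=2.0, seed=3)
        m_actual = fit_quadratic(ccd_design, resp, "Y", scale="actual")
        m_coded = fit_quadratic(ccd_design, resp, "Y", scale="coded")
        for p in ccd_design.points:
            assert m_actual.predict(np.array(p.actual_levels)) == pytest.approx(
                m_coded.predict(np.array(p.coded_levels)), abs=1e-9
            )

    def test_misaligned_responses_rejected(self, ccd_design):
        resp = ResponseTable.from_arrays(["AA01"], Y=[1.0])
        with pytest.raises(ValueError, match="missing"):
            fit_quadratic(ccd_design, resp, "Y")


class TestAnova:
    def test_printed_r_squared_arithmetic(self):
        table5 = load_fixture("table5_anova_y1").set_index("term")
        resid = table5.loc["Residual", "sum_sq"]
        total = table5.loc["Cor Total", "sum_sq"]
        assert round(1 - resid / total, 4) == 0.9706

    def test_printed_lof_pe_additivity(self):
        table5 = load_fixture("table5_anova_y1").set_index("term")
        assert table5.loc["Lack of Fit", "sum_sq"] + table5.loc["Pure Error", "sum_sq"] == (
            pytest.approx(table5.loc["Residual", "sum_sq"])
        )

    def test_decomposition_on_fixture_data(self, ccd_with_responses):
        design, resp = ccd_with_responses
        model = fit_quadratic(design, resp, "Y1")
        table = anova(design, resp, model, "Y1")
        table.check_consistency()
        assert table.df("Residual") == 9
        assert table.df("Lack of Fit") == 5
        assert table.df("Pure Error") == 4
        assert table.df("Cor Total") == 19
        # corrected total is a pure function of the printed responses
        assert table.sum_sq("Cor Total") == pytest.approx(11920.4, abs=0.1)

    def test_exact_quadratic_data(self, ccd_design):
        resp = generate_doe_dataset(ccd_design, EQ3_Y1, noise_sd=0.0)
        model = fit_quadratic(ccd_design, resp, "Y", block_handling="ignore")
        table = anova(ccd_design, resp, model, "Y")
        assert table.sum_sq("Residual") == pytest.approx(0.0, abs=1e-6)
        assert table.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_ss_additivity_with_noise(self, ccd_design):
        resp = generate_doe_dataset(ccd_design, EQ4_Y2, noise_sd=4.0, seed=9)
        model = fit_quadratic(ccd_design, resp, "Y")
        table = anova(ccd_design, resp, model, "Y")
        parts = table.sum_sq("Model") + table.sum_sq("Block") + table.sum_sq("Residual")
        assert parts == pytest.approx(table.sum_sq("Cor Total"), rel=1e-9)


class TestScreenEffects:
    @staticmethod
    def _pb_with_response(y):
        design = generate_plackett_burman(6)
        codes = [p.code for p in design.points]
        return design, ResponseTable.from_arrays(codes, Y=y)

    def test_single_active_factor(self):
        design = generate_plackett_burman(6)
        y = design.coded_array()[:, 0]
        _, resp = self._pb_with_response(y)
        effects = {e.factor: e.effect for e in screen_effects(design, resp, "Y")}
        assert effects["F1"] == pytest.approx(2.0)
        for name in ("F2", "F3", "F4", "F5", "F6"):
            assert effects[name] == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_gives_zero_effects(self):
        design, resp = self._pb_with_response(np.full(12, 3.3))
        for e in screen_effects(design, resp, "Y"):
            assert e.effect == pytest.approx(0.0, abs=1e-12)
            assert not e.significant

    def test_type_one_error_rate(self):
        design = generate_plackett_burman(6)
        codes = [p.code for p in design.points]
        rng = np.random.default_rng(404)
        flags = 0
        n_tables = 1000
        for _ in range(n_tables):
            resp = ResponseTable.from_arrays(codes, Y=rng.standard_normal(12))
            flags += sum(e.significant for e in screen_effects(design, resp, "Y", 0.05))
        rate = flags / (6 * n_tables)
        # 0.05 +/- generous Monte-Carlo margin (dummy-based SE is approximate)
        assert 0.02 < rate < 0.09

    def test_requires_pb_design(self, ccd_with_responses):
        design, resp = ccd_with_responses
        with pytest.raises(ValueError):
            screen_effects(design, resp, "Y1")
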
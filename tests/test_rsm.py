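"""Response-surface fitting, ANOVA partition, diagnostics, optimization."""

import numpy as np
import pytest

from nanopk.doe import make_inscribed_ccd
from nanopk.rsm import (ResponseSurfaceModel, Term, build_model_matrix,
                        full_quadratic)

BOUNDS2 = [("a", -1.0, 1.0), ("b", -1.0, 1.0)]


@pytest.fixture(scope="module")
def design2():
    return make_inscribed_ccd(BOUNDS2, n_center=4)


class TestModelMatrix:
    def test_center_row_is_intercept_only(self, ccd_design):
        M = build_model_matrix(ccd_design, full_quadratic(3))
        center = M[-1]
        assert center[0] == 1.0
        assert np.allclose(center[1:], 0.0)

    def test_quadratic_entry_at_axial_point(self, ccd_design):
        M = build_model_matrix(ccd_design, [Term.quadratic(0)])
        # std 10 is the high axial point of factor 1 at coded +2**0.75
        assert M[9, 1] == pytest.approx(2.8284, abs=5e-4)

    def test_full_quadratic_has_ten_columns(self, ccd_design):
        assert build_model_matrix(ccd_design, full_quadratic(3)).shape == (20, 10)

    def test_duplicate_terms_rejected(self, ccd_design):
        with pytest.raises(ValueError, match="duplicate"):
            build_model_matrix(ccd_design, [Term.linear(0), Term.linear(0)])


class TestFit:
    def test_constant_response(self, ccd_design):
        fit = ResponseSurfaceModel(
            ccd_design, np.full(20, 7.5), full_quadratic(3)).fit()
        assert fit.params["Intercept"] == pytest.approx(7.5)
        assert np.allclose(fit.params.iloc[1:], 0.0, atol=1e-10)
        assert fit.ss_resid == pytest.approx(0.0, abs=1e-16)

    def test_noiseless_recovery_is_exact(self, ccd_design):
        rng = np.random.default_rng(7)
        terms = full_quadratic(3)
        beta = rng.normal(size=len(terms))
        y = build_model_matrix(ccd_design, terms) @ beta
        fit = ResponseSurfaceModel(ccd_design, y, terms).fit()
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-9)

    def test_response_length_mismatch(self, ccd_design):
        with pytest.raises(ValueError, match="length"):
            ResponseSurfaceModel(ccd_design, np.ones(19))

    def test_rank_deficiency_names_terms(self):
        dup = make_inscribed_ccd(BOUNDS2, n_center=4)
        dup.coded[:, 1] = dup.coded[:, 0]  # force collinear factors
        y = np.arange(dup.n_runs, dtype=float)
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            ResponseSurfaceModel(dup, y, [Term.linear(0), Term.linear(1)]).fit()


class TestAnova:
    def test_decomposition_identities(self, reduced_fit):
        tab = reduced_fit.anova()
        total = tab.loc["total", "sum_of_squares"]
        assert (tab.loc["model", "sum_of_squares"]
                + tab.loc["residual", "sum_of_squares"]
                ) == pytest.approx(total, rel=1e-6)
        assert (tab.loc["lack_of_fit", "sum_of_squares"]
                + tab.loc["pure_error", "sum_of_squares"]
                ) == pytest.approx(tab.loc["residual", "sum_of_squares"],
                                   rel=1e-6)
        assert tab.loc["model", "df"] + tab.loc["residual", "df"] \
            == tab.loc["total", "df"]
        assert tab.loc["lack_of_fit", "df"] + tab.loc["pure_error", "df"] \
            == tab.loc["residual", "df"]

    def test_perfect_fit_has_zero_residual(self, ccd_design):
        terms = [Term.linear(0)]
        y = build_model_matrix(ccd_design, terms) @ np.array([3.0, 2.0])
        fit = ResponseSurfaceModel(ccd_design, y, terms).fit()
        tab = fit.anova()
        assert tab.loc["residual", "sum_of_squares"] == pytest.approx(0, abs=1e-18)
        assert tab.loc["model", "sum_of_squares"] == pytest.approx(
            tab.loc["total", "sum_of_squares"])

    def test_lack_of_fit_undefined_without_replicates(self):
        d = make_inscribed_ccd(BOUNDS2, n_center=1)
        y = np.random.default_rng(0).normal(size=d.n_runs)
        tab = ResponseSurfaceModel(d, y, [Term.linear(0)]).fit().anova()
        assert np.isnan(tab.loc["lack_of_fit", "sum_of_squares"])
        assert np.isnan(tab.loc["pure_error", "sum_of_squares"])


class TestDiagnostics:
    def test_perfect_fit_r2_family(self, ccd_design):
        terms = [Term.linear(0), Term.linear(1)]
        y = build_model_matrix(ccd_design, terms) @ np.array([1.0, 2.0, -1.0])
        fit = ResponseSurfaceModel(ccd_design, y, terms).fit()
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_press_equals_explicit_leave_one_out_refits(self, reduced_fit):
        """Brute-force LOO oracle: n refits, each predicting its left-out run."""
        model = reduced_fit.model
        X = model.exog
        y = model.response
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            press += (y[i] - X[i] @ beta) ** 2
        assert reduced_fit.press == pytest.approx(press, rel=1e-9)

    def test_ordering_of_r2_family(self, reduced_fit):
        assert reduced_fit.predicted_r2 <= reduced_fit.r2
        assert reduced_fit.adjusted_r2 <= reduced_fit.r2

    def test_adding_a_term_never_increases_residual_ss(self, ccd_design,
                                                       particle_size_table):
        y = particle_size_table["particle_size"].to_numpy()
        terms = [Term.linear(0)]
        prev = ResponseSurfaceModel(ccd_design, y, terms).fit().ss_resid
        for extra in [Term.linear(1), Term.quadratic(1), Term.linear(2),
                      Term.interaction(0, 1), Term.quadratic(0)]:
            terms = terms + [extra]
            cur = ResponseSurfaceModel(ccd_design, y, terms).fit().ss_resid
            assert cur <= prev + 1e-9
            prev = cur

    def test_normal_equations_agree_with_grid_rss_search(self, design2):
        """Coefficients minimize the RSS: brute-force grid on a 2-term model."""
        y = (1.5 + 0.8 * design2.coded[:, 0]
             + np.random.default_rng(3).normal(0, 0.1, design2.n_runs))
        fit = ResponseSurfaceModel(design2, y, [Term.linear(0)]).fit()
        b0s = np.linspace(0.5, 2.5, 201)
        b1s = np.linspace(-0.2, 1.8, 201)
        B0, B1 = np.meshgrid(b0s, b1s)
        rss = ((y[None, None, :] - B0[..., None]
                - B1[..., None] * design2.coded[None, None, :, 0]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        assert fit.params["Intercept"] == pytest.approx(B0[i, j], abs=0.011)
        assert fit.params["a"] == pytest.approx(B1[i, j], abs=0.011)


class TestReduce:
    def test_intercept_only_signal_drops_everything(self, ccd_design):
        rng = np.random.default_rng(11)
        y = 5.0 + rng.normal(0, 1.0, 20)
        red = ResponseSurfaceModel(ccd_design, y).fit().reduce(0.05)
        assert [t.kind for t in red.terms] == ["intercept"]

    def test_hierarchy_keeps_supported_linear_term(self, ccd_design,
                                                   particle_size_table):
        y = particle_size_table["particle_size"].to_numpy()
        red = ResponseSurfaceModel(ccd_design, y).fit().reduce(0.05)
        labels = {t.label() for t in red.terms}
        assert labels == {"Intercept", "x1", "x2", "x2^2"}
        # the linear sonication term alone is not significant...
        p_x2 = red.anova().loc[red.terms[2].label(
            red.model._factor_names()), "p"]
        assert p_x2 == pytest.approx(0.0859, abs=2e-3)
        # ...but stays because its quadratic is

    def test_elimination_is_deterministic(self, ccd_design):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        r1 = ResponseSurfaceModel(ccd_design, y).fit().reduce(0.05)
        r2 = ResponseSurfaceModel(ccd_design, y).fit().reduce(0.05)
        assert [t.label() for t in r1.terms] == [t.label() for t in r2.terms]


class TestPredictOptimize:
    def test_prediction_at_design_runs_matches_matrix_product(self, reduced_fit):
        X = reduced_fit.model.exog
        beta = reduced_fit.params.to_numpy()
        preds = reduced_fit.predict(reduced_fit.model.design.coded)
        assert np.allclose(preds, X @ beta)

    def test_center_prediction_is_the_intercept(self, reduced_fit):
        assert reduced_fit.predict([0.0, 0.0, 0.0]) == pytest.approx(
            reduced_fit.params["Intercept"])

    def test_interior_vertex_matches_closed_form(self, design2):
        # y = 2 - 0.6 x + 1.0 x^2 has its minimum at x = -b1/(2 b11) = 0.3
        terms = [Term.linear(0), Term.quadratic(0)]
        y = build_model_matrix(design2, terms) @ np.array([2.0, -0.6, 1.0])
        fit = ResponseSurfaceModel(design2, y, terms).fit()
        opt = fit.optimize("minimize")
        assert opt.optimum_coded[0] == pytest.approx(0.3, abs=1e-6)
        assert opt.predicted_response == pytest.approx(2 - 0.6 * 0.3 + 0.09,
                                                       abs=1e-9)

    def test_intercept_only_model_is_degenerate(self, design2):
        fit = ResponseSurfaceModel(design2, np.full(design2.n_runs, 4.0),
                                   [Term.intercept()]).fit()
        opt = fit.optimize("minimize")
        assert opt.degenerate
        assert opt.predicted_response == pytest.approx(4.0)
        assert np.allclose(opt.optimum_coded, 0.0)

    def test_desirability_bounds(self, reduced_fit):
        opt = reduced_fit.optimize("minimize")
        assert 0.0 <= opt.desirability <= 1.0
        assert (opt.optimum_coded >= opt.search_region[:, 0] - 1e-9).all()
        assert (opt.optimum_coded <= opt.search_region[:, 1] + 1e-9).all()


class TestRecoverySimulation:
    def test_coefficient_bias_and_se_match_ols_theory(self, ccd_design):
        """Estimates over replicated noisy simulations: bias ~ 0, SE ~ formula."""
        terms = [Term.intercept(), Term.linear(0), Term.quadratic(1)]
        beta = np.array([100.0, 20.0, -8.0])
        X = np.column_stack([t.evaluate(ccd_design.coded) for t in terms])
        sigma = 15.0
        theory_se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        rng = np.random.default_rng(42)
        est = []
        for _ in range(250):
            y = X @ beta + rng.normal(0, sigma, 20)
            est.append(ResponseSurfaceModel(
                ccd_design, y, terms).fit().params.to_numpy())
        est = np.asarray(est)
        mc_se_of_mean = est.std(axis=0, ddof=1) / np.sqrt(est.shape[0])
        assert (np.abs(est.mean(axis=0) - beta) < 3 * mc_se_of_mean + 1e-9).all()
        assert np.allclose(est.std(axis=0, ddof=1), theory_se, rtol=0.15)
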
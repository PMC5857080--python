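"""Quadratic surface fitting, ANOVA decomposition, and fit diagnostics.

Oracles are independent of the implementation: raw numpy lstsq refits
for per-term sums of squares, explicit leave-one-out refitting for
PRESS, and the published regression equations / predicted columns for
the two study tables.
"""

import numpy as np
import pytest

from rsmdeg import (
    Design,
    FactorDef,
    QuadraticFit,
    ResponseSet,
    anova,
    build_model_matrix,
    fit_quadratic,
    fit_summary,
    load_fixture,
    make_ccd,
    predict,
)
from rsmdeg.model import term_labels

# printed coded-unit regression equations for the two strains
EQ15 = load_fixture("eq_adl15")
EQ36 = load_fixture("eq_adl36")


def lstsq_fit(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def loo_press(X, y):
    """Explicit leave-one-out refitting oracle for PRESS."""
    out = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        beta = lstsq_fit(X[keep], y[keep])
        out += (y[i] - X[i] @ beta) ** 2
    return out


class TestModelMatrix:
    def test_shape_and_special_rows(self, adl15):
        X = build_model_matrix(adl15.design)
        assert X.shape == (30, 15)
        # a centre run maps to (1, 0...0)
        centre = [i for i, p in enumerate(adl15.design.points)
                  if p.role == "center"][0]
        assert X[centre, 0] == 1.0
        assert np.all(X[centre, 1:] == 0.0)

    def test_axial_row_squared_column(self):
        X = build_model_matrix(np.array([[0.0, 0.0, 0.0, -2.0]]))
        labels = term_labels(4)
        assert X[0, labels.index("D^2")] == 4.0
        assert np.all(X[0, labels.index("AB"):] == 0.0)


class TestFitQuadratic:
    def test_recovers_published_equation_adl15(self, adl15_fit):
        printed = EQ15.coefficients
        assert np.all(np.abs(adl15_fit.coefficients - printed) <= 0.01)

    def test_recovers_published_equation_adl36(self, adl36_fit):
        printed = EQ36.coefficients
        assert np.all(np.abs(adl36_fit.coefficients - printed) <= 0.01)
        assert adl36_fit.beta0 == pytest.approx(88.76, abs=0.01)
        assert adl36_fit.beta_lin[3] == pytest.approx(-15.95, abs=0.01)

    def test_predicted_column_reproduced(self, adl15, adl15_fit, adl36,
                                         adl36_fit):
        for table, fit in [(adl15, adl15_fit), (adl36, adl36_fit)]:
            yhat = predict(fit, table.design.coded_matrix)
            assert np.all(np.abs(yhat - table.predicted) <= 0.02)

    def test_run3_and_centre_predictions(self, adl15, adl15_fit):
        # run 3 is the single-axis NaCl -2 point; centre prediction is b0
        assert predict(adl15_fit, [0, 0, 0, -2.0]) == pytest.approx(32.88,
                                                                    abs=0.02)
        assert predict(adl15_fit, [0, 0, 0, 0]) == pytest.approx(
            adl15_fit.beta0)

    def test_noiseless_truth_recovered_exactly(self, factors):
        design = make_ccd(factors, alpha=2.0, n_center=6)
        y = predict(EQ36, design.coded_matrix)
        fit = fit_quadratic(design, y)
        assert np.allclose(fit.coefficients, EQ36.coefficients, atol=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)

    def test_hat_diag_sums_to_p_and_residuals_centered(self, adl15_fit):
        assert adl15_fit.hat_diag.sum() == pytest.approx(15.0)
        assert adl15_fit.residuals.sum() == pytest.approx(0.0, abs=1e-8)

    def test_too_few_runs_rejected(self, factors):
        design = make_ccd(factors[:2], alpha=1.0, n_center=1)  # 9 runs, p=6
        small = Design(design.factors, design.points[:5], kind="custom")
        with pytest.raises(ValueError, match="more runs"):
            fit_quadratic(small, np.ones(5))

    def test_rank_deficiency_names_terms(self, factors):
        # duplicate the same runs: squared terms become collinear
        design = make_ccd(factors[:2], alpha=1.0, n_center=1)
        pts = [p for p in design.points if abs(p.coded[0]) == 1.0]
        degenerate = Design(design.factors, (pts * 3)[:10], kind="custom")
        with pytest.raises(ValueError, match="rank deficient"):
            fit_quadratic(degenerate, np.ones(10))


class TestAnova:
    def test_ss_additivity(self, adl15, adl15_fit, adl36, adl36_fit):
        for table, fit in [(adl15, adl15_fit), (adl36, adl36_fit)]:
            rep = anova(table.design, table.response, fit)
            assert rep.model_row.ss + rep.residual_row.ss == pytest.approx(
                rep.cor_total_row.ss, abs=0.05)
            assert (rep.lack_of_fit_row.ss + rep.pure_error_row.ss
                    == pytest.approx(rep.residual_row.ss, abs=0.05))

    def test_partial_ss_equals_refit_oracle(self, adl15, adl15_fit):
        rep = anova(adl15.design, adl15.response, adl15_fit)
        X = build_model_matrix(adl15.design)
        y = adl15.response.y
        ss_full = float(np.sum((y - X @ lstsq_fit(X, y)) ** 2))
        labels = term_labels(4)
        for row in rep.rows:
            j = labels.index(row.term)
            Xr = np.delete(X, j, axis=1)
            ss_red = float(np.sum((y - Xr @ lstsq_fit(Xr, y)) ** 2))
            assert row.ss == pytest.approx(ss_red - ss_full, abs=1e-6)

    def test_pure_error_from_centre_replicates(self, adl15, adl15_fit):
        # six centre runs: 33.34, 32.01, 31.67, 30.45, 30.12, 26.83
        rep = anova(adl15.design, adl15.response, adl15_fit)
        assert rep.pure_error_row.ss == pytest.approx(24.98, abs=0.05)
        assert rep.pure_error_row.df == 5
        assert rep.lack_of_fit_row.df == 10

    def test_published_anova_rows_adl15(self, adl15, adl15_fit):
        rep = anova(adl15.design, adl15.response, adl15_fit)
        assert rep.model_row.f == pytest.approx(18.28, rel=1e-3, abs=0.01)
        assert rep.model_row.p < 1e-4
        d = rep.term("D")
        assert d.ss == pytest.approx(1042.93, rel=1e-3)
        assert d.f == pytest.approx(59.91, rel=1e-3, abs=0.01)
        assert rep.lack_of_fit_row.f == pytest.approx(4.73, abs=0.01)
        assert rep.lack_of_fit_row.p == pytest.approx(0.0502, abs=0.001)
        # significance pattern printed for this strain
        sig = {r.term for r in rep.rows if r.significant}
        assert sig == {"B", "C", "D", "A^2", "B^2", "C^2", "D^2", "BD"}

    def test_published_anova_rows_adl36(self, adl36, adl36_fit):
        rep = anova(adl36.design, adl36.response, adl36_fit)
        assert rep.model_row.f == pytest.approx(38.35, rel=1e-3, abs=0.01)
        bd = rep.term("BD")
        assert bd.f == pytest.approx(28.40, rel=1e-3, abs=0.01)
        assert bd.p < 1e-3
        assert rep.lack_of_fit_row.f == pytest.approx(3.56, abs=0.01)

    def test_noiseless_data_zero_residual_ss(self, factors):
        design = make_ccd(factors, alpha=2.0, n_center=6)
        y = predict(EQ15, design.coded_matrix)
        fit = fit_quadratic(design, y)
        rep = anova(design, y, fit)
        assert rep.residual_row.ss == pytest.approx(0.0, abs=1e-12)

    def test_no_replicates_warns_and_omits_lof(self, factors):
        design = make_ccd(factors, alpha=2.0, n_center=1)
        rng = np.random.default_rng(3)
        y = predict(EQ15, design.coded_matrix) + rng.normal(0, 1, 25)
        fit = fit_quadratic(design, y)
        with pytest.warns(UserWarning, match="lack-of-fit"):
            rep = anova(design, y, fit)
        assert rep.lack_of_fit_row is None


class TestFitSummary:
    def test_published_fit_statistics_adl15(self, adl15, adl15_fit):
        s = fit_summary(adl15.design, adl15.response, adl15_fit)
        assert s.r2 == pytest.approx(0.9446, abs=0.001)
        assert s.adj_r2 == pytest.approx(0.8930, abs=0.001)
        assert s.pred_r2 == pytest.approx(0.7040, abs=0.001)
        assert s.press == pytest.approx(1396.23, rel=1e-3)
        assert s.std_dev == pytest.approx(4.17, abs=0.01)
        assert s.mean == pytest.approx(14.32, abs=0.01)
        assert s.cv_percent == pytest.approx(29.13, abs=0.02)
        assert s.adeq_precision == pytest.approx(12.819, abs=0.01)

    def test_published_fit_statistics_adl36(self, adl36, adl36_fit):
        s = fit_summary(adl36.design, adl36.response, adl36_fit)
        assert s.r2 == pytest.approx(0.9728, abs=0.001)
        assert s.pred_r2 == pytest.approx(0.8579, abs=0.001)
        assert s.press == pytest.approx(4413.71, rel=1e-3)
        assert s.adeq_precision == pytest.approx(18.503, abs=0.01)

    def test_pred_r2_press_identity(self, adl15, adl15_fit):
        s = fit_summary(adl15.design, adl15.response, adl15_fit)
        ss_tot = np.sum((adl15.response.y - adl15.response.y.mean()) ** 2)
        assert s.pred_r2 == pytest.approx(1 - s.press / ss_tot)

    def test_press_equals_explicit_loo(self, adl15, adl36, factors):
        for table in (adl15, adl36):
            fit = fit_quadratic(table.design, table.response)
            s = fit_summary(table.design, table.response, fit)
            X = build_model_matrix(table.design)
            assert s.press == pytest.approx(
                loo_press(X, table.response.y), rel=1e-10)
        # and on random designs/responses
        rng = np.random.default_rng(11)
        for _ in range(5):
            design = make_ccd(factors, alpha=2.0, n_center=6)
            y = rng.normal(50, 10, design.n_runs)
            fit = fit_quadratic(design, y)
            s = fit_summary(design, y, fit)
            X = build_model_matrix(design)
            assert s.press == pytest.approx(loo_press(X, y), rel=1e-8)
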
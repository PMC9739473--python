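"""Fit, ANOVA decomposition and adequacy diagnostics of the quadratic surface.

The published study's printed coefficients and aggregate error sums of
squares serve as the worked example throughout; an independent statsmodels
OLS fit cross-checks the in-package solver on synthetic data.
"""

import numpy as np
import pandas as pd
import pytest

from rsmval import (
    DesignTable,
    QuadraticModel,
    ResponseSurfaceModel,
    ResponseSurfaceResults,
    construct_consistent_response,
    fit_quadratic,
    generate_bbd,
)
from rsmval.design import FactorSpec
from rsmval.exceptions import SingularDesignError
from rsmval.model import significance_flag


class TestPredict:
    def test_center_value_is_intercept(self, ref_model):
        assert ref_model.predict(np.zeros(3)) == pytest.approx(41.80)

    @pytest.mark.parametrize(
        "point,expected",
        [((0, -1, -1), 34.75), ((1, 1, 0), 23.0)],
    )
    def test_polynomial_evaluation(self, ref_model, point, expected):
        assert ref_model.predict(np.array(point, float)) == pytest.approx(expected)

    def test_non_finite_point_rejected(self, ref_model):
        with pytest.raises(ValueError):
            ref_model.predict(np.array([np.inf, 0, 0]))


class TestFit:
    def test_noiseless_response_interpolates(self, ref_model, ref_design):
        y = ref_model.predict(ref_design.coded())
        res = fit_quadratic(ref_design, y)
        assert res.ss_resid == pytest.approx(0, abs=1e-18)
        assert np.allclose(res.model.params, ref_model.params)

    def test_fitted_value_at_center_is_intercept(self, ref_design, rng):
        y = rng.uniform(20, 45, len(ref_design))
        res = fit_quadratic(ref_design, y)
        centers = ref_design.runs["point_type"] == "center"
        assert np.allclose(res.fitted[centers.to_numpy()], res.model.intercept)

    def test_consistent_response_round_trip(self, ref_model, ref_design, ref_aggregates):
        res_ss, pe_ss = ref_aggregates
        y = construct_consistent_response(ref_model, res_ss, pe_ss, ref_design, seed=7)
        refit = fit_quadratic(ref_design, y)
        assert np.allclose(refit.model.params, ref_model.params, rtol=0, atol=1e-10)

    def test_length_mismatch_rejected(self, ref_design):
        with pytest.raises(ValueError, match="length"):
            ResponseSurfaceModel(ref_design, np.ones(5))

    def test_rank_deficient_design_rejected(self):
        runs = pd.DataFrame(
            {
                "run_id": range(1, 13),
                "point_type": ["edge"] * 12,
                "A": [0.0] * 12,  # constant column: A, A^2 collinear w/ intercept
                "B": [-1, 1] * 6,
                "C": [1, -1] * 6,
            }
        )
        with pytest.raises(SingularDesignError):
            ResponseSurfaceModel(DesignTable(runs), np.ones(12)).fit()

    def test_matches_statsmodels_ols(self, ref_design, rng):
        """Independent oracle: statsmodels OLS on the same model matrix."""
        import statsmodels.api as sm

        y = rng.uniform(20, 45, len(ref_design))
        ours = fit_quadratic(ref_design, y)
        theirs = sm.OLS(y, ref_design.model_matrix()).fit()
        assert np.allclose(ours.model.params, theirs.params)
        assert ours.adequacy().r2 == pytest.approx(theirs.rsquared)
        assert ours.adequacy().adj_r2 == pytest.approx(theirs.rsquared_adj)
        assert np.allclose(ours.leverage, theirs.get_influence().hat_matrix_diag)


class TestAnova:
    """Type-III decomposition against the published ANOVA table."""

    # term -> (SS, F, p as printed); p "<0.0001" checked separately
    PRINTED = {
        "A": (2.0, 1.24, 0.3024),
        "B": (18.0, 11.15, 0.0124),
        "C": (60.5, 37.48, 0.0005),
        "AB": (1.0, 0.62, 0.4571),
        "AC": (4.0, 2.48, 0.1595),
        "BC": (0.0, 0.0, 1.0),
        "A2": (262.78, 162.78, None),
        "B2": (297.09, 184.04, None),
        "C2": (35.41, 21.94, 0.0023),
    }

    def test_per_term_rows_match_printed_table(self, ref_results):
        table = ref_results.anova()
        for term, (ss, f, p) in self.PRINTED.items():
            row = table.row(term)
            assert row["ss"] == pytest.approx(ss, abs=5e-3)
            assert row["F"] == pytest.approx(f, abs=5e-3)
            if p is not None:
                assert row["p_value"] == pytest.approx(p, abs=5e-5)
            else:
                assert row["p_value"] < 1e-4

    def test_model_row(self, ref_results):
        row = ref_results.anova().row("Model")
        assert row["ss"] == pytest.approx(737.76, abs=5e-3)
        assert row["df"] == 9
        assert row["F"] == pytest.approx(50.78, abs=5e-3)
        assert row["p_value"] < 1e-4

    def test_lack_of_fit_row(self, ref_results):
        row = ref_results.anova().row("Lack of fit")
        assert row["ss"] == pytest.approx(8.5)
        assert row["df"] == 3
        assert row["F"] == pytest.approx(4.05, abs=5e-3)
        assert row["p_value"] == pytest.approx(0.1051, abs=5e-5)

    def test_totals_are_consistent(self, ref_results):
        t = ref_results.anova()
        assert t.row("Cor total")["ss"] == pytest.approx(749.06, abs=5e-3)
        assert t.row("Cor total")["df"] == 16
        assert t.row("Residual")["ss"] == pytest.approx(
            t.row("Lack of fit")["ss"] + t.row("Pure error")["ss"]
        )

    def test_zero_coefficient_gives_zero_ss(self, ref_results):
        row = ref_results.anova().row("BC")
        assert row["ss"] == 0 and row["F"] == 0 and row["p_value"] == 1

    def test_significance_flags_follow_thresholds(self, ref_results):
        table = ref_results.anova().to_frame().set_index("term")
        assert table.loc["B", "flag"] == "*"
        assert table.loc["C", "flag"] == "**"
        assert table.loc["A", "flag"] == ""
        # p = 0.0023 < 0.01 takes two stars by the threshold rule
        assert table.loc["C2", "flag"] == "**"
        assert significance_flag(np.nan) == ""

    def test_quadratic_diagonal_closed_form(self, ref_design):
        """[(X'X)^-1] quadratic diagonal = 0.2375, via the 4x4 symmetric block."""
        block = np.array(
            [[17, 8, 8, 8], [8, 8, 4, 4], [8, 4, 8, 4], [8, 4, 4, 8]], dtype=float
        )
        closed = np.diag(np.linalg.inv(block))[1:]
        X = ref_design.model_matrix()
        design_based = np.diag(np.linalg.inv(X.T @ X))[7:]
        assert np.allclose(closed, 0.2375)
        assert np.allclose(design_based, closed)

    def test_raw_and_aggregate_paths_agree(self, ref_model, ref_design, ref_aggregates):
        res_ss, pe_ss = ref_aggregates
        y = construct_consistent_response(ref_model, res_ss, pe_ss, ref_design, seed=3)
        raw = fit_quadratic(ref_design, y).anova().to_frame()
        agg = ResponseSurfaceResults.from_aggregates(
            ref_model, ref_design, res_ss, pe_ss
        ).anova().to_frame()
        pd.testing.assert_frame_equal(raw, agg, atol=1e-9, rtol=0, check_exact=False)

    def test_linear_and_interaction_ss_are_additive(self, ref_results):
        """The orthogonal block of the design: first-order SS sum exactly.

        (Quadratic Type-III SS are partial and do not sum to the model SS.)
        """
        ss = ref_results.term_ss()
        first_order = ss[["A", "B", "C", "AB", "AC", "BC"]].sum()
        assert first_order == pytest.approx(85.5)
        assert ss.sum() < ref_results.ss_model  # partial SS under-count jointly

    def test_pure_error_exceeding_residual_rejected(self, ref_model, ref_design):
        with pytest.raises(ValueError, match="pure-error"):
            ResponseSurfaceResults.from_aggregates(ref_model, ref_design, 2.0, 5.0)

    def test_unreplicated_design_warns(self, ref_model):
        d = generate_bbd(
            [FactorSpec("A", 1, 3), FactorSpec("B", 1, 3), FactorSpec("C", 1, 3)],
            n_center=1,
        )
        y = ref_model.predict(d.coded()) + np.linspace(-1, 1, len(d))
        with pytest.warns(UserWarning, match="replicated"):
            fit_quadratic(d, y).anova()


class TestAdequacy:
    def test_r2_family_from_aggregates(self, ref_results):
        adq = ref_results.adequacy()
        assert adq.r2 == pytest.approx(0.9849, abs=5e-5)
        assert adq.adj_r2 == pytest.approx(0.9655, abs=5e-5)
        assert adq.pred_r2 is None and adq.press is None

    def test_adequate_precision(self, ref_results):
        assert ref_results.adequacy().adeq_precision == pytest.approx(19.293, abs=5e-4)
        assert ref_results.fitted.max() == pytest.approx(41.80)
        assert ref_results.fitted.min() == pytest.approx(23.0)

    def test_predicted_r2_from_constructed_response(
        self, ref_model, ref_design, ref_aggregates
    ):
        """PRESS is direction-invariant on this design (class-wise constant
        leverage), so the published predicted R² follows from the aggregates."""
        y = construct_consistent_response(ref_model, *ref_aggregates, ref_design, seed=11)
        adq = fit_quadratic(ref_design, y).adequacy()
        assert adq.press == pytest.approx(140.375, abs=1e-9)
        assert adq.pred_r2 == pytest.approx(0.8126, abs=5e-5)

    def test_ordering_invariant(self, ref_design, rng):
        y = rng.uniform(20, 45, len(ref_design))
        adq = fit_quadratic(ref_design, y).adequacy()
        assert adq.pred_r2 <= adq.adj_r2 <= adq.r2 <= 1

    def test_perfect_fit_degenerates_cleanly(self, ref_model, ref_design):
        y = ref_model.predict(ref_design.coded())
        adq = fit_quadratic(ref_design, y).adequacy()
        assert adq.r2 == pytest.approx(1) and adq.adj_r2 == pytest.approx(1)
        assert adq.press == pytest.approx(0, abs=1e-18)

    def test_orthogonal_noise_never_raises_r2(self, ref_model, ref_design):
        """Error added outside the model space inflates SS_res and SS_tot
        equally, so R² can only fall."""
        r2_prev = 1.0
        for scale in (1.0, 4.0, 16.0):
            y = construct_consistent_response(
                ref_model, scale * 11.3, scale * 2.8, ref_design, seed=5
            )
            r2 = fit_quadratic(ref_design, y).adequacy().r2
            assert r2 < r2_prev
            r2_prev = r2


def test_summary_reports_key_statistics(ref_model, ref_design, ref_aggregates):
    y = construct_consistent_response(ref_model, *ref_aggregates, ref_design, seed=1)
    text = fit_quadratic(ref_design, y).summary()
    assert "41.8000" in text  # intercept
    assert "R-squared" in text and "0.9849" in text
    assert "Adeq. precision" in text and "19.293" in text
    assert "<0.0001" in text


def test_quadratic_model_validates_param_count():
    with pytest.raises(ValueError):
        QuadraticModel.from_params(np.ones(9))
    with pytest.raises(ValueError):
        QuadraticModel(np.nan, (0, 0, 0), (0, 0, 0), (1, 1, 1))
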
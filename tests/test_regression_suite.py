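"""Screening diagnostics and the hierarchical logistic engine."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

from passnet.regression_suite import (
    SeparationError,
    classification_table,
    drop_zero_pass_sop,
    fit_logistic,
    hierarchical_fit,
    hosmer_lemeshow,
    model_report,
    nagelkerke_r2,
    odds_percent_change,
    odds_ratio,
    odds_ratio_ci,
    render_report,
    rescale_metrics,
    run_analysis,
    screen_collinearity,
    screen_outliers,
    test_logit_linearity as logit_linearity_pvalues,
)
from passnet.synthetic_match import simulate_network_cases


def bernoulli_frame(rng, n, logits, extra=None):
    df = pd.DataFrame(extra or {})
    df["outcome"] = (rng.random(n) < expit(logits)).astype(int)
    return df


class TestCollinearity:
    def test_orthogonal_design_has_unit_indexes_and_no_flags(self):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        rep = screen_collinearity(df, ["x1", "x2"])
        assert np.allclose(rep.condition_indexes, 1.0)
        assert rep.collinearity_flags == []

    def test_duplicated_predictor_flagged_with_infinite_index(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x1": x, "x2": x})
        rep = screen_collinearity(df, ["x1", "x2"])
        assert np.isinf(rep.condition_indexes).any() or rep.condition_indexes.max() > 1e10
        assert any({"x1", "x2"} <= set(vs) for _, vs in rep.collinearity_flags)

    def test_moderate_correlation_below_30_not_flagged(self, rng):
        x = rng.normal(size=200)
        y = 0.8 * x + 0.6 * rng.normal(size=200)
        df = pd.DataFrame({"x1": x, "x2": y})
        rep = screen_collinearity(df, ["x1", "x2"])
        finite = rep.condition_indexes[np.isfinite(rep.condition_indexes)]
        assert finite.max() < 30
        assert rep.collinearity_flags == []

    def test_variance_proportions_sum_to_one_and_indexes_ordered(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)) + 2.0, columns=["a", "b", "c"])
        rep = screen_collinearity(df, ["a", "b", "c"])
        sums = rep.variance_proportions.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-8)
        assert (rep.condition_indexes >= 1.0 - 1e-12).all()
        assert np.all(np.diff(np.sort(rep.condition_indexes)) >= 0)


class TestLinearity:
    def test_linear_logit_passes_in_at_least_ninety_percent(self):
        passed = 0
        reps = 500
        for s in range(reps):
            r = np.random.default_rng(1000 + s)
            x = r.uniform(1, 10, 300)
            df = bernoulli_frame(r, 300, -1 + 0.25 * x, {"x": x})
            passed += logit_linearity_pvalues(df, ["x"])["x"] > 0.05
        assert passed / reps >= 0.90

    def test_strong_curvature_detected_with_high_power(self):
        rejected = 0
        for s in range(100):
            r = np.random.default_rng(5000 + s)
            x = r.uniform(1, 10, 300)
            df = bernoulli_frame(r, 300, 4 - 2.0 * x + 0.22 * x**2, {"x": x})
            rejected += logit_linearity_pvalues(df, ["x"])["x"] <= 0.05
        assert rejected / 100 >= 0.9

    def test_all_interactions_reported_for_multiple_predictors(self, rng):
        n = 300
        d = {"total_passes": rng.poisson(20, n).astype(float), "density": rng.uniform(0, 0.3, n)}
        df = bernoulli_frame(rng, n, -0.5 + 0.05 * d["total_passes"], d)
        ps = logit_linearity_pvalues(df, ["total_passes", "density"])
        assert set(ps) == {"total_passes", "density"}

    def test_nonpositive_values_error_names_offset_convention(self, rng):
        df = pd.DataFrame({"x": [0.0, 1.0] * 20, "outcome": [0, 1] * 20})
        with pytest.raises(ValueError, match="offset"):
            logit_linearity_pvalues(df, ["x"], shift="none")


class TestOutlierScreen:
    def test_identical_cases_produce_no_outliers(self):
        df = pd.DataFrame({"x": [3.0] * 20})
        assert screen_outliers(df, ["x"]) == []

    def test_planted_five_sd_case_is_the_only_flag(self, rng):
        x = rng.normal(size=200)
        x[77] = x.mean() + 8 * x.std()
        df = pd.DataFrame({"x": x})
        assert screen_outliers(df, ["x"]) == [77]

    def test_boundary_z_score_excluded_by_strict_inequality(self):
        # the cutoff is strict: a case sitting exactly at the threshold is kept
        n = 100
        x = np.zeros(n)
        x[0] = 1.0
        df = pd.DataFrame({"x": x})
        z_max = float(((df["x"] - df["x"].mean()) / df["x"].std(ddof=1)).abs().max())
        assert screen_outliers(df, ["x"], threshold=z_max) == []
        assert screen_outliers(df, ["x"], threshold=z_max - 1e-9) == [0]


class TestCaseFilters:
    def test_zero_pass_successful_cases_removed(self):
        df = pd.DataFrame(
            {
                "outcome": [1, 1, 0, 1, 0],
                "total_passes": [0, 5, 0, 0, 3],
            }
        )
        out = drop_zero_pass_sop(df)
        assert len(out) == 3
        assert ((out["outcome"] == 1) & (out["total_passes"] == 0)).sum() == 0
        # zero-pass unsuccessful case retained
        assert ((out["outcome"] == 0) & (out["total_passes"] == 0)).sum() == 1

    def test_no_zero_pass_cases_is_identity(self):
        df = pd.DataFrame({"outcome": [1, 0], "total_passes": [4, 2]})
        pd.testing.assert_frame_equal(drop_zero_pass_sop(df), df)

    def test_rescale_multiplies_metrics_only(self):
        df = pd.DataFrame(
            {"outcome": [1], "total_passes": [7], "density": [0.25],
             "clustering": [0.4], "centralization": [0.1]}
        )
        out = rescale_metrics(df)
        assert out.loc[0, "density"] == 2.5
        assert out.loc[0, "clustering"] == 4.0
        assert out.loc[0, "total_passes"] == 7

    def test_double_rescale_refused(self):
        df = pd.DataFrame({"density": [0.2], "clustering": [0.1], "centralization": [0.3]})
        once = rescale_metrics(df)
        with pytest.raises(ValueError, match="twice"):
            rescale_metrics(once)

    def test_rescaled_fit_is_equivalent_up_to_beta_scaling(self, rng):
        n = 400
        d = rng.uniform(0, 1, n)
        df = pd.DataFrame({"density": d, "clustering": 0.0, "centralization": 0.0})
        df["outcome"] = (rng.random(n) < expit(-1 + 3 * d)).astype(int)
        raw = fit_logistic(df, ["density"])
        scaled = fit_logistic(rescale_metrics(df), ["density"])
        assert scaled.coef["density"] == pytest.approx(raw.coef["density"] / 10, rel=1e-6)
        assert scaled.loglik == pytest.approx(raw.loglik, abs=1e-8)


class TestLogisticEngine:
    def test_intercept_only_balanced_outcome(self):
        df = pd.DataFrame({"outcome": [0, 1] * 25})
        fit = fit_logistic(df, [])
        assert fit.coef["constant"] == pytest.approx(0.0, abs=1e-10)
        assert fit.odds_ratio["constant"] == pytest.approx(1.0)

    def test_two_by_two_matches_hand_log_odds_ratio(self):
        n00, n01, n10, n11 = 20, 10, 5, 15
        rows = [(0, 0)] * n00 + [(0, 1)] * n01 + [(1, 0)] * n10 + [(1, 1)] * n11
        df = pd.DataFrame(rows, columns=["x", "outcome"])
        fit = fit_logistic(df, ["x"])
        assert fit.coef["x"] == pytest.approx(math.log(n11 * n00 / (n01 * n10)), abs=1e-9)
        assert fit.odds_ratio["x"] == pytest.approx(n11 * n00 / (n01 * n10), rel=1e-9)

    def test_irls_matches_derivative_free_oracle(self, rng):
        n = 50
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        df["outcome"] = (rng.random(n) < expit(0.3 + 0.8 * x1 - 0.5 * x2)).astype(int)
        fit = fit_logistic(df, ["x1", "x2"], on_separation="flag")
        X = np.column_stack([np.ones(n), x1, x2])
        y = df["outcome"].to_numpy(float)

        def nll(b):
            eta = X @ b
            return -(y @ eta - np.logaddexp(0, eta).sum())

        res = minimize(nll, np.zeros(3), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxiter=50_000))
        ours = np.array([fit.coef["constant"], fit.coef["x1"], fit.coef["x2"]])
        assert np.max(np.abs(ours - res.x)) < 1e-5

    def test_matches_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        n = 200
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x})
        df["outcome"] = (rng.random(n) < expit(-0.4 + 1.1 * x)).astype(int)
        fit = fit_logistic(df, ["x"])
        ref = sm.Logit(df["outcome"], sm.add_constant(df[["x"]])).fit(disp=0)
        assert fit.coef["x"] == pytest.approx(ref.params["x"], abs=1e-6)
        assert fit.se["x"] == pytest.approx(ref.bse["x"], rel=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_separation_raises_not_silent(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "outcome": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        with pytest.raises(SeparationError):
            fit_logistic(df, ["x"])
        flagged = fit_logistic(df, ["x"], on_separation="flag")
        assert flagged.separation

    def test_predictor_scaling_invariance(self, rng):
        n = 300
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x})
        df["outcome"] = (rng.random(n) < expit(0.2 + 0.9 * x)).astype(int)
        base = fit_logistic(df, ["x"])
        df2 = df.assign(x=df["x"] * 4.0)
        scaled = fit_logistic(df2, ["x"])
        assert scaled.coef["x"] == pytest.approx(base.coef["x"] / 4.0, rel=1e-6)
        assert scaled.loglik == pytest.approx(base.loglik, abs=1e-8)
        assert nagelkerke_r2(scaled) == pytest.approx(nagelkerke_r2(base), abs=1e-8)
        assert classification_table(scaled) == classification_table(base)

    def test_parameter_recovery_within_three_ses(self):
        coef = (0.4, 0.05, -1.1)
        df = simulate_network_cases(5000, coef, seed=2)
        fit = fit_logistic(df, ["total_passes", "density10"])
        for term, true in zip(("constant", "total_passes", "density10"), coef):
            assert abs(fit.coef[term] - true) < 3 * fit.se[term]


class TestHierarchical:
    def _cases(self, rng, n=288):
        total = rng.poisson(20, n).astype(float)
        d = {
            "total_passes": total,
            "density": rng.uniform(0, 0.35, n),
            "clustering": rng.uniform(0, 0.5, n),
            "centralization": rng.uniform(0, 0.6, n),
        }
        return bernoulli_frame(rng, n, -1.0 + 0.05 * total, d)

    def test_block2_loglik_never_below_block1(self, rng):
        h = hierarchical_fit(self._cases(rng), on_separation="flag")
        assert h.block2.loglik >= h.block1.loglik - 1e-10

    def test_g_statistics_are_additive(self, rng):
        h = hierarchical_fit(self._cases(rng), on_separation="flag")
        assert h.block2.g_vs_null == pytest.approx(
            h.block1.g_vs_null + h.block2.g_vs_previous, abs=1e-8
        )

    def test_block_degrees_of_freedom(self, rng):
        h = hierarchical_fit(self._cases(rng), on_separation="flag")
        assert (h.block1.g_vs_null_df, h.block2.g_vs_null_df) == (1, 4)
        assert h.block2.g_vs_previous_df == 3


class TestDiagnostics:
    def _fit(self, rng, n=500):
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x})
        df["outcome"] = (rng.random(n) < expit(-0.2 + 0.8 * x)).astype(int)
        return fit_logistic(df, ["x"])

    def test_hosmer_lemeshow_ten_groups_have_df_eight(self, rng):
        chi2, df, p = hosmer_lemeshow(self._fit(rng), groups=10)
        assert df == 8
        assert chi2 >= 0 and 0 <= p <= 1

    def test_hosmer_lemeshow_merges_sparse_fitted_values(self):
        df = pd.DataFrame({"x": [0.0, 1.0] * 50, "outcome": [0, 1, 1, 0] * 25})
        fit = fit_logistic(df, ["x"], on_separation="flag")
        chi2, dof, p = hosmer_lemeshow(fit, groups=10)
        assert dof < 8  # only two distinct fitted probabilities

    def test_hosmer_lemeshow_p_uniform_under_correct_model(self):
        pvals = []
        for s in range(200):
            r = np.random.default_rng(900 + s)
            x = r.normal(size=2000)
            df = pd.DataFrame({"x": x})
            df["outcome"] = (r.random(2000) < expit(-0.2 + 0.7 * x)).astype(int)
            fit = fit_logistic(df, ["x"], on_separation="flag")
            pvals.append(hosmer_lemeshow(fit)[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.005

    def test_nagelkerke_zero_when_no_improvement(self):
        df = pd.DataFrame({"outcome": [0, 1] * 30})
        fit = fit_logistic(df, [])
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_nagelkerke_approaches_one_for_near_perfect_fit(self, rng):
        n = 200
        x = np.r_[rng.normal(-4, 0.5, n // 2), rng.normal(4, 0.5, n // 2)]
        df = pd.DataFrame({"x": x, "outcome": (x > 0).astype(int)})
        fit = fit_logistic(df, ["x"], on_separation="flag")
        assert nagelkerke_r2(fit) > 0.95

    def test_nagelkerke_matches_hand_formula(self, rng):
        fit = self._fit(rng, n=80)
        n = fit.n
        r2_cs = 1 - math.exp(2 * (fit.loglik_null - fit.loglik) / n)
        expected = r2_cs / (1 - math.exp(2 * fit.loglik_null / n))
        assert nagelkerke_r2(fit) == pytest.approx(expected, abs=1e-12)

    def test_classification_perfectly_separated_toy_is_100_percent(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)],
                           "outcome": np.r_[np.zeros(10), np.ones(10)].astype(int)})
        fit = fit_logistic(df, ["x"], on_separation="flag")
        cls = classification_table(fit)
        assert cls["pct_uop_correct"] == cls["pct_sop_correct"] == 100.0

    def test_classification_constant_model_majority_class(self):
        df = pd.DataFrame({"outcome": [0] * 60 + [1] * 40})
        fit = fit_logistic(df, [])
        cls = classification_table(fit)
        assert cls["pct_uop_correct"] == 100.0
        assert cls["pct_sop_correct"] == 0.0
        assert cls["pct_overall_correct"] == 60.0

    def test_classification_matches_manual_count_on_ten_cases(self):
        fit_probs = np.array([0.9, 0.8, 0.6, 0.55, 0.5, 0.45, 0.4, 0.3, 0.2, 0.1])
        y = np.array([1, 1, 0, 1, 0, 1, 0, 0, 1, 0])
        fake = fit_logistic(pd.DataFrame({"outcome": y}), [])
        fake.fitted = fit_probs
        fake.y = y.astype(float)
        cls = classification_table(fake)
        # manual tally at cutoff 0.5: predictions 1,1,1,1,1,0,0,0,0,0
        assert cls["table"] == {"tn": 3, "fp": 2, "fn": 2, "tp": 3}
        assert cls["pct_overall_correct"] == 60.0


class TestReporting:
    def test_odds_ratio_transforms_of_printed_coefficients(self):
        assert round(odds_ratio(0.079), 3) == 1.082
        assert odds_ratio_ci(0.079, 0.034)[0] == pytest.approx(1.0124, abs=1e-4)
        assert round(odds_percent_change(odds_ratio(0.079)), 1) == 8.2
        assert round(odds_percent_change(odds_ratio(-1.320)), 1) == 73.3

    def test_report_schema_and_json_round_trip(self, rng, tmp_path):
        n = 300
        total = rng.poisson(20, n).astype(float)
        d = {
            "outcome": (rng.random(n) < expit(-1 + 0.05 * total)).astype(int),
            "total_passes": total,
            "density": rng.uniform(0, 0.35, n),
            "clustering": rng.uniform(0, 0.5, n),
            "centralization": rng.uniform(0, 0.6, n),
        }
        cases = pd.DataFrame(d)
        screen, fits, _ = run_analysis(cases)
        rep = model_report(screen, fits)
        for blk in rep["blocks"]:
            assert {"G_vs_null", "nagelkerke_r2", "hosmer_lemeshow", "classification"} <= set(blk)
        text = render_report(rep)
        assert "Exp(b)" in text and "Hosmer-Lemeshow" in text
        path = tmp_path / "report.json"
        with open(path, "w") as fh:
            json.dump(rep, fh, default=float)
        assert json.loads(path.read_text())["blocks"][1]["block"] == 2

    def test_rendered_table_shows_exp_beta(self):
        from passnet.regression_suite import _TERM_LABELS

        assert _TERM_LABELS["total_passes"] == "Total number of passes"
        assert f"{odds_ratio(0.079):.3f}" == "1.082"
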
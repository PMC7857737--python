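"""Kaplan-Meier, log-rank, Cox regression, adjusted curves and PH diagnostics,
checked against brute-force oracles and the independent lifelines library."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from lumcna import survkit
from lumcna.cna_score import score_and_quartile
from lumcna.synth import CohortConfig, generate_cohort

from conftest import make_clinical


def random_cohort(seed, n, beta=0.5, tied=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / np.exp(beta * x))
    c = rng.exponential(2.0, n)
    obs, e = np.minimum(t, c), (t <= c).astype(int)
    if tied:
        obs = np.ceil(obs * 4) / 4
    return x, obs, e


# ---------------------------------------------------------------------------
# Kaplan-Meier and medians
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_single_subject_event(self):
        c = survkit.km_estimate([5.0], [1])
        assert c.evaluate(4.9) == 1.0
        assert c.evaluate(5.0) == 0.0

    def test_event_then_censor(self):
        c = survkit.km_estimate([2.0, 3.0], [1, 0])
        assert c.evaluate(2.5) == pytest.approx(0.5)
        assert c.evaluate(10.0) == pytest.approx(0.5)

    def test_matches_direct_product_limit_enumeration(self):
        rng = np.random.default_rng(7)
        t = rng.integers(1, 15, size=20).astype(float)
        e = rng.integers(0, 2, size=20)
        curve = survkit.km_estimate(t, e)
        # independent enumeration: walk distinct event times, multiply hazards
        s, expected = 1.0, {}
        for u in sorted(set(t[e == 1])):
            n_at_risk = int((t >= u).sum())
            d = int(((t == u) & (e == 1)).sum())
            s *= 1.0 - d / n_at_risk
            expected[u] = s
        for u, sv in expected.items():
            assert curve.evaluate(u) == pytest.approx(sv)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 50)
        curve = survkit.km_estimate(t, np.ones(50, dtype=int))
        for u in t:
            assert curve.evaluate(u) == pytest.approx(1.0 - np.mean(t <= u))

    def test_survival_non_increasing_and_starts_at_one(self):
        _, t, e = random_cohort(5, 60)
        c = survkit.km_estimate(t, e)
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert c.evaluate(0.0) <= 1.0
        assert np.all(np.diff(c.at_risk) <= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            survkit.km_estimate([], [])


class TestMedianSurvival:
    def test_median_at_drop_below_half(self):
        c = survkit.SurvivalCurve(
            np.array([5.0, 10.0]), np.array([0.7, 0.4]), np.array([10, 6]), n=10
        )
        assert survkit.median_survival(c) == 10.0

    def test_not_reached_sentinel(self):
        c = survkit.SurvivalCurve(
            np.array([5.0]), np.array([0.8]), np.array([10]), n=10
        )
        assert survkit.median_survival(c) is survkit.NOT_REACHED

    def test_matches_scan_of_curve(self):
        _, t, e = random_cohort(9, 40)
        c = survkit.km_estimate(t, e)
        got = survkit.median_survival(c)
        candidates = [u for u, s in zip(c.event_times, c.survival) if s <= 0.5]
        assert got == (min(candidates) if candidates else None)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.repeat(["a", "b"], 4)
        res = survkit.logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_equals_breslow_cox_score_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        g = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(5.0 / np.exp(0.4 * g))
        c = rng.exponential(8.0, n)
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        lr = survkit.logrank_test(obs, e, g)
        fit = survkit.cox_fit(g[:, None], obs, e, ties_method="breslow")
        assert lr.statistic == pytest.approx(fit.score_test[0], abs=1e-8)

    def test_k_group_matches_lifelines(self):
        rng = np.random.default_rng(11)
        n = 120
        g = rng.choice(["a", "b", "c", "d"], n)
        t = np.ceil(rng.exponential(np.where(g == "d", 3.0, 6.0)))
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        res = survkit.logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-10)
        assert res.df == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            survkit.logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


# ---------------------------------------------------------------------------
# Design builder
# ---------------------------------------------------------------------------


class TestBuildDesign:
    @pytest.fixture(scope="class")
    def cohort(self):
        cna, clinical, _ = generate_cohort(CohortConfig(n_patients=120, n_genes=200, seed=2))
        return clinical, score_and_quartile(cna)

    def test_final_model_has_thirteen_columns(self, cohort):
        clinical, score = cohort
        design = survkit.build_design(clinical, score, survkit.PAPER_FORMULA)
        assert list(design.columns) == [
            "pam50[lumB]",
            "grade[2]",
            "grade[3]",
            "tumour_size",
            "positive_lymph_nodes",
            "age_at_diagnosis",
            "her2_status[positive]",
            "quartile[Q2]",
            "quartile[Q3]",
            "quartile[Q4]",
            "quartile[Q2]:pam50[lumB]",
            "quartile[Q3]:pam50[lumB]",
            "quartile[Q4]:pam50[lumB]",
        ]

    def test_marginal_only_formula(self, cohort):
        clinical, score = cohort
        design = survkit.build_design(clinical, score, "pam50 + tumour_size")
        assert list(design.columns) == ["pam50[lumB]", "tumour_size"]

    def test_interaction_is_product_of_parents(self, cohort):
        clinical, score = cohort
        design = survkit.build_design(clinical, score, survkit.PAPER_FORMULA)
        for q in ("Q2", "Q3", "Q4"):
            np.testing.assert_allclose(
                design[f"quartile[{q}]:pam50[lumB]"],
                design[f"quartile[{q}]"] * design["pam50[lumB]"],
            )

    def test_unknown_variable_raises_formula_error(self, cohort):
        clinical, score = cohort
        with pytest.raises(survkit.FormulaError):
            survkit.build_design(clinical, score, "pam50 + nonexistent")


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------


class TestCoxFit:
    def test_identical_groups_give_null_effect(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        e = np.array([1, 1, 0, 1, 0] * 2)
        g = np.repeat([0.0, 1.0], 5)
        fit = survkit.cox_fit(g[:, None], t, e)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_six_subject_fit_matches_grid_search(self):
        # untied toy data; independent partial-likelihood grid search
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([0.5, -0.2, 1.0, 0.0, -0.7, 0.3])

        def pll(b):
            ll = 0.0
            for i in range(6):
                if e[i] == 1:
                    risk = np.exp(b * x[t >= t[i]])
                    ll += b * x[i] - np.log(risk.sum())
            return ll

        grid = np.arange(-3.0, 3.0, 1e-4)
        best = grid[np.argmax([pll(b) for b in grid])]
        fit = survkit.cox_fit(x[:, None], t, e)
        assert fit.beta[0] == pytest.approx(best, abs=1e-4)

    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_lifelines_efron(self, tied):
        x, t, e = random_cohort(21, 150, tied=tied)
        fit = survkit.cox_fit(x[:, None], t, e)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.beta[0] == pytest.approx(ref.params_["x"], abs=1e-6)
        assert fit.se[0] == pytest.approx(ref.standard_errors_["x"], abs=1e-6)
        assert fit.loglik_fit == pytest.approx(ref.log_likelihood_, abs=1e-8)

    def test_shift_invariance_and_scaling(self):
        x, t, e = random_cohort(31, 120)
        f1 = survkit.cox_fit(x[:, None], t, e)
        f2 = survkit.cox_fit((x + 7.0)[:, None], t, e)
        f3 = survkit.cox_fit((3.0 * x)[:, None], t, e)
        assert f2.beta[0] == pytest.approx(f1.beta[0], abs=1e-8)
        assert f3.beta[0] == pytest.approx(f1.beta[0] / 3.0, abs=1e-8)
        assert f3.z[0] == pytest.approx(f1.z[0], abs=1e-6)

    def test_three_test_statistics_agree_asymptotically(self):
        x, t, e = random_cohort(41, 2000, beta=0.3)
        fit = survkit.cox_fit(x[:, None], t, e)
        stats_ = [fit.lr_test[0], fit.wald_test[0], fit.score_test[0]]
        assert max(stats_) / min(stats_) < 1.05

    def test_ci_contains_hr_and_lr_nonnegative(self):
        x, t, e = random_cohort(51, 100)
        fit = survkit.cox_fit(x[:, None], t, e)
        ci = fit.ci95
        assert ci[0, 0] <= fit.hr[0] <= ci[0, 1]
        assert fit.lr_test[0] >= 0
        assert fit.lr_test[0] == pytest.approx(
            2 * (fit.loglik_fit - fit.loglik_null), abs=1e-10
        )

    def test_collinear_design_rejected(self):
        x, t, e = random_cohort(61, 50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="linear"):
            survkit.cox_fit(X, t, e)

    def test_separation_warns(self):
        # perfectly separating covariate: all events in one group first
        t = np.r_[np.arange(1, 11), np.arange(20, 30)].astype(float)
        e = np.ones(20, dtype=int)
        x = np.r_[np.ones(10), np.zeros(10)]
        with pytest.warns(UserWarning, match="monotone"):
            survkit.cox_fit(x[:, None], t, e)


class TestReparametrization:
    @pytest.fixture(scope="class")
    def cohort(self):
        cna, clinical, _ = generate_cohort(CohortConfig(n_patients=250, n_genes=200, seed=8))
        score = score_and_quartile(cna)
        fit = survkit.fit_cox_model(clinical, score, outcome="DSS")
        return clinical, score, fit

    def test_swap_and_swap_back_is_identity(self, cohort):
        clinical, score, fit = cohort
        back = survkit.reparametrize_reference(clinical, score, "pam50", "lumA")
        np.testing.assert_allclose(back.beta, fit.beta, atol=1e-8)

    def test_loglik_invariant_under_reference_choice(self, cohort):
        clinical, score, fit = cohort
        refit = survkit.reparametrize_reference(clinical, score, "pam50", "lumB")
        assert refit.loglik_fit == pytest.approx(fit.loglik_fit, abs=1e-6)

    def test_within_lumb_contrast_equals_linear_combination(self, cohort):
        clinical, score, fit = cohort
        refit = survkit.reparametrize_reference(clinical, score, "pam50", "lumB")
        est, se, _ = survkit.linear_contrast(
            fit, {"quartile[Q4]": 1.0, "quartile[Q4]:pam50[lumB]": 1.0}
        )
        i = refit.terms.index("quartile[Q4]")
        assert refit.beta[i] == pytest.approx(est, abs=1e-5)
        assert refit.se[i] == pytest.approx(se, abs=1e-5)


# ---------------------------------------------------------------------------
# Adjusted curves
# ---------------------------------------------------------------------------


class TestAdjustedCurves:
    @pytest.fixture(scope="class")
    def fitted(self):
        cna, clinical, _ = generate_cohort(CohortConfig(n_patients=200, n_genes=200, seed=13))
        score = score_and_quartile(cna)
        fit = survkit.fit_cox_model(clinical, score, outcome="DSS")
        template = clinical.data.join(score.table)
        return fit, template

    def reference_profile(self, template):
        prof = survkit.median_mode_profile(template)
        prof.update(
            {
                "pam50": "lumA",
                "grade": "1",
                "her2_status": "negative",
                "quartile": "Q1",
                "tumour_size": 0.0,
                "positive_lymph_nodes": 0.0,
                "age_at_diagnosis": 0.0,
            }
        )
        return prof

    def test_reference_profile_equals_baseline(self, fitted):
        fit, template = fitted
        prof = self.reference_profile(template)
        curves = survkit.adjusted_survival_curves(
            fit, {"ref": prof}, survkit.PAPER_FORMULA, template
        )
        np.testing.assert_allclose(
            curves["ref"].survival, survkit.baseline_survival(fit).survival
        )

    def test_zero_coefficients_make_every_profile_baseline(self, fitted):
        fit, template = fitted
        null_fit = dataclasses.replace(fit, beta=np.zeros_like(fit.beta))
        prof = survkit.median_mode_profile(template)
        curves = survkit.adjusted_survival_curves(
            null_fit, {"any": prof}, survkit.PAPER_FORMULA, template
        )
        np.testing.assert_allclose(
            curves["any"].survival, np.exp(-null_fit.baseline_cumhazard)
        )

    def test_cloglog_offset_equals_linear_predictor(self, fitted):
        fit, template = fitted
        prof = survkit.median_mode_profile(template)
        prof.update({"pam50": "lumB", "quartile": "Q4"})
        curves = survkit.adjusted_survival_curves(
            fit, {"p": prof}, survkit.PAPER_FORMULA, template
        )
        s = curves["p"].survival
        s0 = survkit.baseline_survival(fit).survival
        keep = (s > 1e-12) & (s < 1.0 - 1e-12) & (s0 > 1e-12) & (s0 < 1.0 - 1e-12)
        offset = np.log(-np.log(s[keep])) - np.log(-np.log(s0[keep]))
        assert np.ptp(offset) < 1e-8  # constant in t
        # and the constant is the linear predictor of the profile
        row = {k: [v] for k, v in prof.items()}
        frame = pd.DataFrame(row, index=["p"])
        for col in frame.columns:
            if isinstance(template[col].dtype, pd.CategoricalDtype):
                frame[col] = pd.Categorical(
                    frame[col], categories=template[col].cat.categories, ordered=True
                )
        lp = (
            survkit.design_from_frame(frame, survkit.PAPER_FORMULA)
            .reindex(columns=fit.terms, fill_value=0.0)
            .to_numpy() @ fit.beta
        ).item()
        assert offset[0] == pytest.approx(lp, abs=1e-8)

    def test_incomplete_profile_rejected(self, fitted):
        fit, template = fitted
        with pytest.raises(ValueError, match="missing"):
            survkit.adjusted_survival_curves(
                fit, {"bad": {"pam50": "lumA"}}, survkit.PAPER_FORMULA, template
            )


# ---------------------------------------------------------------------------
# PH diagnostics
# ---------------------------------------------------------------------------


class TestPhDiagnostics:
    def test_schoenfeld_residuals_sum_to_zero(self):
        x, t, e = random_cohort(71, 100)
        fit = survkit.cox_fit(x[:, None], t, e)
        resid, _ = survkit.schoenfeld_residuals(fit)
        # estimating equation at beta-hat: residuals sum to ~0
        assert np.abs(resid.sum(axis=0)).max() < 1e-5

    def test_matches_lifelines_km_transform(self):
        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1.0 / np.exp(0.6 * x[:, 0]))
        c = rng.exponential(2.0, n)
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        fit = survkit.cox_fit(x, obs, e)
        diag = survkit.ph_diagnostics(fit)
        from lifelines.statistics import proportional_hazard_test

        df = pd.DataFrame({"t": obs, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        cf = CoxPHFitter().fit(df, "t", "e")
        ref = proportional_hazard_test(cf, df, time_transform="km")
        np.testing.assert_allclose(
            diag.term_statistics,
            ref.summary["test_statistic"].values,
            rtol=0.05,
            atol=1e-3,
        )

    def test_type_one_error_under_exact_ph(self):
        # data simulated under exact PH: global test should reject ~5%
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / np.exp(0.5 * x))
            c = rng.exponential(1.5, n)
            obs, e = np.minimum(t, c), (t <= c).astype(int)
            fit = survkit.cox_fit(x[:, None], obs, e)
            diag = survkit.ph_diagnostics(fit)
            rejections += diag.global_p_value < 0.05
        rate = rejections / reps
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / reps) <= rate <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / reps
        )

    def test_detects_time_varying_effect(self):
        # hazard effect reverses over time: per-term p should be small
        rng = np.random.default_rng(22)
        detected = 0
        reps = 40
        for _ in range(reps):
            n = 400
            x = (rng.random(n) < 0.5).astype(float)
            # piecewise hazards: strong early effect that vanishes later
            t = np.where(
                x == 1,
                rng.exponential(0.5, n),
                rng.exponential(2.0, n),
            )
            late = t > 1.0
            t[late] = 1.0 + rng.exponential(2.0, int(late.sum()))
            c = np.full(n, 6.0)
            obs, e = np.minimum(t, c), (t <= c).astype(int)
            fit = survkit.cox_fit(x[:, None], obs, e)
            diag = survkit.ph_diagnostics(fit)
            detected += diag.term_p_values[0] < 0.05
        assert detected > reps / 2

    def test_no_events_rejected(self):
        x, t, _ = random_cohort(81, 30)
        e = np.zeros(30, dtype=int)
        e[0] = 1
        fit = survkit.cox_fit(x[:, None], t, e)
        fit2 = dataclasses.replace(fit, n_events=1)
        with pytest.raises(ValueError):
            survkit.ph_diagnostics(fit2)
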
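"""Excursion-effect estimator: roots, weights, inference, covariates."""

import numpy as np
import pandas as pd
import pytest

import pushmrt as pm
from pushmrt.emee import (
    ModelMatrixSpec,
    FitResult,
    SeparationError,
    _prepare,
    derive_covariates,
    estimating_function,
    moderator_matrix,
)


def manual_fit(beta, vcov_beta, alpha=()):
    """Assemble a FitResult directly from coefficients (for identity tests)."""
    beta = np.asarray(beta, float)
    alpha = np.asarray(alpha, float)
    q = len(alpha) + len(beta)
    vcov = np.zeros((q, q))
    vcov[len(alpha):, len(alpha):] = np.asarray(vcov_beta, float)
    return FitResult(
        alpha_hat=alpha, beta_hat=beta, vcov=vcov,
        per_user_scores=np.zeros((2, q)), n_users=2, iterations=0,
        converged=True, spec=ModelMatrixSpec(),
        alpha_names=[f"a{i}" for i in range(len(alpha))],
        beta_names=[f"b{i}" for i in range(len(beta))],
    )


class TestRootFinding:
    def test_intercept_only_matches_closed_form(self, toy_intercept):
        """With f = g = {1} and ptilde = p, the root is available in closed
        form: alpha = log untreated rate, beta = log ratio of arm rates."""
        fit = pm.fit_emee(toy_intercept, ModelMatrixSpec(control_terms=()))
        cons = toy_intercept[toy_intercept.considered == 1]
        m1 = cons.loc[cons.push == 1, "outcome_24h"].mean()
        m0 = cons.loc[cons.push == 0, "outcome_24h"].mean()
        assert fit.alpha_hat[0] == pytest.approx(np.log(m0), abs=1e-8)
        assert fit.beta_hat[0] == pytest.approx(np.log(m1 / m0), abs=1e-8)

    def test_matches_brute_force_root_on_moderated_fixture(
        self, toy_moderated, oracle_root
    ):
        terms = ("which_day",)
        controls = ("week_in_study", "days_since_chart")
        fit = pm.fit_emee(
            toy_moderated,
            ModelMatrixSpec(moderator_terms=terms, control_terms=controls),
        )
        expected = oracle_root(toy_moderated, terms, controls)
        np.testing.assert_allclose(fit.theta, expected, atol=1e-6)

    def test_duplicating_every_user_leaves_estimates_unchanged(self, toy_moderated):
        spec = ModelMatrixSpec(control_terms=("week_in_study",))
        fit1 = pm.fit_emee(toy_moderated, spec)
        clone = toy_moderated.copy()
        clone["user_id"] = clone["user_id"] + 10_000
        fit2 = pm.fit_emee(pd.concat([toy_moderated, clone]), spec)
        np.testing.assert_allclose(fit1.theta, fit2.theta, atol=1e-7)

    def test_moderator_scaling_rescales_coefficient_exactly(self, medium_sim):
        df = medium_sim.copy()
        df["week_scaled"] = 4.0 * df["week_in_study"]
        f1 = pm.fit_emee(df, ModelMatrixSpec(moderator_terms=("week_in_study",)))
        f2 = pm.fit_emee(df, ModelMatrixSpec(moderator_terms=("week_scaled",)))
        assert f2.beta_hat[1] == pytest.approx(f1.beta_hat[1] / 4.0, abs=1e-8)
        assert f2.beta_hat[0] == pytest.approx(f1.beta_hat[0], abs=1e-7)

    def test_separation_raises_informative_error(self, toy_intercept):
        bad = toy_intercept.copy()
        bad.loc[bad.push == 1, "outcome_24h"] = 0
        with pytest.raises(SeparationError, match="all-zero outcomes"):
            pm.fit_emee(bad, ModelMatrixSpec(control_terms=()))

    def test_overflow_names_offending_row(self, toy_intercept):
        d = _prepare(toy_intercept, ModelMatrixSpec(control_terms=()), "considered")
        with pytest.raises(OverflowError, match="nonfinite"):
            estimating_function(np.array([1e4, 0.0]), d)


class TestWeights:
    def test_weights_are_one_when_ptilde_equals_p(self, toy_intercept):
        d = _prepare(
            toy_intercept, ModelMatrixSpec(control_terms=(), p_tilde=0.5),
            "considered",
        )
        np.testing.assert_allclose(d.weights, 1.0)
        fit_default = pm.fit_emee(toy_intercept, ModelMatrixSpec(control_terms=()))
        fit_ptilde = pm.fit_emee(
            toy_intercept, ModelMatrixSpec(control_terms=(), p_tilde=0.5)
        )
        np.testing.assert_allclose(fit_default.theta, fit_ptilde.theta, atol=1e-8)

    def test_weight_formula_for_reference_probability(self, toy_intercept):
        d = _prepare(
            toy_intercept, ModelMatrixSpec(control_terms=(), p_tilde=0.3),
            "considered",
        )
        expected = np.where(d.A == 1, 0.3 / 0.5, 0.7 / 0.5)
        np.testing.assert_allclose(d.weights, expected)

    def test_available_mode_uses_slot_selection_law(self, medium_sim):
        """In the all-available risk set, P(push now | available here) is
        p/(remaining open slots), e.g. 0.5/6 at a weekday's first slot."""
        d = _prepare(medium_sim, ModelMatrixSpec(), "available")
        rows = medium_sim[medium_sim.available == 1]
        first_weekday = (rows["slot"].to_numpy() == 1) & (
            rows["which_day"].to_numpy() == 1
        )
        np.testing.assert_allclose(d.p[first_weekday], 0.5 / 6)
        fit = pm.fit_emee(medium_sim, ModelMatrixSpec(), mode="available")
        assert fit.converged

    def test_estimating_function_mean_near_zero_at_truth(self):
        """Unbiasedness: U evaluated at the generating parameters has mean
        ~0 (within 3 SE) in each coordinate of the beta block."""
        params = pm.OutcomeModelParams()
        data = pm.simulate_trial_dataset(
            pm.TrialConfig(n_days=60), pm.CohortConfig(n_users=600),
            params, np.random.default_rng(21), keep="considered",
        )
        d = _prepare(data, ModelMatrixSpec(), "considered")
        theta = np.concatenate([params.alpha_vector(), params.beta_star])
        U, per_user = estimating_function(theta, d)
        se = per_user.std(axis=0, ddof=1) / np.sqrt(d.n_users)
        assert abs(U[-1]) < 3 * se[-1]


class TestSandwich:
    def test_meat_two_computations_agree(self, toy_moderated):
        fit = pm.fit_emee(toy_moderated, ModelMatrixSpec(control_terms=()))
        per = fit.per_user_scores
        n = fit.n_users
        m_outer = per.T @ per / n
        mean = per.mean(axis=0)
        m_cov = np.cov(per, rowvar=False, ddof=0) + np.outer(mean, mean)
        np.testing.assert_allclose(m_outer, m_cov, atol=1e-12)

    def test_standalone_recomputation_matches_fit(self, toy_moderated):
        spec = ModelMatrixSpec(control_terms=("week_in_study",))
        fit = pm.fit_emee(toy_moderated, spec)
        V = pm.sandwich_variance(fit, toy_moderated)
        np.testing.assert_allclose(V, fit.vcov, atol=1e-12)

    def test_single_record_per_user_equals_classical_iid_sandwich(self):
        """With one row per user, clustering degenerates to the classical
        i.i.d. sandwich, computed here directly from row scores."""
        rng = np.random.default_rng(12)
        n = 400
        a = (rng.random(n) < 0.5).astype(int)
        y = (rng.random(n) < np.where(a == 1, 0.35, 0.3)).astype(int)
        df = pd.DataFrame(
            {
                "user_id": np.arange(n), "day": 1, "slot": 1,
                "available": 1, "considered": 1, "prob": 0.5,
                "push": a, "outcome_24h": y,
            }
        )
        fit = pm.fit_emee(df, ModelMatrixSpec(control_terms=()))
        # direct classical computation at the closed-form root
        alpha, beta = fit.alpha_hat[0], fit.beta_hat[0]
        resid = np.exp(-a * beta) * y - np.exp(alpha)
        scores = np.column_stack([resid, (a - 0.5) * resid])
        B = np.array(
            [
                [-np.exp(alpha), -np.mean(a * np.exp(-a * beta) * y)],
                [
                    -np.mean((a - 0.5) * np.exp(alpha)),
                    -np.mean((a - 0.5) * a * np.exp(-a * beta) * y),
                ],
            ]
        )
        M = scores.T @ scores / n
        V = np.linalg.inv(B) @ M @ np.linalg.inv(B).T / n
        np.testing.assert_allclose(fit.vcov, V, atol=1e-10)

    def test_small_sample_correction_inflates_variance(self, toy_moderated):
        spec = ModelMatrixSpec(control_terms=())
        plain = pm.fit_emee(toy_moderated, spec)
        corrected = pm.fit_emee(toy_moderated, spec, small_sample=True)
        assert np.trace(corrected.vcov) > np.trace(plain.vcov) * 0.999
        eig = np.linalg.eigvalsh(corrected.vcov)
        assert (eig > -1e-12).all()


class TestInference:
    def test_single_df_wald_is_squared_z(self, toy_moderated):
        fit = pm.fit_emee(toy_moderated, ModelMatrixSpec(control_terms=()))
        w = pm.wald_test(fit, [[1.0]])
        z = fit.beta_hat[0] / np.sqrt(fit.vcov_beta[0, 0])
        assert w.statistic == pytest.approx(z**2, rel=1e-12)
        assert w.df == 1

    def test_chi_square_tail_reference_value(self):
        fit = manual_fit([np.sqrt(3.841)], [[1.0]])
        w = pm.wald_test(fit, [[1.0]])
        assert w.statistic == pytest.approx(3.841, rel=1e-12)
        assert w.p_value == pytest.approx(0.05, abs=5e-4)

    def test_null_contrast_gives_p_one(self):
        fit = manual_fit([0.0, 0.3], np.eye(2))
        w = pm.wald_test(fit, [[1.0, 0.0]])
        assert w.statistic == 0.0 and w.p_value == 1.0

    def test_rank_deficient_contrast_rejected(self):
        fit = manual_fit([0.1, 0.2], np.eye(2))
        with pytest.raises(ValueError, match="rank"):
            pm.wald_test(fit, [[1.0, 0.0], [2.0, 0.0]])

    def test_printed_coefficient_translates_to_risk_ratio(self):
        fit = manual_fit([0.071], [[1e-4]])
        est = pm.effect_estimate(fit, [1.0])
        assert round(est.rr, 3) == 1.074

    def test_ci_is_log_symmetric(self, toy_moderated):
        fit = pm.fit_emee(
            toy_moderated, ModelMatrixSpec(moderator_terms=("which_day",))
        )
        for x in ([1.0, 0.0], [1.0, 1.0]):
            est = pm.effect_estimate(fit, x, level=0.9)
            assert est.ci_low * est.ci_high == pytest.approx(
                np.exp(2 * est.log_rr), rel=1e-10
            )
            assert est.ci_low <= est.rr <= est.ci_high

    def test_degenerate_inputs_rejected(self):
        fit = manual_fit([0.1], [[1.0]])
        with pytest.raises(ValueError, match="level"):
            pm.effect_estimate(fit, [1.0], level=1.5)
        with pytest.raises(ValueError, match="shape"):
            pm.effect_estimate(fit, [1.0, 2.0])

    def test_summary_table_layout(self, toy_moderated):
        fit = pm.fit_emee(toy_moderated, ModelMatrixSpec())
        tab = pm.summary_table(fit)
        assert list(tab.columns) == [
            "block", "term", "coefficient", "se", "ci_low", "ci_high", "p",
        ]
        assert (tab.loc[tab.block == "causal", "p"].notna()).all()
        assert (tab.loc[tab.block == "control", "p"].isna()).all()


class TestDeriveCovariates:
    def make_history(self):
        decisions = pd.DataFrame(
            {
                "user_id": 1,
                "day": range(1, 11),
                "slot": 3,  # 17:30 every day
                "push": [1, 0, 1, 0, 1, 0, 0, 0, 0, 0],
            }
        )
        charts = pd.DataFrame(
            {
                "user_id": [1, 1],
                "day": [1, 5],
                "clock": [20.0, 18.0],  # inside the day-1 and day-5 windows
            }
        )
        return decisions, charts

    def test_push_success_ratio_counts_completed_windows(self):
        decisions, charts = self.make_history()
        cov = derive_covariates(decisions, charts)
        row = cov[cov.day == 8].iloc[0]
        assert row["pushed_indicator"] == 1
        assert row["push_success_ratio"] == pytest.approx(2 / 3)

    def test_week_index_and_no_push_history(self):
        decisions, charts = self.make_history()
        cov = derive_covariates(decisions, charts)
        assert cov[cov.day == 8].iloc[0]["week_in_study"] == 1
        assert cov[cov.day == 7].iloc[0]["week_in_study"] == 0
        first = cov[cov.day == 1].iloc[0]
        assert first["pushed_indicator"] == 0
        assert first["push_success_ratio"] == 0.0

    def test_days_since_chart_uses_pre_decision_events(self):
        decisions, charts = self.make_history()
        cov = derive_covariates(decisions, charts)
        # day 5 decision at 17:30 precedes the day-5 chart at 18:00
        assert cov[cov.day == 5].iloc[0]["days_since_chart"] == 4
        assert cov[cov.day == 6].iloc[0]["days_since_chart"] == 1

    def test_unordered_history_rejected(self):
        decisions, charts = self.make_history()
        shuffled = decisions.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="chronologically"):
            derive_covariates(shuffled, charts)


class TestModeratorMatrix:
    def test_slot_indicator_terms(self):
        df = pd.DataFrame({"slot": [1, 2, 2], "which_day": [1, 1, 0]})
        spec = ModelMatrixSpec(
            moderator_terms=("slot_2", "slot_2:weekend"), moderator_intercept=False
        )
        F = moderator_matrix(df, spec)
        np.testing.assert_array_equal(F, [[0, 0], [1, 0], [1, 1]])

    def test_unknown_term_rejected(self):
        df = pd.DataFrame({"slot": [1]})
        with pytest.raises(ValueError, match="unknown model term"):
            moderator_matrix(
                df, ModelMatrixSpec(moderator_terms=("nonexistent",))
            )
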
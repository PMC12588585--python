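import numpy as np
import pytest
import statsmodels.api as sm

from dcepref import (
    BehaviorMix,
    BinaryLogit,
    ConditionalLogit,
    MixedLogit,
    MixedLogitSpec,
    PreferenceModel,
    RawResponseSet,
    RankDeficiencyError,
    REMOTE_CARE_WEIGHTS,
    SeparationError,
    expand_to_rows,
    fit_binary_logit,
    fit_mixed_logit,
    mcfadden_pseudo_r2,
    simulate_cohort,
)
from dcepref.estimation import _collapse_to_choices


def two_by_two_data():
    """Single-attribute data with chosen-by-level table
    (x=1: 80 chosen / 20 not; x=0: 20 chosen / 80 not)."""
    X = np.array([[1.0]] * 100 + [[0.0]] * 100)
    y = np.array([1.0] * 80 + [0.0] * 20 + [1.0] * 20 + [0.0] * 80)
    return X, y


class TestExpandToRows:
    def test_two_rows_per_answered_question(self, design):
        raw = RawResponseSet(design, {"r": ["A"] * 16})
        rows = expand_to_rows(raw)
        assert len(rows.frame) == 32
        assert rows.frame["chosen"].sum() == 16

    def test_row_count_scales_with_respondents(self, design):
        cohort = simulate_cohort(design, REMOTE_CARE_WEIGHTS, BehaviorMix(), 93, seed=1)
        rows = expand_to_rows(RawResponseSet(design, cohort.records()))
        assert len(rows.frame) == 93 * 16 * 2

    def test_pair_level_vectors_sum_to_ones(self, design):
        raw = RawResponseSet(design, {"r": ["B"] * 16})
        rows = expand_to_rows(raw)
        sums = rows.frame.groupby("question_index")[rows.level_columns].sum()
        assert (sums.to_numpy() == 1).all()

    def test_missing_questions_skipped_with_warning(self, design):
        raw = RawResponseSet(design, {"r": ["A"] * 15 + [None]})
        with pytest.warns(UserWarning, match="unanswered"):
            rows = expand_to_rows(raw)
        assert len(rows.frame) == 30


class TestBinaryLogit:
    def test_saturated_two_by_two_closed_form(self):
        X, y = two_by_two_data()
        est = BinaryLogit().fit(X, y)
        assert est.intercept_ == pytest.approx(np.log(0.25), abs=1e-8)
        assert est.coef_[0] == pytest.approx(np.log(16.0), abs=1e-8)

    def test_matches_glm_oracle(self, clean_rows):
        fit = fit_binary_logit(clean_rows)
        X = clean_rows.design_matrix()
        y = clean_rows.outcomes()
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        ours = np.array([fit.alpha, *fit.betas.values()])
        ours_se = np.array([fit.se_alpha, *fit.se.values()])
        np.testing.assert_allclose(ours, oracle.params, atol=1e-6)
        np.testing.assert_allclose(ours_se, oracle.bse, atol=1e-6)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)
        assert fit.pseudo_r2 == pytest.approx(oracle.prsquared, abs=1e-9)

    def test_null_simulation_coefficients_near_zero(self, design, scheme):
        model = PreferenceModel(alpha=0.0, betas={a: 0.0 for a in scheme.attributes})
        cohort = simulate_cohort(design, model, BehaviorMix(), 800, seed=31)
        rows = expand_to_rows(RawResponseSet(design, cohort.records()))
        fit = fit_binary_logit(rows)
        for a in scheme.attributes:
            assert abs(fit.betas[a]) < 3 * fit.se[a]

    def test_intercept_is_half_negative_beta_sum(self, clean_rows):
        # structural identity of the complementary row expansion
        fit = fit_binary_logit(clean_rows)
        assert fit.alpha == pytest.approx(-sum(fit.betas.values()) / 2, abs=1e-8)

    def test_newton_steps_never_decrease_loglik(self, clean_rows):
        est = BinaryLogit().fit(clean_rows.design_matrix(), clean_rows.outcomes())
        path = np.array(est.loglik_path_)
        assert (np.diff(path) >= -1e-10).all()

    def test_row_order_invariance(self, clean_rows):
        X = clean_rows.design_matrix()
        y = clean_rows.outcomes()
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(y))
        a = BinaryLogit().fit(X, y)
        b = BinaryLogit().fit(X[perm], y[perm])
        np.testing.assert_allclose(a.params_, b.params_, atol=1e-9)
        np.testing.assert_allclose(a.se_, b.se_, atol=1e-9)

    def test_separation_raises_with_direction(self):
        X = np.array([[0.0]] * 20 + [[1.0]] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(SeparationError):
            BinaryLogit().fit(X, y)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 50).astype(float)
        X = np.column_stack([x, x])  # duplicated column
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError, match="collinear"):
            BinaryLogit().fit(X, y)

    def test_cluster_robust_ses_larger_on_duplicated_rows(self, clean_rows):
        # the two rows of a question are perfectly anticorrelated, so
        # design-consistent SEs exceed the information-based ones
        naive = fit_binary_logit(clean_rows)
        robust = fit_binary_logit(clean_rows, cov_type="cluster")
        np.testing.assert_allclose(
            [robust.alpha, *robust.betas.values()],
            [naive.alpha, *naive.betas.values()],
            atol=1e-12,
        )
        for a in clean_rows.attributes:
            assert robust.se[a] > naive.se[a]

    def test_sklearn_params_and_prediction(self):
        X, y = two_by_two_data()
        est = BinaryLogit(max_iter=50)
        assert est.get_params()["max_iter"] == 50
        est.set_params(max_iter=100).fit(X, y)
        p = est.predict_proba(np.array([[1.0], [0.0]]))[:, 1]
        np.testing.assert_allclose(p, [0.8, 0.2], atol=1e-8)
        assert est.predict(np.array([[1.0]]))[0] == 1


class TestPseudoR2:
    def test_definition_cases(self):
        assert mcfadden_pseudo_r2(-100.0, -100.0) == 0.0
        assert mcfadden_pseudo_r2(-50.0, -100.0) == pytest.approx(0.5)
        with pytest.raises(ZeroDivisionError):
            mcfadden_pseudo_r2(-1.0, 0.0)


class TestConditionalLogit:
    def test_estimates_are_half_the_row_logit_betas(self, design, clean_rows):
        # the row-expanded likelihood is exactly twice the paired
        # conditional likelihood at half the coefficient scale
        row_fit = fit_binary_logit(clean_rows)
        f = clean_rows.frame
        a_side = f[f["alternative"] == "A"]
        b_side = f[f["alternative"] == "B"]
        X_diff = (
            a_side[clean_rows.level_columns].to_numpy(float)
            - b_side[clean_rows.level_columns].to_numpy(float)
        )
        chose_a = a_side["chosen"].to_numpy(float)
        cond = ConditionalLogit().fit(X_diff, chose_a)
        np.testing.assert_allclose(
            cond.coef_,
            np.array(list(row_fit.betas.values())) / 2,
            atol=1e-6,
        )


class TestMixedLogit:
    def test_sigma_zero_marginal_equals_plain_loglik(self, clean_rows):
        plain = fit_binary_logit(clean_rows)
        mixed = fit_mixed_logit(clean_rows, MixedLogitSpec(fix_sigma=0.0))
        assert mixed.loglik == pytest.approx(plain.loglik, abs=1e-8)

    def test_quadrature_refinement_converged(self, design):
        model = PreferenceModel(
            REMOTE_CARE_WEIGHTS.alpha, REMOTE_CARE_WEIGHTS.betas, sigma_re=0.5
        )
        cohort = simulate_cohort(design, model, BehaviorMix(), 500, seed=33)
        rows = expand_to_rows(RawResponseSet(design, cohort.records()))
        X, y, g = _collapse_to_choices(rows)
        params = np.array(
            [model.alpha, *model.beta_vector(design.scheme.attributes)]
        )
        ll31 = MixedLogit(n_quadrature=31).marginal_loglik(params, 0.5, X, y, g)
        ll61 = MixedLogit(n_quadrature=61).marginal_loglik(params, 0.5, X, y, g)
        assert abs(ll31 - ll61) < 1e-6

    def test_sigma_recovered_on_collapsed_choices(self, design):
        model = PreferenceModel(
            REMOTE_CARE_WEIGHTS.alpha, REMOTE_CARE_WEIGHTS.betas, sigma_re=1.0
        )
        cohort = simulate_cohort(design, model, BehaviorMix(), 1000, seed=34)
        rows = expand_to_rows(RawResponseSet(design, cohort.records()))
        fit = fit_mixed_logit(rows, MixedLogitSpec(collapse_pairs=True))
        assert fit.sigma_re == pytest.approx(1.0, abs=0.25)

    def test_sigma_unidentified_on_full_row_expansion(self, design):
        # structural property of the complementary expansion: the
        # respondent log-likelihood is even in the random intercept, so
        # its MLE is zero even when the data are heterogeneous
        model = PreferenceModel(
            REMOTE_CARE_WEIGHTS.alpha, REMOTE_CARE_WEIGHTS.betas, sigma_re=1.0
        )
        cohort = simulate_cohort(design, model, BehaviorMix(), 200, seed=35)
        rows = expand_to_rows(RawResponseSet(design, cohort.records()))
        fit = fit_mixed_logit(rows, MixedLogitSpec())
        assert fit.sigma_re == pytest.approx(0.0, abs=1e-4)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MixedLogitSpec(n_quadrature=3)
        with pytest.raises(ValueError):
            MixedLogitSpec(fix_sigma=-0.5)
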
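"""Pooling-route checks: pointwise vs multivariate, comparators, weights."""

import numpy as np
import pytest

from fpmeta import (
    FPSpec,
    StudyData,
    StudyFit,
    ValidationError,
    categorize_pool,
    contrast_matrix,
    curve_from_mvmeta,
    empirical_bayes_curves,
    fit_cox_fp,
    linear_range_meta,
    metacurve_pool,
    mvmeta_pool,
    univariate_meta,
    weight_profiles,
)

GRID = np.linspace(18.0, 32.0, 43)
SPEC12 = FPSpec((1.0, 2.0))


def make_fit(study_id, beta, cov, spec=SPEC12):
    return StudyFit(study_id=study_id, spec=spec, beta=np.asarray(beta, float),
                    cov=np.asarray(cov, float), gamma=np.zeros(0),
                    loglik=-50.0, n_events=100)


class TestMetacurve:
    def test_single_study_returns_its_own_contrast(self):
        fit = make_fit("a", [0.5, -0.01], 0.01 * np.eye(2))
        curve = metacurve_pool([fit], GRID, 25.0)
        A = contrast_matrix(curve.grid, 25.0, SPEC12)
        np.testing.assert_allclose(curve.estimate, A @ fit.beta, atol=1e-12)
        assert np.all(curve.weights == 1.0)

    def test_duplicated_study_halves_the_variance(self):
        fit = make_fit("a", [0.5, -0.01], 0.01 * np.eye(2))
        fit2 = make_fit("b", [0.5, -0.01], 0.01 * np.eye(2))
        one = metacurve_pool([fit], GRID, 25.0)
        two = metacurve_pool([fit, fit2], GRID, 25.0)
        np.testing.assert_allclose(two.estimate, one.estimate, atol=1e-12)
        np.testing.assert_allclose(two.se**2, one.se**2 / 2.0, atol=1e-14)

    def test_reference_point_is_exactly_zero(self, proportional_fits):
        for model in ("ce", "re"):
            curve = metacurve_pool(proportional_fits, GRID, 25.0, model=model)
            at_ref = np.isclose(curve.grid, 25.0)
            assert at_ref.any()
            assert np.all(curve.estimate[at_ref] == 0.0)
            assert np.all(curve.se[at_ref] == 0.0)

    def test_confidence_band_brackets_estimate(self, proportional_fits):
        curve = metacurve_pool(proportional_fits, GRID, 25.0, model="re")
        assert np.all(curve.ci_low <= curve.estimate + 1e-12)
        assert np.all(curve.estimate <= curve.ci_high + 1e-12)

    def test_ce_estimate_within_study_contrast_envelope(self, proportional_fits):
        curve = metacurve_pool(proportional_fits, GRID, 25.0, model="ce")
        per_study = np.array([
            contrast_matrix(curve.grid, 25.0, f.spec) @ f.beta
            for f in proportional_fits
        ])
        assert np.all(curve.estimate >= per_study.min(axis=0) - 1e-9)
        assert np.all(curve.estimate <= per_study.max(axis=0) + 1e-9)

    def test_non_psd_study_dropped_with_warning(self, caplog):
        good = make_fit("good", [0.1, 0.0], 0.01 * np.eye(2))
        bad = make_fit("bad", [9.9, 9.9], np.array([[1.0, 2.0], [2.0, 1.0]]))
        with caplog.at_level("WARNING", logger="fpmeta"):
            curve = metacurve_pool([good, bad], GRID, 25.0)
        assert curve.study_ids == ["good"]
        assert any("not PSD" in m for m in caplog.messages)

    def test_mixed_specs_are_allowed(self):
        f1 = make_fit("a", [0.3], np.array([[0.01]]), FPSpec((1.0,)))
        f2 = make_fit("b", [0.5, -0.01], 0.01 * np.eye(2))
        curve = metacurve_pool([f1, f2], GRID, 25.0)
        assert np.all(np.isfinite(curve.estimate))


class TestEquivalenceAndEfficiency:
    def test_proportional_variances_ce_equivalence(self, proportional_fits):
        """With S_i = lambda_i S, CE pooling by both routes coincides."""
        mc = metacurve_pool(proportional_fits, GRID, 25.0, model="ce")
        mv = curve_from_mvmeta(
            mvmeta_pool(proportional_fits, model="ce"), GRID, 25.0
        )
        assert np.max(np.abs(mc.estimate - mv.estimate)) < 1e-8
        assert np.max(np.abs(mc.se - mv.se)) < 1e-8

    def test_multivariate_route_never_less_precise(self, rng):
        # Gauss-Markov: the GLS contrast variance is a lower bound for any
        # pointwise inverse-variance combination, whatever the S_i
        fits = [
            make_fit(f"s{i}", rng.normal(size=2),
                     (lambda A: A @ A.T + 0.05 * np.eye(2))(
                         rng.normal(size=(2, 2)) * 0.3))
            for i in range(4)
        ]
        mc = metacurve_pool(fits, GRID, 25.0, model="ce")
        mv = curve_from_mvmeta(mvmeta_pool(fits, model="ce"), GRID, 25.0)
        off = ~np.isclose(mc.grid, 25.0)
        assert np.all(mv.se[off] <= mc.se[off] + 1e-12)


class TestCurveFromMvmeta:
    def test_known_coefficients_and_zero_covariance(self):
        res = mvmeta_pool(
            [make_fit("a", [1.0, 1.0], 1e-14 * np.eye(2))], model="ce"
        )
        curve = curve_from_mvmeta(res, np.array([1.0, 2.0]), 1.0)
        # contrast at x=2 vs 1: (2-1) + (4-1) = 4
        assert curve.estimate[np.isclose(curve.grid, 2.0)][0] == pytest.approx(4.0)
        assert curve.se[np.isclose(curve.grid, 2.0)][0] == pytest.approx(0.0, abs=1e-6)

    def test_reference_reparameterization_is_exact(self, proportional_fits):
        res = mvmeta_pool(proportional_fits, model="ce")
        grid = np.linspace(20, 30, 51)
        c1 = curve_from_mvmeta(res, grid, 25.0)
        c2 = curve_from_mvmeta(res, grid, 22.0)
        shift = c2.estimate[np.isclose(c2.grid, 25.0)][0]
        np.testing.assert_allclose(c2.estimate - shift, c1.estimate, atol=1e-12)

    def test_mixed_specs_rejected(self):
        f1 = make_fit("a", [0.3], np.array([[0.01]]), FPSpec((1.0,)))
        f2 = make_fit("b", [0.5, -0.01], 0.01 * np.eye(2))
        with pytest.raises(ValidationError, match="common powers"):
            mvmeta_pool([f1, f2])


class TestEmpiricalBayes:
    def test_zero_heterogeneity_shrinks_fully_to_pooled(self, proportional_fits):
        res = mvmeta_pool(proportional_fits, model="re")
        res.between_cov = np.zeros((2, 2))
        curves = empirical_bayes_curves(proportional_fits, res, GRID, 25.0)
        pooled = curve_from_mvmeta(res, GRID, 25.0)
        for c in curves:
            np.testing.assert_allclose(c.estimate, pooled.estimate, atol=1e-10)

    def test_precise_study_keeps_its_own_curve(self):
        fits = [make_fit("a", [0.4, -0.008], 1e-12 * np.eye(2)),
                make_fit("b", [0.2, 0.01], 1e-12 * np.eye(2))]
        res = mvmeta_pool(fits, model="re")
        res.between_cov = 0.5 * np.eye(2)
        curves = empirical_bayes_curves(fits, res, GRID, 25.0)
        own = contrast_matrix(curves[0].grid, 25.0, SPEC12) @ fits[0].beta
        np.testing.assert_allclose(curves[0].estimate, own, atol=1e-6)

    def test_scalar_blup_hand_value(self):
        # beta_i=2, pooled=0, Psi=1, S_i=1 -> shrunken coefficient 1
        spec1 = FPSpec((1.0,))
        fits = [StudyFit("a", spec1, np.array([2.0]), np.array([[1.0]]),
                         np.zeros(0), -1.0, 10)]
        res = mvmeta_pool(fits, model="ce")
        res.model = "re"
        res.beta = np.array([0.0])
        res.between_cov = np.array([[1.0]])
        curves = empirical_bayes_curves(fits, res, np.array([25.0, 26.0]), 25.0)
        # contrast at 26 vs 25 with power 1 is 1 * shrunken beta
        assert curves[0].estimate[-1] == pytest.approx(1.0)

    def test_ce_input_rejected(self, proportional_fits):
        res = mvmeta_pool(proportional_fits, model="ce")
        with pytest.raises(ValidationError, match="RE"):
            empirical_bayes_curves(proportional_fits, res, GRID, 25.0)


class TestWeightProfiles:
    def test_single_study_gets_full_weight(self):
        fit = make_fit("a", [0.5, -0.01], 0.01 * np.eye(2))
        wp = weight_profiles(metacurve_pool([fit], GRID, 25.0))
        np.testing.assert_allclose(wp.values, 100.0)

    def test_identical_studies_split_evenly_and_sum_to_100(self):
        fits = [make_fit(s, [0.5, -0.01], 0.01 * np.eye(2)) for s in "ab"]
        wp = weight_profiles(metacurve_pool(fits, GRID, 25.0))
        np.testing.assert_allclose(wp.values, 50.0)
        np.testing.assert_allclose(wp.sum(axis=0).values, 100.0)

    def test_mvmeta_curve_rejected(self, proportional_fits):
        curve = curve_from_mvmeta(
            mvmeta_pool(proportional_fits, model="ce"), GRID, 25.0
        )
        with pytest.raises(ValidationError):
            weight_profiles(curve)

    def test_re_weights_more_uniform_than_ce_at_extremes(self, small_cohort_fits):
        grid = np.linspace(18, 34, 33)
        ce = metacurve_pool(small_cohort_fits, grid, 25.0, model="ce")
        re = metacurve_pool(small_cohort_fits, grid, 25.0, model="re")
        for j in (0, len(grid) - 1):
            assert re.weights[:, j].max() <= ce.weights[:, j].max() + 1e-12


class TestCategorize:
    def test_two_groups_reduce_to_binary_univariate_meta(self, small_cohorts):
        studies, _ = small_cohorts
        pooled_x = np.concatenate([s.exposure for s in studies])
        cut = np.quantile(pooled_x, 0.5)
        res = categorize_pool(studies, K=2, x0=cut - 5.0, model="ce")
        # independent route: per-study Cox on the binary indicator
        from fpmeta.cox import cox_fit

        est, var = [], []
        for s in studies:
            d = (s.exposure > cut).astype(float)[:, None]
            X = np.hstack([d, s.confounders])
            r = cox_fit(X, s.time, s.event)
            est.append(r.beta[0])
            var.append(r.cov[0, 0])
        uni = univariate_meta(est, var, "ce")
        upper = res.table[~res.table.reference].iloc[0]
        assert upper.estimate == pytest.approx(uni.pooled, abs=1e-8)
        assert upper.se == pytest.approx(np.sqrt(uni.pooled_var), abs=1e-8)

    def test_reference_category_contains_reference_exposure(self, small_cohorts):
        studies, _ = small_cohorts
        res = categorize_pool(studies, K=5, x0=25.0)
        row = res.table[res.table.reference].iloc[0]
        assert row.low <= 25.0 <= row.high
        assert row.estimate == 0.0 and row.se == 0.0

    def test_joint_close_to_univariate_on_modest_heterogeneity(self, small_cohorts):
        studies, _ = small_cohorts
        uni = categorize_pool(studies, K=4, x0=25.0, model="ce", joint=False)
        joint = categorize_pool(studies, K=4, x0=25.0, model="ce", joint=True)
        # same dummies, pooled jointly: correlated within-study estimates may
        # shift results, but they estimate the same contrasts
        diff = np.abs(uni.table.estimate.values - joint.table.estimate.values)
        assert diff.max() < 5 * uni.table.se.max()

    def test_finer_categorization_resolves_interior_nadir(self):
        from fpmeta import make_erfc_like

        studies, _ = make_erfc_like(
            n_cohorts=4, mean_size=12000, size_sigma=0.1,
            curve_heterogeneity=0.0, seed=31,
        )
        for K in (10, 20):
            res = categorize_pool(studies, K=K, x0=24.0, model="ce")
            tab = res.table.sort_values("category").reset_index(drop=True)
            nadir_idx = int(np.argmin(tab.estimate.values))
            assert 0 < nadir_idx < len(tab) - 1, f"nadir on boundary for K={K}"

    def test_k_below_two_rejected(self, small_cohorts):
        with pytest.raises(ValidationError):
            categorize_pool(small_cohorts[0], K=1, x0=25.0)


class TestLinearRange:
    def test_window_with_single_study_returns_that_study(self, small_cohorts):
        studies, _ = small_cohorts
        res = linear_range_meta(studies[:1], 20.0, 30.0, model="ce",
                                min_events=5)
        assert len(res.forest) == 1
        assert res.pooled == pytest.approx(res.forest.estimate.iloc[0])
        assert res.se == pytest.approx(res.forest.se.iloc[0])

    def test_impossible_event_threshold_raises(self, small_cohorts):
        studies, _ = small_cohorts
        with pytest.raises(ValidationError):
            linear_range_meta(studies, 20.0, 24.0, min_events=np.inf)

    def test_detects_negative_slope_in_declining_window(self):
        rng = np.random.default_rng(12)
        studies = []
        for i in range(4):
            n = 12000
            x = rng.uniform(18.0, 22.0, n)
            t = rng.exponential(1, n) / np.exp(-0.3 * (x - 20.0))
            e = (t <= 0.12).astype(int)
            studies.append(StudyData(f"s{i}", np.minimum(t, 0.12), e, x))
        res = linear_range_meta(studies, 18.0, 20.0, model="re", min_events=10)
        assert res.pooled < 0
        assert res.ci_high < 0
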
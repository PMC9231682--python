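import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from calanfeed import (
    ConfigError,
    DataError,
    InsufficientDataError,
    MixtureModel,
    fit_mixture,
    intersection_point,
    meal_criterion_from_model,
    prepare_intervals,
    select_model,
)
from calanfeed.criterion import information_criteria


class TestPrepareIntervals:
    def test_short_intervals_dropped_and_counted(self):
        out = prepare_intervals([60.0, 90.0, 600.0], min_interval_s=120.0, min_n=1)
        assert out.n == 1 and out.n_excluded_short == 2
        assert out.values[0] == pytest.approx(np.log(600.0))

    def test_survivor_arithmetic_at_herd_scale(self):
        # 17,468 raw intervals, 10,974 below the 2-min cutoff -> 6,494 fitted
        durations = np.concatenate([np.full(10_974, 60.0), np.full(6_494, 600.0)])
        out = prepare_intervals(durations)
        assert out.n == 6_494 and out.n_excluded_short == 10_974

    def test_exclusion_fraction_matches_planted_short_mass(self, small_bundle):
        cfg = small_bundle.config
        durations = small_bundle.true_gaps["duration_s"].to_numpy()
        out = prepare_intervals(durations)
        observed = out.n_excluded_short / len(durations)
        # epoch rounding sends raw gaps below 105 s to {30,60,90}: the planted
        # short mass is the mixture CDF at ln(105)
        planted = sum(
            w * norm.cdf((np.log(105.0) - m) / s)
            for w, m, s in zip(cfg.gap_weights, cfg.gap_means, cfg.gap_sds)
        )
        assert observed == pytest.approx(planted, abs=0.02)

    def test_too_few_survivors_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            prepare_intervals(np.full(60, 60.0))


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "minus2ll,K,aicc,bic",
        [(20_729.3, 3, 20_745.3, 20_799.5), (21_160.5, 2, 21_170.5, 21_204.4)],
    )
    def test_reproduces_published_model_comparison(self, minus2ll, K, aicc, bic):
        _, a, b = information_criteria(minus2ll, 3 * K - 1, n=6_494)
        assert a == pytest.approx(aicc, abs=0.1)
        assert b == pytest.approx(bic, abs=0.1)

    def test_zero_free_parameters_is_identity(self):
        m2ll, a, b = information_criteria(123.4, 0, n=100)
        assert a == b == m2ll == 123.4

    def test_undefined_for_tiny_n(self):
        with pytest.raises(DataError):
            information_criteria(10.0, 5, n=6)


class TestFitMixture:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 1.3, 400)
        m = fit_mixture(x, K=1)
        assert m.means[0] == pytest.approx(np.mean(x))
        assert m.sds[0] == pytest.approx(np.std(x))
        assert m.minus2LL == pytest.approx(-2 * norm.logpdf(x, np.mean(x), np.std(x)).sum())

    def test_two_spike_symmetry_gives_equal_weights(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.05, 300), rng.normal(10, 0.05, 300)])
        m = fit_mixture(x, K=2, seed=0)
        np.testing.assert_allclose(m.weights, [0.5, 0.5], atol=0.01)
        np.testing.assert_allclose(m.means, [0.0, 10.0], atol=0.02)

    def test_parameter_recovery_at_published_scale(self):
        rng = np.random.default_rng(123)
        z = rng.random(6_494) < 0.5
        x = np.where(z, rng.normal(6.34, 0.61, 6_494), rng.normal(8.77, 0.63, 6_494))
        m = fit_mixture(x, K=2, seed=123)
        np.testing.assert_allclose(m.means, [6.34, 8.77], atol=0.10)
        np.testing.assert_allclose(m.sds, [0.61, 0.63], atol=0.05)

    def test_agrees_with_independent_em_implementation(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(6.3, 0.6, 800), rng.normal(8.8, 0.6, 500)])
        ours = fit_mixture(x, K=2, seed=5)
        ref = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref.means_.ravel()[order], atol=0.02)
        np.testing.assert_allclose(ours.sds, np.sqrt(ref.covariances_.ravel()[order]), atol=0.02)
        assert ours.minus2LL == pytest.approx(-2 * ref.score(x[:, None]) * len(x), rel=1e-4)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        a = fit_mixture(x, K=2, seed=7)
        b = fit_mixture(x, K=2, seed=7)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.minus2LL == b.minus2LL

    def test_too_little_data_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_mixture(np.arange(30.0), K=2)


class TestSelectModel:
    def _model(self, K, minus2ll, n=6_494):
        w = np.full(K, 1.0 / K)
        return MixtureModel(K=K, weights=w, means=np.arange(K, dtype=float),
                            sds=np.ones(K), minus2LL=minus2ll, n=n)

    def test_published_comparison_prefers_three_components(self):
        m3, m2 = self._model(3, 20_729.3), self._model(2, 21_160.5)
        assert select_model([m2, m3], rule="bic").K == 3
        assert select_model([m2, m3], rule="aicc").K == 3

    def test_tie_goes_to_first_candidate(self):
        a, b = self._model(2, 100.0), self._model(2, 100.0)
        assert select_model([a, b]) is a

    def test_different_n_rejected(self):
        with pytest.raises(DataError):
            select_model([self._model(2, 10.0, n=500), self._model(3, 9.0, n=600)])

    def test_recovers_true_component_count_in_replicates(self):
        hits = 0
        n_rep = 20
        mus, sds = np.array([4.9, 6.34, 8.77]), np.array([0.3, 0.61, 0.63])
        for rep in range(n_rep):
            rng = np.random.default_rng(2_000 + rep)
            comp = rng.choice(3, p=[0.18, 0.5, 0.32], size=3_000)
            x = rng.normal(mus[comp], sds[comp])
            models = [fit_mixture(x, K=k, n_restarts=3, seed=rep) for k in (2, 3)]
            hits += select_model(models, rule="bic").K == 3
        assert hits >= 0.95 * n_rep


class TestIntersectionPoint:
    def test_published_three_component_criterion(self):
        C = intersection_point(6.34, 0.61, 8.77, 0.63)
        assert np.exp(C) / 60 == pytest.approx(31.3, abs=0.5)

    def test_published_two_component_criterion(self):
        C = intersection_point(5.97, 0.69, 8.75, 0.65)
        assert np.exp(C) / 60 == pytest.approx(27.4, abs=0.5)

    def test_equal_sigma_midpoint(self):
        for sigma in (0.2, 0.7, 1.5):
            assert intersection_point(0.0, sigma, 2.0, sigma) == pytest.approx(1.0)

    def test_matches_bisection_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            mu1 = rng.uniform(0, 5)
            mu2 = mu1 + rng.uniform(1.0, 4.0)
            s1, s2 = rng.uniform(0.2, 0.9, 2)
            C = intersection_point(mu1, s1, mu2, s2)
            f = lambda x: norm.pdf(x, mu1, s1) - norm.pdf(x, mu2, s2)
            assert abs(C - brentq(f, mu1, mu2, xtol=1e-12)) < 1e-8

    def test_misordered_means_rejected(self):
        with pytest.raises(ConfigError):
            intersection_point(3.0, 0.5, 2.0, 0.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        mu1=st.floats(0, 5),
        delta=st.floats(1.0, 4.0),
        s1=st.floats(0.2, 0.9),
        s2=st.floats(0.2, 0.9),
    )
    def test_root_lies_between_means_with_equal_densities(self, mu1, delta, s1, s2):
        mu2 = mu1 + delta
        C = intersection_point(mu1, s1, mu2, s2)
        assert mu1 < C < mu2
        assert abs(norm.pdf(C, mu1, s1) - norm.pdf(C, mu2, s2)) < 1e-8


class TestMealCriterionFromModel:
    def _model(self, weights, means, sds, n=6_494):
        K = len(means)
        return MixtureModel(K=K, weights=np.asarray(weights, float),
                            means=np.asarray(means, float), sds=np.asarray(sds, float),
                            minus2LL=0.0, n=n)

    def test_uses_two_rightmost_components(self):
        m = self._model([0.3, 0.4, 0.3], [4.0, 6.34, 8.77], [0.6, 0.61, 0.63])
        crit = meal_criterion_from_model(m)
        assert crit.source_components == (1, 2)
        assert crit.mii_minutes == pytest.approx(31.3, abs=0.5)

    def test_symmetric_toy_model(self):
        m = self._model([0.5, 0.5], [0.0, 2.0], [0.4, 0.4])
        assert meal_criterion_from_model(m).mii_minutes == pytest.approx(np.e / 60)

    def test_invariant_to_component_permutation(self):
        a = self._model([0.2, 0.3, 0.5], [4.0, 6.34, 8.77], [0.6, 0.61, 0.63])
        b = self._model([0.5, 0.3, 0.2], [8.77, 6.34, 4.0], [0.63, 0.61, 0.6])
        assert meal_criterion_from_model(a).mii_minutes == pytest.approx(
            meal_criterion_from_model(b).mii_minutes
        )

    def test_single_component_undefined(self):
        m = self._model([1.0], [5.0], [0.5])
        with pytest.raises(ConfigError):
            meal_criterion_from_model(m)

    def test_weighted_variant_shifts_toward_lighter_component(self):
        m = self._model([0.2, 0.7, 0.1], [4.0, 6.34, 8.77], [0.6, 0.61, 0.63])
        plain = meal_criterion_from_model(m).C
        weighted = meal_criterion_from_model(m, weighted=True).C
        # heavier left component pushes the weighted crossing right
        assert weighted > plain
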
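import math

import numpy as np
import pytest

from tumorcal.bayes import (
    MCMCConfig,
    Prior,
    PriorSpec,
    fit_posterior_distribution,
    log_likelihood_pcc,
    log_likelihood_timecourse,
    log_prior,
    pearson_cc,
    posterior_predictive,
    posterior_to_prior,
    run_mcmc,
)
from tumorcal.data_model import FieldSeries, TimeCourseDataset
from tumorcal.forward_models import PhaseFieldState, Trajectory

LOG_2PI = math.log(2 * math.pi)


class TestPriors:
    def test_uniform_log_density(self):
        spec = PriorSpec([Prior("a", "uniform", (0, 10))])
        assert log_prior(np.array([5.0]), spec) == pytest.approx(math.log(0.1))
        assert log_prior(np.array([-1.0]), spec) == -math.inf
        assert log_prior(np.array([10.5]), spec) == -math.inf

    def test_name_mismatch_is_configuration_error(self):
        spec = PriorSpec([Prior("a", "uniform", (0, 1))])
        with pytest.raises(ValueError, match="names"):
            log_prior(np.array([0.5]), spec, names=["b"])

    def test_truncated_normal_integrates_to_one(self):
        p = Prior("x", "normal", (0.1, 0.05), bounds=(0.0, 0.2))
        grid = np.linspace(0.0, 0.2, 20_001)
        dens = np.exp([p.logpdf(x) for x in grid])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_lognormal_density_and_sampling(self):
        p = Prior("x", "lognormal", (-2.11, 0.35))
        from scipy import stats

        ref = stats.lognorm(s=0.35, scale=math.exp(-2.11))
        for x in (0.05, 0.12, 0.3):
            assert p.logpdf(x) == pytest.approx(ref.logpdf(x), rel=1e-9)
        rng = np.random.default_rng(0)
        draws = p.sample(rng, 50_000)
        assert np.log(draws).mean() == pytest.approx(-2.11, abs=0.01)

    def test_empirical_prior_finite_on_support(self):
        rng = np.random.default_rng(1)
        p = Prior("x", "empirical", samples=rng.normal(0.1, 0.02, 500))
        assert math.isfinite(p.logpdf(0.1))

    def test_samples_respect_bounds(self):
        rng = np.random.default_rng(2)
        p = Prior("x", "normal", (0.0, 1.0), bounds=(0.5, 2.0))
        draws = p.sample(rng, 10_000)
        assert draws.min() >= 0.5 and draws.max() <= 2.0


class TestTimecourseLikelihood:
    def _dataset(self, meta, times, values):
        return TimeCourseDataset(meta, times, values)

    def test_zero_residual_single_observation(self, meta_mmc):
        sigma = 0.3
        data = self._dataset(meta_mmc, [0.0], np.array([[0.5]]))
        traj = Trajectory(times=np.array([0.0]), values=np.array([0.5]))
        assert log_likelihood_timecourse(data, traj, sigma) == pytest.approx(
            -0.5 * (LOG_2PI + 2 * math.log(sigma))
        )

    def test_doubling_sigma_costs_log2_per_observation(self, meta_mmc):
        data = self._dataset(meta_mmc, [0.0, 1.0], np.full((2, 4), 0.5))
        traj = Trajectory(times=np.array([0.0, 1.0]), values=np.full(2, 0.5))
        l1 = log_likelihood_timecourse(data, traj, 0.1)
        l2 = log_likelihood_timecourse(data, traj, 0.2)
        assert l1 - l2 == pytest.approx(8 * math.log(2))

    def test_two_point_hand_computation(self, meta_mmc):
        sigma = 0.25
        data = self._dataset(meta_mmc, [0.0, 1.0], np.array([[0.5], [0.5 + sigma]]))
        traj = Trajectory(times=np.array([0.0, 1.0]), values=np.full(2, 0.5))
        assert log_likelihood_timecourse(data, traj, sigma) == pytest.approx(
            -(LOG_2PI + 2 * math.log(sigma)) - 0.5
        )

    def test_replicate_exchangeability(self, small_dataset):
        traj = Trajectory(times=small_dataset.times,
                          values=small_dataset.values.mean(axis=1))
        base = log_likelihood_timecourse(small_dataset, traj, 0.01)
        shuffled = TimeCourseDataset(
            small_dataset.meta, small_dataset.times,
            small_dataset.values[:, ::-1].copy(),
        )
        assert log_likelihood_timecourse(shuffled, traj, 0.01) == pytest.approx(base)

    def test_time_misalignment_raises(self, small_dataset):
        traj = Trajectory(times=small_dataset.times[:-1],
                          values=np.ones(small_dataset.n_times - 1))
        with pytest.raises(ValueError, match="times"):
            log_likelihood_timecourse(small_dataset, traj, 0.1)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (16, 16))
        assert pearson_cc(a, a) == pytest.approx(1.0)
        assert pearson_cc(a, -a + 0.7) == pytest.approx(-1.0)

    def test_independent_noise_fields_near_zero(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert abs(pearson_cc(a, b)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_cc(np.ones(10), np.arange(10.0))

    def test_pcc_likelihood_terms(self):
        rng = np.random.default_rng(2)
        grids = rng.uniform(0.1, 0.9, (3, 8, 8))
        data = FieldSeries(times=np.array([0.0, 0.5, 1.0]), grids=grids.copy(),
                           pixel_size=1.0)
        states = [PhaseFieldState(g.copy(), np.zeros((8, 8)), t)
                  for g, t in zip(data.grids, data.times / 24.0)]
        model = Trajectory(times=data.times / 24.0, states=states)
        sigma = 0.05
        # perfect correlation at every frame: residuals vanish
        assert log_likelihood_pcc(data, model, sigma) == pytest.approx(
            3 * -0.5 * (LOG_2PI + 2 * math.log(sigma))
        )
        # anti-correlated model: residual 2 per frame
        anti = Trajectory(
            times=data.times / 24.0,
            states=[PhaseFieldState(1.0 - g, np.zeros((8, 8)), t)
                    for g, t in zip(data.grids, data.times / 24.0)],
        )
        assert log_likelihood_pcc(data, anti, sigma) == pytest.approx(
            3 * (-0.5 * (LOG_2PI + 2 * math.log(sigma)) - 4.0 / (2 * sigma**2))
        )

    def test_pcc_likelihood_monotone_in_correlation(self):
        # at fixed sigma, blending the model field toward the data raises
        # the PCC and with it the likelihood
        rng = np.random.default_rng(5)
        obs = rng.uniform(0.2, 0.8, (12, 12))
        noise = rng.uniform(0.2, 0.8, (12, 12))
        data = FieldSeries(times=np.array([0.0]), grids=obs[None].copy(),
                           pixel_size=1.0)
        lls = []
        for alpha in (0.0, 0.3, 0.6, 0.9, 1.0):
            blend = alpha * obs + (1 - alpha) * noise
            model = Trajectory(
                times=np.array([0.0]),
                states=[PhaseFieldState(blend, np.zeros_like(blend), 0.0)],
            )
            lls.append(log_likelihood_pcc(data, model, 0.1))
        assert np.all(np.diff(lls) > 0)


class TestMCMC:
    def test_flat_posterior_samples_the_prior(self):
        spec = PriorSpec([Prior("u", "uniform", (0, 1))])
        post = run_mcmc(lambda th: log_prior(th, spec), spec,
                        MCMCConfig(n_steps=40_000, burn_in=3_000, seed=2))
        assert post.draws.mean() == pytest.approx(0.5, abs=0.02)
        assert post.draws.var() == pytest.approx(1 / 12, rel=0.05)

    def test_fixed_seed_bit_identical(self):
        spec = PriorSpec([Prior("u", "uniform", (0, 1))])
        cfg = MCMCConfig(n_steps=2_000, burn_in=500, seed=7)
        a = run_mcmc(lambda th: log_prior(th, spec), spec, cfg)
        b = run_mcmc(lambda th: log_prior(th, spec), spec, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_unidentifiable_setup_raises(self):
        spec = PriorSpec([Prior("u", "uniform", (0, 1))])
        with pytest.raises(RuntimeError, match="unidentifiable"):
            run_mcmc(lambda th: -math.inf, spec, MCMCConfig(n_steps=10, burn_in=10))

    def test_draws_respect_prior_support(self):
        spec = PriorSpec([Prior("u", "uniform", (0.2, 0.8))])
        post = run_mcmc(lambda th: log_prior(th, spec), spec,
                        MCMCConfig(n_steps=5_000, burn_in=1_000, seed=3))
        assert post.draws.min() >= 0.2 and post.draws.max() <= 0.8


class TestPosteriorFitting:
    def test_normal_self_recovery(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.1, 0.02, 100_000)
        fit = fit_posterior_distribution(draws)
        assert fit.prior.family == "normal"
        assert fit.prior.params[0] == pytest.approx(0.1, rel=0.02)
        assert fit.prior.params[1] == pytest.approx(0.02, rel=0.02)

    def test_lognormal_self_recovery(self):
        rng = np.random.default_rng(1)
        draws = np.exp(rng.normal(-2.11, 0.35, 100_000))
        fit = fit_posterior_distribution(draws)
        assert fit.prior.family == "lognormal"
        assert fit.prior.params[0] == pytest.approx(-2.11, rel=0.03)
        assert fit.prior.params[1] == pytest.approx(0.35, rel=0.03)
        assert set(fit.candidates) == {"normal", "lognormal"}

    def test_constant_samples_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_posterior_distribution(np.full(500, 0.3))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="100"):
            fit_posterior_distribution(np.arange(50.0))

    def test_negative_samples_skip_lognormal(self):
        rng = np.random.default_rng(2)
        fit = fit_posterior_distribution(rng.normal(0.0, 1.0, 5_000))
        assert fit.prior.family == "normal"
        assert "lognormal" not in fit.candidates


class TestPosteriorToPrior:
    def _posterior_from(self, draws, name="x"):
        from tumorcal.bayes import PosteriorSample

        return PosteriorSample(
            names=[name], draws=draws[:, None], log_posterior=np.zeros(len(draws)),
            acceptance_rate=0.3, ess=np.array([float(len(draws))]), seed=0,
        )

    def test_self_consistency_at_large_n(self):
        rng = np.random.default_rng(0)
        original = PriorSpec([Prior("x", "uniform", (0, 1))])
        post = self._posterior_from(np.clip(rng.normal(0.4, 0.05, 50_000), 0, 1))
        updated = posterior_to_prior(post, original)
        assert updated["x"].family == "normal"
        assert updated["x"].params[0] == pytest.approx(0.4, rel=0.02)
        assert updated["x"].bounds == (0, 1)

    def test_truncation_to_original_support(self):
        rng = np.random.default_rng(1)
        original = PriorSpec([Prior("x", "uniform", (0, 0.45))])
        post = self._posterior_from(rng.uniform(0.3, 0.44, 5_000))
        updated = posterior_to_prior(post, original)
        draws = updated["x"].sample(np.random.default_rng(2), 20_000)
        assert draws.max() <= 0.45

    def test_round_trip_density_normalized(self):
        rng = np.random.default_rng(3)
        original = PriorSpec([Prior("x", "uniform", (0, 1))])
        post = self._posterior_from(np.clip(rng.normal(0.5, 0.1, 20_000), 0, 1))
        updated = posterior_to_prior(post, original)
        grid = np.linspace(0, 1, 50_001)
        dens = np.exp([updated["x"].logpdf(v) for v in grid])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_uncalibrated_parameters_keep_their_priors(self):
        rng = np.random.default_rng(4)
        original = PriorSpec([Prior("x", "uniform", (0, 1)),
                              Prior("y", "uniform", (0, 2))])
        post = self._posterior_from(rng.uniform(0.2, 0.8, 1_000))
        updated = posterior_to_prior(post, original)
        assert updated["y"] is original["y"]


class TestPosteriorPredictive:
    def _point_mass_posterior(self, theta):
        from tumorcal.bayes import PosteriorSample

        return PosteriorSample(
            names=["lam"], draws=np.full((100, 1), theta),
            log_posterior=np.zeros(100), acceptance_rate=0.3,
            ess=np.array([100.0]), seed=0,
        )

    def test_point_mass_collapses_band(self):
        times = np.arange(0.0, 8.0)
        post = self._point_mass_posterior(0.1)
        band = posterior_predictive(
            post, lambda th: 0.05 * np.exp(-th[0] * times), times, n_draws=500
        )
        np.testing.assert_allclose(band.lower, band.upper)
        np.testing.assert_allclose(band.mean, 0.05 * np.exp(-0.1 * times))

    def test_lognormal_mgf_oracle(self):
        # lam ~ N(0.1, 0.01): E[phi0 e^{-lam t}] = phi0 e^{-0.1 t + 0.00005 t^2}
        from tumorcal.bayes import PosteriorSample

        rng = np.random.default_rng(0)
        draws = rng.normal(0.1, 0.01, 200_000)[:, None]
        post = PosteriorSample(names=["lam"], draws=draws,
                               log_posterior=np.zeros(len(draws)),
                               acceptance_rate=0.3, ess=np.array([1e5]), seed=0)
        times = np.arange(0.0, 8.0)
        band = posterior_predictive(
            post, lambda thetas: 0.05 * np.exp(-thetas[:, [0]] * times), times,
            n_draws=200_000, vectorized=True, seed=1,
        )
        expected = 0.05 * np.exp(-0.1 * times + 0.5 * 0.01**2 * times**2)
        np.testing.assert_allclose(band.mean, expected, rtol=5e-4)

    def test_band_widens_with_posterior_variance(self):
        from tumorcal.bayes import PosteriorSample

        times = np.arange(0.0, 8.0)
        widths = []
        for sd in (0.01, 0.03):
            rng = np.random.default_rng(5)
            draws = rng.normal(0.1, sd, 20_000)[:, None]
            post = PosteriorSample(names=["lam"], draws=draws,
                                   log_posterior=np.zeros(len(draws)),
                                   acceptance_rate=0.3, ess=np.array([1e4]), seed=0)
            band = posterior_predictive(
                post, lambda thetas: 0.05 * np.exp(-thetas[:, [0]] * times), times,
                n_draws=20_000, vectorized=True, seed=2,
            )
            widths.append((band.upper - band.lower)[1:].mean())
        assert widths[1] > widths[0]

    def test_failure_fraction_guard(self):
        post = self._point_mass_posterior(0.1)

        def flaky(th):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="failed"):
            posterior_predictive(post, flaky, np.arange(3.0), n_draws=100)
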
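"""MCMC, point estimation, information criteria and cross-validation."""

import math

import arviz as az
import numpy as np
import pytest
from scipy import stats

from stickcontest.inference import (
    MCMCConfig,
    compare_models,
    kfold_cv,
    log_prior,
    map_estimate,
    psis_loo,
    run_mcmc,
    sample_posterior,
    waic,
)
from stickcontest.response import ResponseParams
from stickcontest.synth import GeneratorConfig, generate_records

FAST = MCMCConfig(n_draws=400, n_chains=4, burn_in=800, thin=5, seed=1)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

class TestSamplePosterior:
    def test_conjugate_normal_mean_recovered(self):
        # flat prior on the mean (the "offset" prior is U(-0.5, 0.5)) and
        # known sd: the posterior is N(ybar, sd^2/n) up to truncation
        rng = np.random.default_rng(0)
        y = rng.normal(0.1, 0.2, size=40)
        post_mean, post_sd = y.mean(), 0.2 / math.sqrt(len(y))

        def log_lik(theta):
            return float(stats.norm.logpdf(y, loc=theta[0], scale=0.2).sum())

        draws, chains, rates, rhat = sample_posterior(log_lik, ("offset",), FAST)
        assert abs(draws.mean() - post_mean) < 4 * post_sd / math.sqrt(50)  # generous MC error
        assert draws.std() == pytest.approx(post_sd, rel=0.3)
        assert rhat["offset"] < 1.1

    def test_same_seed_reproduces_draws(self, records_small):
        config = MCMCConfig(n_draws=80, n_chains=2, burn_in=200, thin=2, seed=11)
        a = run_mcmc(records_small, "rsa-hom", config)
        b = run_mcmc(records_small, "rsa-hom", config)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_prior_only_run_samples_the_prior(self):
        draws, _, _, _ = sample_posterior(lambda theta: 0.0, ("beta", "noise_sd"), FAST)
        beta, noise = draws[:, 0], draws[:, 1]
        assert beta.min() >= 0 and beta.max() <= 10
        assert abs(beta.mean() - 5.0) < 0.6  # U(0, 10) mean
        assert abs(noise.mean() - 0.3 * math.sqrt(2 / math.pi)) < 0.05  # half-normal mean

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1, n_draws=100)


# ---------------------------------------------------------------------------
# Point estimation
# ---------------------------------------------------------------------------

class TestMapEstimate:
    @pytest.fixture(scope="class")
    def pragmatic_only(self):
        config = GeneratorConfig(
            n_participants=400, p_pragmatic=1.0, beta_true=2.0, seed=5,
            response=ResponseParams(offset=0.0, noise_sd=0.1),
        )
        return generate_records(config)

    def test_recovers_generating_bias(self, pragmatic_only):
        fit = map_estimate(pragmatic_only, "rsa-hom", seed=1)
        assert fit["beta"] == pytest.approx(2.0, abs=0.5)
        assert fit["offset"] == pytest.approx(0.0, abs=0.05)
        assert fit["noise_sd"] == pytest.approx(0.1, abs=0.03)

    def test_deterministic_given_seed(self, pragmatic_only):
        a = map_estimate(pragmatic_only, "rsa-hom", seed=3, n_starts=3)
        b = map_estimate(pragmatic_only, "rsa-hom", seed=3, n_starts=3)
        assert a == b

    def test_ml_fit_attains_at_least_map_likelihood(self, pragmatic_only):
        fit_map = map_estimate(pragmatic_only, "rsa-hom", seed=1)
        fit_ml = map_estimate(pragmatic_only, "rsa-hom", seed=1, include_prior=False)
        assert fit_ml["log_lik"] >= fit_map["log_lik"] - 1e-6

    def test_heterogeneous_fit_dominates_nested_homogeneous(self, records_small):
        hom = map_estimate(records_small, "rsa-hom", seed=1, include_prior=False)
        het = map_estimate(
            records_small, "rsa-het", seed=1, include_prior=False,
            extra_starts=[dict(hom, w_prag=1.0)],
        )
        assert het["log_lik"] >= hom["log_lik"] - 1e-8
        mas = map_estimate(records_small, "mas-hom", seed=1, include_prior=False)
        mas_het = map_estimate(
            records_small, "mas-het", seed=1, include_prior=False,
            extra_starts=[dict(mas, w_mas=1.0)],
        )
        assert mas_het["log_lik"] >= mas["log_lik"] - 1e-8

    def test_pure_literal_population_drives_bias_to_zero(self):
        # a pragmatic-only model can explain literal responders only by
        # collapsing to the beta = 0 (literal) listener
        config = GeneratorConfig(
            n_participants=150, p_pragmatic=0.0, seed=21,
            response=ResponseParams(offset=0.0, noise_sd=0.1),
        )
        fit = map_estimate(generate_records(config), "rsa-hom", seed=1)
        assert fit["beta"] < 0.5

    def test_unknown_variant_rejected(self, records_small):
        with pytest.raises(ValueError):
            map_estimate(records_small, "rsa-extra")


# ---------------------------------------------------------------------------
# WAIC and PSIS-LOO
# ---------------------------------------------------------------------------

def conjugate_fixture(n=30, n_draws=4000, seed=2):
    """Normal-mean model with closed-form posterior and exact LOO."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0.3, 1.0, size=n)
    tau2 = 100.0  # effectively flat prior on the mean
    def posterior(data):
        v = 1.0 / (len(data) + 1.0 / tau2)
        return v * data.sum(), v
    m, v = posterior(y)
    mu_draws = rng.normal(m, math.sqrt(v), size=n_draws)
    pointwise = stats.norm.logpdf(y[None, :], loc=mu_draws[:, None], scale=1.0)
    # exact leave-one-out predictive densities
    exact = 0.0
    for i in range(n):
        rest = np.delete(y, i)
        m_i, v_i = posterior(rest)
        exact += stats.norm.logpdf(y[i], loc=m_i, scale=math.sqrt(1.0 + v_i))
    return y, mu_draws, pointwise, -2.0 * exact


class TestInformationCriteria:
    def test_zero_variance_draws_reduce_to_lppd(self):
        row = np.array([-1.3, -0.4, -2.2])
        pointwise = np.tile(row, (50, 1))
        value, se = waic(pointwise)
        assert value == pytest.approx(-2.0 * row.sum(), abs=1e-10)
        loo_value, loo_se, k = psis_loo(pointwise)
        assert loo_value == pytest.approx(value, abs=1e-10)

    def test_waic_matches_exact_loo_on_conjugate_model(self):
        _, _, pointwise, exact_loo = conjugate_fixture()
        value, se = waic(pointwise)
        assert value == pytest.approx(exact_loo, abs=1.0)

    def test_psis_loo_matches_exact_loo_on_conjugate_model(self):
        _, _, pointwise, exact_loo = conjugate_fixture()
        value, se, k = psis_loo(pointwise)
        assert value == pytest.approx(exact_loo, abs=1.0)
        assert np.all(np.isfinite(k))
        assert np.all(k < 0.7)

    def test_matches_arviz_reference_implementation(self):
        _, mu_draws, pointwise, _ = conjugate_fixture()
        idata = az.from_dict(
            posterior={"mu": mu_draws[None, :]},
            log_likelihood={"y": pointwise[None, :, :]},
        )
        ref_waic = az.waic(idata, scale="deviance")
        value, se = waic(pointwise)
        assert value == pytest.approx(float(ref_waic.elpd_waic), rel=1e-5)
        # arviz uses the population variance for the se; we use ddof=1
        assert se == pytest.approx(float(ref_waic.se), rel=0.05)
        ref_loo = az.loo(idata, scale="deviance")
        loo_value, loo_se, _ = psis_loo(pointwise)
        assert loo_value == pytest.approx(float(ref_loo.elpd_loo), rel=1e-4)

    def test_duplicating_observations_doubles_waic(self):
        _, _, pointwise, _ = conjugate_fixture(n=10)
        value, _ = waic(pointwise)
        doubled, _ = waic(np.concatenate([pointwise, pointwise], axis=1))
        assert doubled == pytest.approx(2 * value, abs=1e-8)

    def test_high_variance_points_trigger_warning(self):
        rng = np.random.default_rng(0)
        pointwise = rng.normal(size=(100, 5)) * 2.0
        with pytest.warns(UserWarning, match="p_waic"):
            waic(pointwise)

    def test_requires_at_least_two_draws(self):
        with pytest.raises(ValueError):
            waic(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            psis_loo(np.zeros((1, 4)))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

class TestKFold:
    def test_leave_one_out_partition(self):
        records = generate_records(GeneratorConfig(n_participants=12, seed=9))
        fits = kfold_cv(records, "aa-hom", k=12, seed=1)
        assert len(fits) == 12
        assert (fits["n_train"] == 11).all()

    def test_deterministic_given_seed(self, records_small):
        a = kfold_cv(records_small, "aa-hom", k=5, seed=4)
        b = kfold_cv(records_small, "aa-hom", k=5, seed=4)
        assert a.equals(b)

    def test_fold_mean_recovers_generating_bias(self):
        config = GeneratorConfig(
            n_participants=200, p_pragmatic=1.0, beta_true=2.0, seed=5,
            response=ResponseParams(offset=0.0, noise_sd=0.1),
        )
        fits = kfold_cv(generate_records(config), "rsa-hom", k=5, seed=1)
        assert fits["beta"].mean() == pytest.approx(2.0, abs=0.5)

    def test_rejects_folds_smaller_than_parameter_count(self):
        records = generate_records(GeneratorConfig(n_participants=10, seed=9))
        with pytest.raises(ValueError):
            kfold_cv(records, "rsa-speaker", k=2, seed=1)


# ---------------------------------------------------------------------------
# Posterior coverage of the generating bias
# ---------------------------------------------------------------------------

def test_posterior_interval_covers_generating_bias_across_replicates():
    """The 95% interval for beta from the speaker-dependent fit should
    cover the generating value in >= 90% of replicated experiments."""
    covered = 0
    n_reps = 20
    for rep in range(n_reps):
        records = generate_records(GeneratorConfig(seed=100 + rep))
        post = run_mcmc(records, "rsa-speaker", MCMCConfig(
            n_draws=400, n_chains=4, burn_in=800, thin=5, seed=100 + rep))
        beta = post.draws[:, list(post.param_names).index("beta")]
        lo, hi = np.percentile(beta, [2.5, 97.5])
        covered += lo <= 2.26 <= hi
    assert covered >= 0.9 * n_reps


def test_log_prior_support():
    names = ("beta", "offset", "noise_sd", "w_prag")
    assert np.isfinite(log_prior(np.array([2.0, 0.1, 0.2, 0.5]), names))
    assert log_prior(np.array([-0.1, 0.1, 0.2, 0.5]), names) == -math.inf
    assert log_prior(np.array([2.0, 0.9, 0.2, 0.5]), names) == -math.inf
    assert log_prior(np.array([2.0, 0.1, -0.2, 0.5]), names) == -math.inf
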
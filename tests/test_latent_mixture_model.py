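"""Sampler correctness: conjugate limits, identifiability, diagnostics."""

import numpy as np
import pytest
from scipy.stats import norm

from latentroc.latent_mixture_model import (
    GibbsState,
    MCMCConfig,
    MixturePriors,
    UnidentifiableDataError,
    fit_latent_mixture,
    gibbs_step,
    label_posterior,
    mc_error,
)
from latentroc.synthetic_data import STUDY_POOLED, generate_mixture_scores
from dataclasses import replace


class TestMcError:
    def test_constant_chain_has_zero_error(self):
        assert mc_error(np.full(1000, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_iid_chain_matches_sd_over_sqrt_n(self, rng):
        chain = rng.standard_normal(10_000)
        est = mc_error(chain)
        assert abs(est - 0.01) < 0.003  # SE = SD/sqrt(n) for iid draws

    def test_bounded_by_chain_sd(self, rng):
        chain = rng.standard_normal(500).cumsum()  # strongly autocorrelated
        assert mc_error(chain) <= np.std(chain, ddof=1)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="100"):
            mc_error(np.arange(50))


class TestLabelPosterior:
    def test_density_ratio_oracle(self):
        # independent evaluation through scipy's normal densities
        x, pi = 20.0, 0.102
        num = pi * norm.pdf(x, 29.32, 6.59)
        den = num + (1 - pi) * norm.pdf(x, 11.42, 6.14)
        expected = num / den  # = 0.0937
        got = label_posterior(x, pi, 11.42, 6.14, 29.32, 6.59)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.094, abs=1e-3)

    def test_extreme_scores_classified_with_near_certainty(self):
        assert label_posterior(64, 0.1, 11.42, 6.14, 29.32, 6.59) > 0.999
        assert label_posterior(0, 0.1, 11.42, 6.14, 29.32, 6.59) < 1e-4


class TestConjugateLimits:
    """With labels clamped, the pi chain must match its closed-form posterior."""

    def _clamped_fit(self, sd_mu=100.0):
        ds = generate_mixture_scores(replace(STUDY_POOLED, seed=8), fixed_margin=True)
        priors = MixturePriors(sd_mu_neg=sd_mu, sd_mu_pos=sd_mu)
        return ds, fit_latent_mixture(
            ds,
            priors=priors,
            config=MCMCConfig(n_iter=4000, n_burnin=500, seed=3),
            fixed_labels=ds.true_label,
        )

    def test_prevalence_matches_beta_posterior(self):
        # k=22 of n=215 -> Beta(23, 194): mean 23/217
        _, draws = self._clamped_fit()
        expected_mean = 23 / 217
        expected_sd = np.sqrt(23 * 194 / (217**2 * 218))
        err = mc_error(draws.pi)
        assert abs(draws.pi.mean() - expected_mean) < 4 * err
        assert abs(draws.pi.std(ddof=1) - expected_sd) < 0.2 * expected_sd

    def test_flat_prior_mean_centres_on_component_average(self):
        # with sd_mu -> inf the mu full conditional centres on the sample mean
        ds, draws = self._clamped_fit(sd_mu=1e6)
        neg_mean = ds.scores[ds.true_label == 0].mean()
        assert abs(draws.mu_neg.mean() - neg_mean) < 4 * mc_error(draws.mu_neg) + 0.02


class TestGibbsStep:
    def test_single_sweep_preserves_invariants(self, rng):
        scores = generate_mixture_scores(replace(STUDY_POOLED, seed=2)).scores.astype(float)
        priors = MixturePriors.anchored(scores).resolve(scores)
        state = GibbsState(
            pi=0.5, mu_neg=10.0, sigma_neg=6.0, mu_pos=28.0, sigma_pos=6.0,
            z=(scores > 20).astype(int),
        )
        state, _ = gibbs_step(state, scores, priors, rng)
        assert 0 < state.pi < 1
        assert state.mu_pos > state.mu_neg
        low_n, high_n = priors.sigma_bounds("neg")
        low_p, high_p = priors.sigma_bounds("pos")
        assert low_n <= state.sigma_neg <= high_n
        assert low_p <= state.sigma_pos <= high_p


class TestFitLatentMixture:
    def test_seed_determinism(self, study_data):
        cfg = MCMCConfig(n_iter=300, n_burnin=100, seed=5)
        a = fit_latent_mixture(study_data, config=cfg)
        b = fit_latent_mixture(study_data, config=cfg)
        for p in a.PARAMS:
            np.testing.assert_array_equal(getattr(a, p), getattr(b, p))
        np.testing.assert_array_equal(a.label_prob, b.label_prob)

    def test_ordering_constraint_in_every_draw(self, study_fit):
        assert (study_fit.mu_pos > study_fit.mu_neg).all()
        assert ((study_fit.pi > 0) & (study_fit.pi < 1)).all()

    def test_sigma_draws_respect_prior_bounds(self, study_data, study_fit):
        priors = MixturePriors.anchored(study_data.scores)
        assert study_fit.sigma_neg.max() <= priors.sigma_bounds("neg")[1]
        assert study_fit.sigma_pos.max() <= priors.sigma_bounds("pos")[1]
        assert study_fit.sigma_neg.min() >= priors.sigma_low

    def test_label_probabilities_average_to_prevalence(self, study_fit):
        assert study_fit.label_prob.min() >= 0 and study_fit.label_prob.max() <= 1
        diff = abs(study_fit.label_prob.mean() - study_fit.pi.mean())
        assert diff < 4 * mc_error(study_fit.pi) + 0.005

    def test_sigma_acceptance_in_healthy_band(self, study_fit):
        for rate in study_fit.accept_rate.values():
            assert 0.1 < rate < 0.7

    def test_identical_scores_unidentifiable(self):
        with pytest.raises(UnidentifiableDataError):
            fit_latent_mixture(np.full(215, 20.0))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_latent_mixture(np.array([1.0, 2.0, 3.0]))

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError, match="n_iter"):
            MCMCConfig(n_iter=50)

    def test_parameter_recovery_on_large_synthetic_sample(self):
        truth = replace(STUDY_POOLED, n=2000, seed=5000)
        ds = generate_mixture_scores(truth, rounding="continuous")
        draws = fit_latent_mixture(
            ds, config=MCMCConfig(n_iter=2000, n_burnin=600, seed=600)
        )
        s = draws.summary()
        for param, true_val in {
            "pi": truth.prevalence,
            "mu_neg": truth.mu_neg,
            "sigma_neg": truth.sigma_neg,
            "mu_pos": truth.mu_pos,
            "sigma_pos": truth.sigma_pos,
        }.items():
            z = abs(s.loc[param, "mean"] - true_val) / s.loc[param, "sd"]
            assert z < 2, f"{param}: posterior mean {s.loc[param, 'mean']:.3f} vs {true_val}"


class TestMixturePriors:
    def test_anchored_policy_orients_components(self, study_data):
        pr = MixturePriors.anchored(study_data.scores)
        assert pr.mu0_pos > pr.mu0_neg
        assert pr.sigma_bounds("pos")[1] >= 3.0
        assert pr.sigma_bounds("neg")[1] >= 3.0

    def test_vague_policy_resolves_quartile_centres(self, study_data):
        pr = MixturePriors().resolve(study_data.scores.astype(float))
        q25, q75 = np.percentile(study_data.scores, [25, 75])
        assert pr.mu0_neg == pytest.approx(q25)
        assert pr.mu0_pos == pytest.approx(max(q75, q25 + 1.0))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            MixturePriors(sigma_low=5.0, sigma_high=1.0)
        with pytest.raises(ValueError):
            MixturePriors(prev_alpha=0.0)
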
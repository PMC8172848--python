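"""MCMC inference: exact full-conditional checks, an importance-sampling
oracle for the tiny-data posterior, directional behaviour of the two model
variants, and estimator contracts."""

import math

import numpy as np
import pytest

from ednaocc import (
    IdentifiabilityWarning,
    MCMCConfig,
    ModelParams,
    MultiScaleOccupancyModel,
    SimulationConfig,
    compare_models,
    fit_full_model,
    fit_no_false_positive_model,
    simulate_dataset,
    site_occupancy_posteriors,
)
from ednaocc.sampler import occupancy_full_conditional, sample_state_full_conditional

from conftest import binom_pmf, brute_force_occupancy_given_data, make_dataset


class TestFullConditionals:
    """Gibbs full conditionals must agree exactly with direct Bayes rule."""

    def test_occupancy_given_sample_states(self):
        psi, th11, th10 = 0.3, 0.8, 0.05
        # one site, samples states a = (1, 0)
        num = psi * th11 * (1 - th11)
        den = num + (1 - psi) * th10 * (1 - th10)
        p = occupancy_full_conditional(
            psi, th11, th10, a=[True, False], site_index=[0, 0], n_sites=1
        )
        assert p[0] == pytest.approx(num / den, abs=1e-14)

    def test_sample_state_given_occupancy(self):
        th11, th10, p11, p10 = 0.8, 0.05, 0.9, 0.1
        k, y = 4, 2
        num = th11 * binom_pmf(y, k, p11)
        den = num + (1 - th11) * binom_pmf(y, k, p10)
        p = sample_state_full_conditional(
            z=[True], theta11=th11, theta10=th10, p11=p11, p10=p10,
            k=[k], y=[y], site_index=[0],
        )
        # binomial coefficients cancel in the ratio
        assert p[0] == pytest.approx(num / den, abs=1e-12)

    def test_unoccupied_site_uses_stage1_false_positive_rate(self):
        th11, th10, p11, p10 = 0.8, 0.05, 0.9, 0.1
        k, y = 4, 2
        num = th10 * binom_pmf(y, k, p11)
        den = num + (1 - th10) * binom_pmf(y, k, p10)
        p = sample_state_full_conditional(
            z=[False], theta11=th11, theta10=th10, p11=p11, p10=p10,
            k=[k], y=[y], site_index=[0],
        )
        assert p[0] == pytest.approx(num / den, abs=1e-12)


def _importance_posterior(dataset, n_draws, seed):
    """Posterior means by importance sampling from the (truncated) prior.

    Independent of the Gibbs sampler: draws the five probabilities from the
    default priors restricted to the identifiable orientation, weights each
    draw by the exact marginal likelihood, and returns weighted means.
    """
    rng = np.random.default_rng(seed)
    psi = rng.beta(1, 1, n_draws)
    th11, th10 = rng.beta(1, 1, n_draws), rng.beta(1, 19, n_draws)
    p11, p10 = rng.beta(1, 1, n_draws), rng.beta(1, 19, n_draws)
    keep = (th11 > th10) & (p11 > p10)
    psi, th11, th10, p11, p10 = (v[keep] for v in (psi, th11, th10, p11, p10))

    log_w = np.zeros(psi.size)
    for i in range(dataset.n_sites):
        f1 = np.ones(psi.size)
        f0 = np.ones(psi.size)
        for k, y in dataset.site_samples(i):
            c = math.comb(k, y)
            b11 = c * p11**y * (1 - p11) ** (k - y)
            b10 = c * p10**y * (1 - p10) ** (k - y)
            f1 *= th11 * b11 + (1 - th11) * b10
            f0 *= th10 * b11 + (1 - th10) * b10
        log_w += np.log((1 - psi) * f0 + psi * f1)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    ess = 1.0 / np.sum(w**2)
    means = {name: float(np.sum(w * v)) for name, v in
             zip(("psi", "theta11", "theta10", "p11", "p10"), (psi, th11, th10, p11, p10))}
    return means, ess


class TestPosteriorCorrectness:
    def test_tiny_data_posterior_matches_importance_sampling(self):
        """S=3, M=2, K=2: Gibbs posterior means vs. prior-weighted enumeration."""
        dataset = make_dataset(
            [
                ("A", False, [(2, 2), (2, 1)]),
                ("B", False, [(2, 0), (2, 0)]),
                ("C", False, [(2, 0), (2, 1)]),
            ]
        )
        oracle, ess = _importance_posterior(dataset, n_draws=400_000, seed=123)
        assert ess > 2000  # importance sample is informative enough to compare
        result = fit_full_model(
            dataset,
            mcmc=MCMCConfig(n_burnin=2000, n_iterations=20000, thinning=5, seed=31),
        )
        for name in ("psi", "theta11", "p11"):
            assert result.summary.loc[name, "mean"] == pytest.approx(
                oracle[name], abs=0.04
            ), name
        for name in ("theta10", "p10"):
            assert result.summary.loc[name, "mean"] == pytest.approx(
                oracle[name], abs=0.02
            ), name

    def test_two_site_occupancy_posterior_against_enumeration(self):
        """Strong-signal data: site posteriors approach the fixed-parameter
        Bayes answer computed by enumeration at the posterior mean."""
        params = ModelParams(0.3, 0.9, 0.02, 0.95, 0.02)
        dataset = make_dataset(
            [("A", False, [(12, 11)]), ("B", False, [(12, 0)])]
            + [(f"pad{i}", False, [(12, 12 if i % 3 == 0 else 0)]) for i in range(60)]
        )
        result = fit_full_model(
            dataset, mcmc=MCMCConfig(n_burnin=1000, n_iterations=4000, thinning=2, seed=7)
        )
        post = site_occupancy_posteriors(result)
        fitted = ModelParams.from_dict(
            {n: result.summary.loc[n, "mean"] for n in ("psi", "theta11", "theta10", "p11", "p10")}
        )
        for sid, samples in [("A", [(12, 11)]), ("B", [(12, 0)])]:
            expected = brute_force_occupancy_given_data(fitted, samples)
            got = float(post.loc[post["site_id"] == sid, "mean"].iloc[0])
            assert got == pytest.approx(expected, abs=0.05)


class TestDirectionalBehaviour:
    def test_saturated_data(self):
        """Every site confirmed and every replicate amplifying pins the
        occupancy and true-positive rates near one."""
        dataset = make_dataset(
            [(f"s{i}", True, [(12, 12), (12, 12)]) for i in range(30)]
        )
        result = fit_full_model(dataset, mcmc=MCMCConfig(seed=3))
        for name in ("psi", "theta11", "p11"):
            assert result.summary.loc[name, "mean"] > 0.9, name

    def test_confirmed_site_reports_certain_occupancy(self, paper_params):
        dataset = make_dataset(
            [("conf", True, [(12, 0)])]
            + [(f"s{i}", False, [(12, 0)]) for i in range(20)]
        )
        result = fit_full_model(dataset, mcmc=MCMCConfig(seed=4))
        post = site_occupancy_posteriors(result)
        assert float(post.loc[post["site_id"] == "conf", "mean"].iloc[0]) == 1.0

    def test_all_negative_data_pulls_psi_below_prior_mean(self):
        dataset = make_dataset([(f"s{i}", False, [(12, 0), (12, 0)]) for i in range(50)])
        result = fit_no_false_positive_model(dataset, mcmc=MCMCConfig(seed=5))
        assert result.summary.loc["psi", "mean"] < 0.5  # prior mean is 0.5

    def test_ignoring_false_positives_inflates_occupancy(self, paper_params):
        """On data containing false positives the constrained model's psi
        estimate exceeds the full model's."""
        dataset = simulate_dataset(
            SimulationConfig(S=800, M=2, K=12, params=paper_params, seed=21)
        )
        full = fit_full_model(dataset, mcmc=MCMCConfig(seed=22))
        nofp = fit_no_false_positive_model(dataset, mcmc=MCMCConfig(seed=23))
        assert (
            nofp.summary.loc["psi", "mean"] > full.summary.loc["psi", "mean"]
        )

    def test_nested_models_agree_without_false_positives(self):
        """No false positives in the data *and* the priors: the full model
        collapses onto the constrained one."""
        from ednaocc import BetaPrior, PriorSpec

        params = ModelParams(0.3, 0.85, 0.0, 0.9, 0.0)
        dataset = simulate_dataset(
            SimulationConfig(S=400, M=2, K=6, params=params, seed=33)
        )
        priors = PriorSpec(theta10=BetaPrior(1, 1e4), p10=BetaPrior(1, 1e4))
        full = fit_full_model(dataset, priors=priors, mcmc=MCMCConfig(seed=34))
        nofp = fit_no_false_positive_model(dataset, priors=priors, mcmc=MCMCConfig(seed=35))
        assert full.summary.loc["psi", "mean"] == pytest.approx(
            nofp.summary.loc["psi", "mean"], abs=0.02
        )


class TestEstimatorContract:
    def test_fit_is_deterministic_given_random_state(self, paper_params):
        dataset = simulate_dataset(
            SimulationConfig(S=50, M=2, K=6, params=paper_params, seed=1)
        )
        kwargs = dict(n_burnin=100, n_iterations=200, thinning=10, random_state=8)
        a = MultiScaleOccupancyModel(**kwargs).fit(dataset)
        b = MultiScaleOccupancyModel(**kwargs).fit(dataset)
        assert a.draws_.equals(b.draws_)
        assert a.site_occupancy_.equals(b.site_occupancy_)

    def test_sklearn_params_round_trip(self):
        model = MultiScaleOccupancyModel(n_chains=2, random_state=1)
        clone = MultiScaleOccupancyModel(**model.get_params())
        assert clone.get_params() == model.get_params()

    def test_fitted_attributes_and_predict(self, paper_params):
        dataset = simulate_dataset(
            SimulationConfig(S=80, M=2, K=6, params=paper_params, seed=2)
        )
        model = MultiScaleOccupancyModel(
            n_burnin=200, n_iterations=400, thinning=4, random_state=9
        ).fit(dataset)
        for name in ("psi_", "theta11_", "theta10_", "p11_", "p10_"):
            assert 0.0 <= getattr(model, name) <= 1.0
        proba = model.predict_proba()
        assert proba.shape == (80,)
        # re-scoring the training data reproduces the stored site posteriors
        np.testing.assert_allclose(model.predict_proba(dataset), proba, atol=1e-10)
        assert set(np.unique(model.predict(dataset))) <= {0, 1}

    def test_single_sample_design_warns_when_unidentifiable(self, paper_params):
        dataset = simulate_dataset(
            SimulationConfig(
                S=40, M=1, K=12, params=paper_params, include_covariates=False, seed=6
            )
        )
        with pytest.warns(IdentifiabilityWarning):
            MultiScaleOccupancyModel(
                n_burnin=50, n_iterations=100, thinning=10, random_state=0
            ).fit(dataset)

    def test_covariate_fit_keeps_orientation_and_reports_coefficients(self, paper_params):
        dataset = simulate_dataset(
            SimulationConfig(S=150, M=2, K=6, params=paper_params, seed=12)
        )
        model = MultiScaleOccupancyModel(
            covariates="all", n_burnin=300, n_iterations=600, thinning=6, random_state=13
        ).fit(dataset)
        draws = model.draws_
        assert np.all(draws["theta11"] > draws["theta10"])
        assert np.all(draws["p11"] > draws["p10"])
        assert "beta_psi_cov_continuous" in draws.columns
        assert "beta_p11_cov_binary" in draws.columns

    def test_summary_interval_brackets_mean(self, paper_params):
        dataset = simulate_dataset(
            SimulationConfig(S=60, M=2, K=6, params=paper_params, seed=14)
        )
        result = fit_full_model(
            dataset, mcmc=MCMCConfig(n_burnin=100, n_iterations=200, thinning=10, seed=15)
        )
        s = result.summary
        assert (s["pci_lower"] <= s["mean"]).all()
        assert (s["mean"] <= s["pci_upper"]).all()
        assert len(result.draws) == result.n_chains * result.n_stored


class TestModelComparison:
    def _results_pair(self, paper_params):
        dataset = simulate_dataset(
            SimulationConfig(S=100, M=2, K=6, params=paper_params, seed=41)
        )
        mcmc = MCMCConfig(n_burnin=200, n_iterations=400, thinning=4, seed=42)
        return (
            fit_full_model(dataset, mcmc=mcmc),
            fit_no_false_positive_model(dataset, mcmc=mcmc),
        )

    def test_self_comparison(self, paper_params):
        full, _ = self._results_pair(paper_params)
        report = compare_models(full, full)
        assert report.frac_constrained_higher == 0.0
        assert report.frac_pci_overlap == 1.0

    def test_fractions_bounded(self, paper_params):
        full, nofp = self._results_pair(paper_params)
        report = compare_models(full, nofp)
        for value in (
            report.frac_constrained_higher,
            report.frac_constrained_wider,
            report.frac_pci_overlap,
        ):
            assert 0.0 <= value <= 1.0

    def test_mismatched_sites_rejected(self, paper_params):
        full, nofp = self._results_pair(paper_params)
        trimmed = nofp.site_occupancy.iloc[:-1]
        nofp.site_occupancy = trimmed
        with pytest.raises(ValueError, match="site"):
            compare_models(full, nofp)
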
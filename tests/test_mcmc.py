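"""Sampler contracts, convergence diagnostics, and posterior predictive checks."""

import numpy as np
import pandas as pd
import pytest

import cjspersist as cp
from cjspersist.likelihood import ModelData, Params
from cjspersist.mcmc import ModelSpec, PosteriorDraws


def small_fit(seed=4, n_pop=60, iters=8000):
    truth_spec = cp.TruthSpec(n_populations=n_pop)
    data, truth = cp.simulate_matrices(truth_spec, seed=seed)
    spec = ModelSpec(chains=2, iterations=iters, burn_in=iters // 2, thin=4, seed=seed)
    return data, truth, cp.run_mcmc(spec, data)


class TestSamplerContracts:
    def test_same_seed_identical_draws(self):
        data, _ = cp.simulate_matrices(cp.TruthSpec(n_populations=20), seed=9)
        spec = ModelSpec(chains=2, iterations=3000, burn_in=1500, thin=3, seed=77)
        a = cp.run_mcmc(spec, data)
        b = cp.run_mcmc(spec, data)
        np.testing.assert_array_equal(a.thetas, b.thetas)
        np.testing.assert_array_equal(a.persist_draws, b.persist_draws)

    def test_prior_only_run_recovers_prior(self):
        # zero populations: the posterior is the Normal(0, 10) prior
        empty = ModelData(
            np.zeros((0, 5), np.int8), np.zeros((0, 5)), np.zeros(0, np.int64),
            np.zeros(0, np.int64), np.zeros((0, 3)), np.arange(5), 0.0, ("eco0",),
        )
        spec = ModelSpec(chains=3, iterations=40000, burn_in=10000, thin=5, seed=3)
        draws = cp.run_mcmc(spec, empty)
        flat = draws.flat()
        se = 10.0 / np.sqrt(200.0)  # generous effective-sample allowance
        assert np.all(np.abs(flat.mean(axis=0)) < 4 * se)
        assert np.all(np.abs(flat.std(axis=0) - 10.0) < 1.5)

    def test_acceptance_rates_near_target(self):
        data, _, draws = small_fit(seed=10, n_pop=40, iters=6000)
        assert np.all(draws.acceptance > 0.15) and np.all(draws.acceptance < 0.6)

    def test_persistence_one_for_final_year_detections(self):
        data, truth, draws = small_fit(seed=12, n_pop=50, iters=4000)
        final = data.y[:, -1] == 1
        if final.any():
            np.testing.assert_allclose(draws.persist_mean[final], 1.0)
        assert np.all((draws.persist_mean >= 0) & (draws.persist_mean <= 1))

    def test_augmented_sampler_matches_marginalized(self):
        # Gibbs-on-latent-states and marginalized samplers target one posterior
        data, _ = cp.simulate_matrices(
            cp.TruthSpec(n_populations=40), seed=21, year_range=(1995, 2014)
        )
        spec = ModelSpec(
            year_range=(1995, 2014), chains=2, iterations=30000, burn_in=10000, thin=10, seed=5
        )
        marg = cp.run_mcmc(spec, data).flat()
        aug = cp.run_mcmc_augmented(spec, data).reshape(-1, marg.shape[1])
        import arviz as az
        from scipy.stats import ks_2samp

        for j in range(marg.shape[1]):
            ma, au = marg[:, j], aug[:, j]
            ess_m = az.ess(ma.reshape(2, -1))
            ess_a = az.ess(au.reshape(2, -1))
            se = np.sqrt(ma.var() / max(ess_m, 4) + au.var() / max(ess_a, 4))
            assert abs(ma.mean() - au.mean()) < 5 * se
            # KS on thinned draws; threshold sized for the effective samples
            sa, sb = ma[:: max(1, len(ma) // 300)], au[:: max(1, len(au) // 300)]
            stat = ks_2samp(sa, sb).statistic
            assert stat < 2.5 * np.sqrt(2.0 / min(ess_m, ess_a, 300))


class TestGelmanRubin:
    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.normal(0.0, 1.0, size=(4, 5000))
        rhat, degenerate = cp.gelman_rubin(chains)
        assert 0.99 <= rhat <= 1.05 and not degenerate

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 2000), rng.normal(3, 1, 2000)])
        rhat, _ = cp.gelman_rubin(chains)
        assert rhat > 1.1

    def test_constant_chains_degenerate(self):
        chains = np.stack([np.zeros(100), np.ones(100)])
        rhat, degenerate = cp.gelman_rubin(chains)
        assert degenerate and np.isinf(rhat)

    def test_matches_hand_formula_on_fixed_arrays(self):
        x = np.array(
            [[1.0, 2.0, 3.0, 4.0, 2.0, 1.0, 0.0, 3.0, 2.0, 2.0],
             [2.0, 3.0, 1.0, 2.0, 4.0, 3.0, 2.0, 1.0, 2.0, 3.0]]
        )
        # split each chain in half -> 4 half-chains of 5
        halves = x.reshape(4, 5)
        W = halves.var(axis=1, ddof=1).mean()
        B_over_n = halves.mean(axis=1).var(ddof=1)
        expected = np.sqrt((4 / 5 * W + B_over_n) / W)
        rhat, _ = cp.gelman_rubin(x)
        assert rhat == pytest.approx(expected, abs=1e-12)

    def test_matches_arviz_split_rhat(self, rng):
        chains = rng.normal(0, 1, size=(3, 400)) + rng.normal(0, 0.3, size=(3, 1))
        import arviz as az

        ours, _ = cp.gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values.ravel()[0])
        assert ours == pytest.approx(theirs, abs=0.02)


class TestSummaries:
    def fake_draws(self, flat):
        flat = np.asarray(flat, dtype=float)
        return PosteriorDraws(
            thetas=flat.reshape(1, *flat.shape),
            param_names=Params.names(("eco0",)),
            ecoregion_names=("eco0",),
            persist_mean=np.array([0.5]),
            persist_draws=np.full((10, 1), 0.5),
            acceptance=np.full((1, 7), 0.37),
            spec=ModelSpec(chains=2, iterations=100, burn_in=50, thin=1),
        )

    def test_symmetric_draws_centered(self, rng):
        flat = rng.normal(2.0, 0.5, size=(4000, 7))
        s = cp.summarize_posterior(self.fake_draws(flat))
        assert np.allclose(s.loc[:6, "mean"], 2.0, atol=0.1)

    def test_positive_coefficient_flagged_important(self, rng):
        flat = np.abs(rng.normal(1.0, 0.2, size=(500, 7)))
        s = cp.summarize_posterior(self.fake_draws(flat)).set_index("parameter")
        assert bool(s.loc["beta_hs", "important"])

    def test_percentiles_match_sort_oracle(self, rng):
        vals = rng.normal(size=1000)
        flat = np.tile(vals[:, None], (1, 7))
        s = cp.summarize_posterior(self.fake_draws(flat))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        assert s.loc[0, "q2.5"] == pytest.approx(lo) and s.loc[0, "q97.5"] == pytest.approx(hi)


class TestPosteriorPredictive:
    def test_zero_detection_draws_simulate_zero(self):
        data, _ = cp.simulate_matrices(cp.TruthSpec(n_populations=15), seed=2)
        dead = Params(np.zeros(3), 0, 0, 0, -60.0, 0.0, 0.0).to_vector()
        out = cp.posterior_predictive_check(np.tile(dead, (50, 1)), data, windows=((1970, 1974),), n_draws=50)
        assert out.loc[0, "simulated_mean"] == 0.0

    def test_certain_detection_single_population(self):
        y = np.ones((1, 3), np.int8)
        data = ModelData(y, np.zeros((1, 3)), [3], [0], np.zeros((1, 3)), np.arange(2000, 2003), 2000.0, ("eco0",))
        sure = Params([60.0], 0, 0, 0, 60.0, 0.0, 0.0).to_vector()
        out = cp.posterior_predictive_check(np.tile(sure, (20, 1)), data, windows=((2000, 2000),), n_draws=20)
        assert out.loc[0, "simulated_mean"] == 1.0 and out.loc[0, "observed"] == 1.0
        assert out.loc[0, "p_value"] == 1.0  # ties count toward the upper tail

    def test_window_outside_years_rejected(self):
        data, _ = cp.simulate_matrices(cp.TruthSpec(n_populations=5), seed=2)
        with pytest.raises(ValueError):
            cp.posterior_predictive_check(np.zeros((10, 9)), data, windows=((1900, 1905),))
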
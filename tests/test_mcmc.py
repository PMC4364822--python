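"""Sampler correctness: conjugate updates, Metropolis targets, latent Gibbs."""

import numpy as np
import pytest

import pitmark as pm
from pitmark import mcmc
from pitmark.diagnostics import effective_sample_size
from .conftest import make_set, monthly_calendar


class TestLatentGibbs:
    def test_fully_observed_row_unchanged(self, cal4):
        hset = make_set(cal4, ["1 1 1 1"])
        spec = pm.preset("model3")
        latent = pm.init_latent_states(hset, spec)
        rng = np.random.default_rng(0)
        params = pm.ParamState([0.9], [0.8], [0.4])
        for _ in range(10):
            latent = mcmc.update_latent_states(latent, hset, params, spec, rng)
            assert latent.death_occasion.tolist() == [4]

    def test_certain_survival_forces_alive(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1 0"])
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        rng = np.random.default_rng(0)
        params = pm.ParamState([1.0 - 1e-15], [0.5])
        for _ in range(20):
            latent = mcmc.update_latent_states(latent, hset, params, spec, rng)
            assert latent.death_occasion[0] == 2

    def test_two_path_posterior_frequency(self):
        """For a '1 0' row without the dead layer, P(alive) is the Bayes
        ratio s(1-p) / (s(1-p) + (1-s)); check the Gibbs frequency over
        10^5 parallel rows within 3 Monte-Carlo standard errors."""
        s, p = 0.8, 0.9
        n = 100_000
        cal = monthly_calendar(2)
        codes = np.tile(np.array([1, 0], np.int8), (n, 1))
        hset = pm.CaptureHistorySet(
            codes, np.zeros(n, int), tuple(f"i{j}" for j in range(n)), cal
        )
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        rng = np.random.default_rng(42)
        params = pm.ParamState([s], [p])
        latent = mcmc.update_latent_states(latent, hset, params, spec, rng)
        frac_alive = float((latent.death_occasion == 2).mean())
        target = s * (1 - p) / (s * (1 - p) + (1 - s))
        se = np.sqrt(target * (1 - target) / n)
        assert abs(frac_alive - target) < 3 * se


class TestDetectionUpdate:
    def test_zero_trials_samples_the_prior(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1"], release=[1])  # released at the last occasion
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        rng = np.random.default_rng(1)
        draws = [
            mcmc.update_detection(latent, hset, spec, None, "live", rng)
            for _ in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(0.5, abs=3 * np.sqrt(1 / 12 / 4000))

    def test_full_conditional_is_beta(self):
        """With known latent states the update must average to the Beta
        posterior mean (1+y)/(2+m)."""
        truth = pm.study_truth(s=1.0, pcl=0.9, pcd=0.5, seed=3)
        hset = pm.simulate_histories(truth)
        spec = pm.preset("model3")
        latent = pm.init_latent_states(hset, spec)  # unique: nobody died
        karr = np.arange(hset.n_occasions)
        trials = int((karr[None, :] > hset.release[:, None]).sum())
        succ = int(((hset.codes == 1) & (karr[None, :] > hset.release[:, None])).sum())
        rng = np.random.default_rng(7)
        draws = [
            mcmc.update_detection(latent, hset, spec, None, "live", rng)
            for _ in range(3000)
        ]
        mean = (1 + succ) / (2 + trials)
        sd = np.sqrt(mean * (1 - mean) / (3 + trials))
        assert np.mean(draws) == pytest.approx(mean, abs=3 * sd / np.sqrt(3000) + 1e-4)

    def test_all_success_mean(self):
        cal = monthly_calendar(4)
        hset = make_set(cal, ["1 1 1 1", "1 1 1 1"])
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        rng = np.random.default_rng(2)
        m = 6  # post-release detection cells
        draws = [
            mcmc.update_detection(latent, hset, spec, None, "live", rng)
            for _ in range(6000)
        ]
        assert np.mean(draws) == pytest.approx((m + 1) / (m + 2), abs=0.01)


class TestSurvivalUpdate:
    def test_exposure_closed_form(self):
        """All transitions survived, total exposure E mussel-months: the
        full conditional is proportional to S^E, whose mean is
        (E+1)/(E+2)."""
        cal = monthly_calendar(3)
        hset = make_set(cal, ["1 1 1"] * 5)
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        rng = np.random.default_rng(5)
        exposure = 10.0  # 5 rows x 2 transitions x 1 month
        value, trace = 0.5, []
        for _ in range(8000):
            value = mcmc.update_survival(latent, hset, spec, None, value, 1.0, rng)
            trace.append(value)
        trace = np.asarray(trace[500:])
        target = (exposure + 1) / (exposure + 2)
        sd = np.sqrt(target * (1 - target) / (exposure + 3))
        mcse = sd / np.sqrt(effective_sample_size(trace))
        assert trace.mean() == pytest.approx(target, abs=3 * mcse)

    def test_no_data_samples_the_prior(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1"], release=[1])
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        rng = np.random.default_rng(6)
        value, trace = 0.5, []
        for _ in range(6000):
            value = mcmc.update_survival(latent, hset, spec, None, value, 2.0, rng)
            trace.append(value)
        trace = np.asarray(trace)
        mcse = np.sqrt(1 / 12) / np.sqrt(effective_sample_size(trace))
        assert trace.mean() == pytest.approx(0.5, abs=3 * mcse)


class TestHierarchicalUpdate:
    def _one_row_setup(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1"], release=[1])  # flat likelihood
        spec = pm.preset("model4-1")
        latent = pm.init_latent_states(hset, spec)
        params = pm.ParamState([0.5], [0.5])
        params.s_i = np.array([[0.5]])
        params.pcl_i = np.array([[0.5]])
        params.sigma_s = 0.1
        params.sigma_pcl = 0.1
        return hset, spec, latent, params

    def test_flat_likelihood_individual_samples_truncnorm_prior(self):
        from scipy.stats import truncnorm

        hset, spec, latent, params = self._one_row_setup()
        rng = np.random.default_rng(8)
        trace = []
        state = params
        for _ in range(6000):
            new = mcmc.update_hierarchical(latent, hset, state, spec, rng)
            # hold the hyperparameters fixed so the marginal of the
            # individual value is exactly its truncated-normal prior
            new.s = np.array([0.5])
            new.pcl = np.array([0.5])
            new.sigma_s, new.sigma_pcl = 0.1, 0.1
            state = new
            trace.append(float(state.pcl_i[0, 0]))
        trace = np.asarray(trace[1000:])
        a, b = (0 - 0.5) / 0.1, (1 - 0.5) / 0.1
        target = truncnorm.mean(a, b, loc=0.5, scale=0.1)
        mcse = trace.std() / np.sqrt(effective_sample_size(trace))
        assert trace.mean() == pytest.approx(target, abs=max(3 * mcse, 0.01))

    def test_sigma_to_zero_collapses_individuals(self):
        hset, spec, latent, params = self._one_row_setup()
        params.sigma_s = params.sigma_pcl = 1e-7
        rng = np.random.default_rng(9)
        for _ in range(200):
            new = mcmc.update_hierarchical(latent, hset, params, spec, rng)
            new.sigma_s = new.sigma_pcl = 1e-7
            params = new
        assert params.pcl_i[0, 0] == pytest.approx(float(params.pcl[0]), abs=1e-5)

    def test_nonhierarchical_spec_rejected(self):
        hset, _, latent, params = self._one_row_setup()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mcmc.update_hierarchical(latent, hset, params, pm.preset("model4"), rng)


class TestRunChains:
    def test_same_seed_identical_draws(self, reconstruction):
        cfg = pm.McmcConfig(n_chains=2, n_iter=400, burn_in=100, seed=3)
        spec = pm.preset("model3")
        a = pm.run_chains(reconstruction, spec, cfg)
        b = pm.run_chains(reconstruction, spec, cfg)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_retention_and_bounds(self, reconstruction):
        cfg = pm.McmcConfig(n_chains=2, n_iter=600, burn_in=100, thin=5, seed=4)
        draws = pm.run_chains(reconstruction, pm.preset("model3"), cfg)
        for name, arr in draws.draws.items():
            assert arr.shape == (2, 100)
            assert np.all(arr >= 0) and np.all(arr <= 1)

    def test_chain_seed_permutation_leaves_pooled_summary_invariant(self):
        truth = pm.study_truth(s=0.95, pcl=0.9, pcd=0.4, seed=1)
        hset = pm.simulate_histories(truth)
        spec = pm.preset("model3")
        a = pm.run_chains(hset, spec, pm.McmcConfig(n_chains=2, n_iter=4000, burn_in=1000, seed=10))
        b = pm.run_chains(hset, spec, pm.McmcConfig(n_chains=2, n_iter=4000, burn_in=1000, seed=11))
        # chains of b are fresh seeds; pooled means agree within MC error
        assert a.posterior_mean("Pc_l") == pytest.approx(b.posterior_mean("Pc_l"), abs=0.01)

    def test_model4_drops_dead_detection_parameter(self, reconstruction):
        cfg = pm.McmcConfig(n_chains=2, n_iter=300, burn_in=100, seed=0)
        draws = pm.run_chains(reconstruction, pm.preset("model4"), cfg)
        assert "Pc_d" not in draws.draws
        assert set(draws.draws) == {"S", "Pc_l"}

    def test_seasonal_model_names_parameters_by_season(self, reconstruction):
        cfg = pm.McmcConfig(n_chains=2, n_iter=300, burn_in=100, seed=0)
        draws = pm.run_chains(reconstruction, pm.preset("model1"), cfg)
        assert {"S_summer", "S_winter", "Pc_l_summer", "Pc_l_winter",
                "Pc_d_summer", "Pc_d_winter"} == set(draws.draws)

    def test_hierarchical_model_records_hyperparameters(self, reconstruction):
        cfg = pm.McmcConfig(n_chains=2, n_iter=300, burn_in=100, seed=0)
        draws = pm.run_chains(reconstruction, pm.preset("model3-1"), cfg)
        assert {"mu_S", "mu_Pc_l", "mu_Pc_d", "sigma_S", "sigma_Pc_l",
                "sigma_Pc_d"} == set(draws.draws)
        assert draws.indiv_means["pcl_i"].shape == (99, 1)
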
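"""Model specs, priors, likelihoods and the latent-state machinery."""

import math

import numpy as np
import pytest
from scipy.stats import truncnorm

import pitmark as pm
from pitmark import models
from pitmark.models import (
    LatentStateMatrix,
    SINGLE_OCCASION,
    SizeError,
    truncnorm_logpdf,
)
from .conftest import brute_force_marginal, make_set, monthly_calendar


class TestPresets:
    @pytest.mark.parametrize(
        "name,seasonal_s,seasonal_pcl,seasonal_pcd,dead,hier",
        [
            ("model1", True, True, True, True, False),
            ("model1-1", True, True, True, True, True),
            ("model2", False, False, True, True, False),
            ("model2-1", False, False, True, True, True),
            ("model3", False, False, False, True, False),
            ("model3-1", False, False, False, True, True),
            ("model4", False, False, False, False, False),
            ("model4-1", False, False, False, False, True),
        ],
    )
    def test_preset_structure(self, name, seasonal_s, seasonal_pcl, seasonal_pcd, dead, hier):
        spec = pm.preset(name)
        assert spec.seasonal_S is seasonal_s
        assert spec.seasonal_Pcl is seasonal_pcl
        assert spec.seasonal_Pcd is seasonal_pcd
        assert spec.include_dead_submodel is dead
        assert spec.hierarchical is hier

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            pm.preset("model9")


class TestIntervalSurvival:
    @pytest.mark.parametrize(
        "s,dt,expected",
        [(1.0, 8.5, 1.0), (0.5, 1.0, 0.5), (0.999, 2.0, 0.998001)],
    )
    def test_power_rule(self, s, dt, expected):
        assert pm.interval_survival(s, dt) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pm.interval_survival(1.2, 1.0)
        with pytest.raises(ValueError):
            pm.interval_survival(0.9, 0.0)


class TestPrior:
    def test_unit_box_density_is_flat(self):
        spec = pm.preset("model3")
        assert pm.prior_logdensity(pm.ParamState([0.4], [0.9], [0.2]), spec) == 0.0

    def test_outside_support(self):
        spec = pm.preset("model3")
        assert pm.prior_logdensity(pm.ParamState([1.2], [0.9], [0.2]), spec) == -np.inf

    def test_truncated_normal_matches_scipy(self):
        mu, sigma = 0.5, 0.1
        a, b = (0 - mu) / sigma, (1 - mu) / sigma
        for x in (0.5, 0.31, 0.93):
            assert truncnorm_logpdf(x, mu, sigma) == pytest.approx(
                truncnorm.logpdf(x, a, b, loc=mu, scale=sigma), rel=1e-10
            )

    def test_hierarchical_prior_includes_sd_and_individuals(self):
        spec = pm.preset("model4-1")
        p = pm.ParamState([0.5], [0.5])
        p.s_i = np.array([[0.5]])
        p.pcl_i = np.array([[0.5]])
        p.sigma_s = 0.1
        p.sigma_pcl = 0.1
        got = pm.prior_logdensity(p, spec)
        expected = (
            2 * -math.log(spec.prior_sd_upper)
            + truncnorm_logpdf(0.5, 0.5, 0.1)
            + truncnorm_logpdf(0.5, 0.5, 0.1)
        )
        assert got == pytest.approx(float(expected))
        p.sigma_s = 0.9  # beyond the Uniform(0, 0.5) support
        assert pm.prior_logdensity(p, spec) == -np.inf


class TestCompleteDataLoglik:
    def test_certain_events_give_zero(self, cal4):
        hset = make_set(cal4, ["1 1 1 1"])
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        params = pm.ParamState([1.0], [1.0])
        assert pm.complete_data_loglik(hset, latent, params, spec) == 0.0

    def test_hand_product_of_two_bernoulli_terms(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1 1"])
        spec = pm.preset("model4")
        latent = pm.init_latent_states(hset, spec)
        params = pm.ParamState([0.8], [0.9])
        got = pm.complete_data_loglik(hset, latent, params, spec)
        assert got == pytest.approx(math.log(0.72), abs=1e-12)

    def test_impossible_observation_is_minus_inf(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1 1"])
        spec = pm.preset("model3")
        latent = LatentStateMatrix(
            np.array([[1, 0]], np.int8), np.array([[0, 1]], np.int8), np.array([1])
        )
        params = pm.ParamState([0.8], [0.9], [0.4])
        assert pm.complete_data_loglik(hset, latent, params, spec) == -np.inf


class TestMarginalEnumeration:
    def test_single_consistent_path(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1 1"])
        p = pm.ParamState([0.8], [0.7], [0.4])
        got = math.exp(pm.marginal_loglik_enumerate(hset, p, pm.preset("model3")))
        assert got == pytest.approx(0.8 * 0.7)

    def test_two_path_sum_without_dead_layer(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1 0"])
        p = pm.ParamState([0.8], [0.7])
        got = math.exp(pm.marginal_loglik_enumerate(hset, p, pm.preset("model4")))
        assert got == pytest.approx(0.8 * 0.3 + 0.2)

    def test_enumeration_over_alive_and_newly_dead(self):
        cal = monthly_calendar(2)
        hset = make_set(cal, ["1 0"])
        p = pm.ParamState([0.8], [0.7], [0.4])
        got = math.exp(pm.marginal_loglik_enumerate(hset, p, pm.preset("model3")))
        assert got == pytest.approx(0.8 * 0.3 + 0.2 * 0.6)

    def test_size_guard(self):
        cal = monthly_calendar(4)
        hset = make_set(cal, ["1 1 1 1"])
        with pytest.raises(SizeError):
            pm.marginal_loglik_enumerate(
                hset, pm.ParamState([0.9], [0.9], [0.4]), pm.preset("model3"), max_cells=8
            )

    @pytest.mark.parametrize("preset_name", ["model1", "model3", "model4"])
    @pytest.mark.parametrize("persistence", ["until_recovered", "single_occasion"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_latent_sum_of_complete_data_likelihood(
        self, preset_name, persistence, seed
    ):
        from dataclasses import replace

        rng = np.random.default_rng(seed)
        spec = replace(pm.preset(preset_name), shell_persistence=persistence)
        cal = monthly_calendar(5, start="2009-09-15")  # spans both seasons
        truth = pm.SimTruth(
            pm.ParamState(
                rng.uniform(0.5, 0.95, spec.n_seasons_S),
                rng.uniform(0.4, 0.9, spec.n_seasons_Pcl),
                rng.uniform(0.2, 0.8, spec.n_seasons_Pcd)
                if spec.include_dead_submodel
                else None,
            ),
            cal,
            pm.CohortTable([0, 1], [2, 2]),
            spec,
            seed=seed,
        )
        hset = pm.simulate_histories(truth)
        params = pm.ParamState(
            rng.uniform(0.5, 0.95, spec.n_seasons_S),
            rng.uniform(0.4, 0.9, spec.n_seasons_Pcl),
            rng.uniform(0.2, 0.8, spec.n_seasons_Pcd)
            if spec.include_dead_submodel
            else None,
        )
        a = pm.marginal_loglik_enumerate(hset, params, spec)
        b = brute_force_marginal(hset, params, spec)
        assert a == pytest.approx(b, rel=1e-12)

    def test_invariant_under_within_cohort_permutation(self):
        truth = pm.study_truth(0.95, 0.8, 0.4, seed=5)
        hset = pm.simulate_histories(truth)
        spec = pm.preset("model3")
        params = pm.ParamState([0.97], [0.85], [0.3])
        base = pm.marginal_loglik_enumerate(hset, params, spec)
        rng = np.random.default_rng(0)
        perm = np.concatenate(
            [rng.permutation(np.flatnonzero(hset.release == r)) for r in range(5)]
        )
        shuffled = hset.subset(perm)
        assert pm.marginal_loglik_enumerate(shuffled, params, spec) == pytest.approx(
            base, rel=1e-12
        )

    def test_never_seen_again_matches_cjs_recursion(self):
        """With dt = 1, one season and no dead layer the marginal of a
        never-seen-again tail is the textbook chi recursion
        chi_k = (1 - S) + S (1 - p) chi_{k+1}."""
        s, p = 0.8, 0.6
        cal = monthly_calendar(5)
        hset = make_set(cal, ["1 0 0 0 0"])
        spec = pm.preset("model4")
        chi = 1.0
        for _ in range(4):
            chi = (1 - s) + s * (1 - p) * chi
        got = math.exp(
            pm.marginal_loglik_enumerate(hset, pm.ParamState([s], [p]), spec)
        )
        assert got == pytest.approx(chi, rel=1e-12)


class TestLatentInit:
    def test_fully_observed_row(self, cal4):
        hset = make_set(cal4, ["1 1 1 1"])
        latent = pm.init_latent_states(hset, pm.preset("model3"))
        assert latent.L.tolist() == [[1, 1, 1, 1]]
        assert latent.death_occasion.tolist() == [4]

    def test_recovery_constrains_death(self):
        cal = monthly_calendar(3)
        hset = make_set(cal, ["1 0 2"])
        spec = pm.preset("model3")
        latent = pm.init_latent_states(hset, spec)
        assert latent.death_occasion.tolist() == [2]
        assert latent.D[0].tolist() == [0, 0, 1]
        support = models.death_time_support(hset, spec)
        assert support[0].tolist() == [True, True, False]  # death at 1 or 2

    def test_single_occasion_persistence_pins_death_to_recovery(self):
        from dataclasses import replace

        cal = monthly_calendar(3)
        hset = make_set(cal, ["1 0 2"])
        spec = replace(pm.preset("model3"), shell_persistence=SINGLE_OCCASION)
        support = models.death_time_support(hset, spec)
        assert support[0].tolist() == [False, True, False]

    def test_unique_latent_when_fully_observed(self, cal4):
        hset = make_set(cal4, ["1 1 1 1", "1 1 1 1"])
        for seed in (0, 1, 2):
            latent = pm.init_latent_states(hset, pm.preset("model3"), seed=seed)
            assert latent.death_occasion.tolist() == [4, 4]

    def test_death_before_last_detection_rejected(self, cal4):
        hset = make_set(cal4, ["1 1 1 1"])
        with pytest.raises(ValueError):
            LatentStateMatrix.from_death_times(hset, np.array([2]), pm.preset("model3"))
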
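import dataclasses

import numpy as np
import pytest
from scipy import stats

from effortpain.synthetic_data import (
    DEFAULT_BETA_MEDIAN,
    AgentPopulationConfig,
    calibrate_beta,
    expected_work_rate,
    sample_population,
    simulate_dataset,
)
from effortpain.task_design import generate_schedule
from effortpain.value_models import ModelSpec, ParameterSet

PARA_2K1B = ModelSpec.from_name("parabolic_2k1b")


class TestSamplePopulation:
    def test_degenerate_sigmas_give_identical_agents(self):
        config = AgentPopulationConfig(
            n_subjects=5, group_sigma_kappa_self=0.0, group_sigma_kappa_effect=0.0,
            group_sigma_log_beta=0.0, model=PARA_2K1B, seed=1,
        )
        agents = sample_population(config)
        assert len({(a.kappa_self, a.kappa_effect, a.beta) for a in agents}) == 1
        assert agents[0].kappa_self == pytest.approx(-0.19)

    def test_monte_carlo_mean_matches_truncated_normal_oracle(self):
        """|kappa_self| mean at n=10k matches the analytic resampled-population mean.

        Resampling into kappa <= 0 makes the population a truncated normal;
        its exact mean is the oracle (the configured -0.19 shifts slightly).
        """
        config = AgentPopulationConfig(n_subjects=10_000, model=PARA_2K1B, seed=42)
        agents = sample_population(config)
        ks = np.array([a.kappa_self for a in agents])
        oracle = stats.truncnorm.mean(
            -np.inf, (0.0 - -0.19) / 0.14, loc=-0.19, scale=0.14
        )
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - oracle) < 3 * se
        assert abs(np.abs(ks).mean() - abs(oracle)) < 3 * se  # all draws <= 0

    def test_admissible_regions(self):
        config = AgentPopulationConfig(
            n_subjects=2000, model=ModelSpec.from_name("hyperbolic_2k1b"), seed=3
        )
        agents = sample_population(config)
        for a in agents:
            assert -0.2 < a.kappa_self <= 0.0
            assert -0.2 < a.kappa_other <= 0.0

    def test_seed_determinism(self):
        config = AgentPopulationConfig(n_subjects=50, model=PARA_2K1B, seed=9)
        assert sample_population(config) == sample_population(config)

    def test_shared_kappa_model_has_zero_effect(self):
        config = AgentPopulationConfig(
            n_subjects=10, model=ModelSpec.from_name("parabolic_1k1b"), seed=2
        )
        assert all(a.kappa_effect == 0.0 for a in sample_population(config))

    @pytest.mark.parametrize("field,value", [
        ("n_subjects", 1),
        ("nonresponse_rate_self", 1.5),
        ("force_success_prob", -0.1),
        ("group_sigma_kappa_self", -0.2),
    ])
    def test_config_validation(self, field, value):
        with pytest.raises(ValueError):
            AgentPopulationConfig(**{field: value})


class TestSimulateDataset:
    def test_dominant_agent_always_works(self, schedule50):
        config = AgentPopulationConfig(n_subjects=2, model=PARA_2K1B, seed=1,
                                       nonresponse_rate_self=0.0,
                                       nonresponse_rate_other=0.0)
        agents = [ParameterSet(kappa_self=0.0, beta=50.0)] * 2
        data = simulate_dataset(agents, schedule50, config, seed=4)
        assert (data["choice"] == "work").all()

    def test_pooled_work_rate_brackets_defaults(self, schedule150):
        config = AgentPopulationConfig(n_subjects=47, model=PARA_2K1B, seed=21)
        agents = sample_population(config)
        data = simulate_dataset(agents, schedule150, config, seed=22)
        responded = data[data["choice"] != "nonresponse"]
        rate = (responded["choice"] == "work").mean()
        assert 0.6 <= rate <= 0.8

    def test_perfect_success_never_delivers_penalty_on_work(self, schedule50):
        config = AgentPopulationConfig(n_subjects=4, model=PARA_2K1B, seed=5,
                                       force_success_prob=1.0)
        data = simulate_dataset(sample_population(config), schedule50, config, seed=6)
        work = data[data["choice"] == "work"]
        assert (work["delivered_shocks"] == work["work_shocks"]).all()

    def test_delivered_shock_contingency(self, small_data):
        data = small_data
        assert set(data["delivered_shocks"]).issubset(set(range(1, 6)) | {6, 10})
        rest = data[data["choice"] == "rest"]
        assert (rest["delivered_shocks"] == 6).all()
        nonresp = data[data["choice"] == "nonresponse"]
        assert (nonresp["delivered_shocks"] == 10).all()
        work = data[data["choice"] == "work"]
        ok = work["success"].astype(bool)
        assert (work.loc[ok, "delivered_shocks"] == work.loc[ok, "work_shocks"]).all()
        assert (work.loc[~ok, "delivered_shocks"] == 10).all()

    def test_force_fields_present_iff_work(self, small_data):
        work = small_data["choice"] == "work"
        assert small_data.loc[work, "force_auc"].notna().all()
        assert small_data.loc[~work, "force_auc"].isna().all()
        assert small_data.loc[work, "success"].notna().all()

    def test_force_auc_scale(self, small_data):
        force = small_data.loc[small_data["choice"] == "work", "force_auc"]
        assert 0.40 < force.mean() < 0.56
        assert (force > 0).all() and (force <= 1).all()

    def test_nonresponse_rates_injected(self, schedule150):
        config = AgentPopulationConfig(n_subjects=100, model=PARA_2K1B, seed=31)
        data = simulate_dataset(sample_population(config), schedule150, config, seed=32)
        for rec, target in (("self", 0.005), ("other", 0.0075)):
            sub = data[data["recipient"] == rec]
            rate = (sub["choice"] == "nonresponse").mean()
            assert abs(rate - target) < 0.004

    def test_choice_rate_monotone_in_effort_and_shocks(self, schedule150):
        config = AgentPopulationConfig(n_subjects=200, model=PARA_2K1B, seed=51,
                                       nonresponse_rate_self=0.0,
                                       nonresponse_rate_other=0.0)
        data = simulate_dataset(sample_population(config), schedule150, config, seed=52)
        data["work"] = data["choice"] == "work"
        by_effort = data.groupby("effort_level")["work"].mean()
        assert (np.diff(by_effort.to_numpy()) < 0).all()
        by_shock = data.groupby("work_shocks")["work"].mean()
        assert (np.diff(by_shock.to_numpy()) < 0).all()

    def test_generative_inferential_consistency(self, small_population, schedule150,
                                                small_data):
        """True parameters beat kappa-perturbed ones on model log-likelihood."""
        config, agents = small_population
        from effortpain.value_models import dataset_loglik

        params_true = {i + 1: a for i, a in enumerate(agents)}
        params_pert = {
            i + 1: dataclasses.replace(a, kappa_self=a.kappa_self - 0.5)
            for i, a in enumerate(agents)
        }
        records = list(small_data.itertuples())
        ll_true = dataset_loglik(params_true, records, config.model)
        ll_pert = dataset_loglik(params_pert, records, config.model)
        assert np.isfinite(ll_true)
        assert ll_true > ll_pert


class TestBetaCalibration:
    def test_default_matches_calibration(self):
        assert calibrate_beta(0.66) == pytest.approx(DEFAULT_BETA_MEDIAN, abs=5e-3)

    def test_expected_rate_monte_carlo_oracle(self, rng):
        """Quadrature expectation agrees with brute-force Monte Carlo."""
        beta = 2.0
        n = 200_000
        kappas = rng.normal(-0.19, 0.14, size=n)
        kappas = kappas[kappas <= 0]
        eff = rng.integers(1, 6, size=kappas.size)
        shk = rng.integers(1, 6, size=kappas.size)
        p = 1.0 / (1.0 + np.exp(-beta * (-shk + kappas * eff**2 + 6.0)))
        assert expected_work_rate(beta) == pytest.approx(p.mean(), abs=3e-3)

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_beta(0.95)

    def test_rate_increases_with_beta_below_ceiling(self):
        assert expected_work_rate(0.5) < expected_work_rate(1.5) < expected_work_rate(4.0)
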
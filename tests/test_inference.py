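import numpy as np
import pytest

from effortpain.inference.fit import (
    SamplerConfig,
    compute_hdi,
    compute_rhat,
    exclude_nonconvergent_subjects,
    fit_model,
    load_fit,
    save_fit,
)
from effortpain.inference.model import ChoiceModel, prepare_choice_data
from effortpain.inference.nuts import NutsConfig, nuts_sample
from effortpain.synthetic_data import (
    AgentPopulationConfig,
    sample_population,
    simulate_dataset,
)
from effortpain.task_design import generate_schedule
from effortpain.value_models import ModelSpec, ParameterSet, trial_loglik


class TestChoiceModelDensity:
    @pytest.mark.parametrize(
        "name", ["linear_1k1b", "parabolic_2k1b", "hyperbolic_2k2b", "parabolic_1k2b"]
    )
    def test_gradient_matches_finite_differences(self, name, schedule50):
        model = ModelSpec.from_name(name)
        config = AgentPopulationConfig(n_subjects=4, model=model, seed=2)
        data = simulate_dataset(sample_population(config), schedule50, config, seed=9)
        cm = ChoiceModel(data, model)
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 0.5, cm.dim)
        _, grad = cm.log_posterior_grad(theta)
        eps = 1e-6
        for i in range(cm.dim):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            numeric = (cm.log_posterior(up) - cm.log_posterior(dn)) / (2 * eps)
            assert grad[i] == pytest.approx(numeric, rel=1e-4, abs=1e-6)

    def test_pointwise_loglik_matches_value_models_oracle(self, schedule50):
        """Cell-based likelihood equals a per-trial recomputation via trial_loglik."""
        model = ModelSpec.from_name("parabolic_2k1b")
        config = AgentPopulationConfig(n_subjects=3, model=model, seed=4)
        data = simulate_dataset(sample_population(config), schedule50, config, seed=5)
        cm = ChoiceModel(data, model)
        theta = np.random.default_rng(1).normal(0, 0.5, cm.dim)
        pointwise = cm.pointwise_loglik(theta[None, :], dtype=np.float64)[:, 0]

        sub = cm.subject_parameters(theta)
        params = {
            sid: ParameterSet(
                kappa_self=float(sub["kappa_self"][i]),
                kappa_effect=float(sub["kappa_other"][i] - sub["kappa_self"][i]),
                beta=float(sub["beta_self"][i]),
                log_beta_effect=float(
                    np.log(sub["beta_other"][i]) - np.log(sub["beta_self"][i])
                ),
            )
            for i, sid in enumerate(cm.subject_ids)
        }
        responded = data[data["choice"] != "nonresponse"].reset_index(drop=True)
        expected = np.array([
            trial_loglik(params[row.subject_id], row, row.choice, model)
            for row in responded.itertuples()
        ])
        np.testing.assert_allclose(pointwise, expected, rtol=1e-10)

    def test_rejects_single_subject(self, schedule50):
        model = ModelSpec.from_name("parabolic_2k1b")
        config = AgentPopulationConfig(n_subjects=2, model=model, seed=4)
        data = simulate_dataset(sample_population(config), schedule50, config, seed=5)
        solo = data[data["subject_id"] == 1]
        with pytest.raises(ValueError, match="2 subjects"):
            prepare_choice_data(solo)

    def test_rejects_single_recipient(self, schedule50):
        model = ModelSpec.from_name("parabolic_2k1b")
        config = AgentPopulationConfig(n_subjects=3, model=model, seed=4)
        data = simulate_dataset(sample_population(config), schedule50, config, seed=5)
        with pytest.raises(ValueError, match="both"):
            prepare_choice_data(data[data["recipient"] == "self"])


class TestNuts:
    def test_recovers_gaussian_moments(self):
        var = np.array([1.0, 25.0, 0.04])

        def logp_grad(theta):
            return float(-0.5 * np.sum(theta**2 / var)), -theta / var

        rng = np.random.default_rng(5)
        res = nuts_sample(logp_grad, np.zeros(3), NutsConfig(500, 1500), rng)
        draws = res["draws"]
        assert res["n_divergent"] == 0
        np.testing.assert_allclose(draws.mean(axis=0) / np.sqrt(var), 0.0,
                                   atol=3.0 / np.sqrt(400))
        np.testing.assert_allclose(draws.var(axis=0), var, rtol=0.25)

    def test_seeded_determinism(self):
        def logp_grad(theta):
            return float(-0.5 * theta @ theta), -theta

        a = nuts_sample(logp_grad, np.zeros(2), NutsConfig(100, 100),
                        np.random.default_rng(7))
        b = nuts_sample(logp_grad, np.zeros(2), NutsConfig(100, 100),
                        np.random.default_rng(7))
        np.testing.assert_array_equal(a["draws"], b["draws"])

    def test_nonfinite_start_rejected(self):
        def logp_grad(theta):
            return float("-inf"), theta

        with pytest.raises(ValueError):
            nuts_sample(logp_grad, np.zeros(2), NutsConfig(10, 10),
                        np.random.default_rng(0))


class TestRhat:
    def test_identical_constant_chains(self):
        chains = np.ones((4, 200))
        assert compute_rhat(chains) == 1.0

    def test_stationary_chains_converge(self, rng):
        chains = rng.standard_normal((4, 5000))
        assert compute_rhat(chains) < 1.01

    def test_disjoint_chains_diverge(self, rng):
        chains = rng.standard_normal((2, 500))
        chains[0] += 10.0
        assert compute_rhat(chains) > 1.05

    def test_single_chain_raises(self):
        with pytest.raises(ValueError):
            compute_rhat(np.random.default_rng(0).standard_normal((1, 100)))

    def test_too_few_draws_raises(self):
        with pytest.raises(ValueError):
            compute_rhat(np.zeros((2, 1)))

    def test_matches_arviz_rank_rhat(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.standard_normal((4, 400)) + rng.normal(0, 0.1, size=(4, 1))
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert compute_rhat(chains) == pytest.approx(theirs, abs=1e-8)


class TestHdi:
    def test_uniform_width(self, rng):
        draws = rng.random(10_000)
        lo, hi = compute_hdi(draws, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_symmetric_matches_quantiles(self, rng):
        draws = rng.standard_normal(50_000)
        lo, hi = compute_hdi(draws, 0.9)
        q_lo, q_hi = np.quantile(draws, [0.05, 0.95])
        assert lo == pytest.approx(q_lo, abs=0.08)
        assert hi == pytest.approx(q_hi, abs=0.08)

    def test_constant_sample_zero_width(self):
        lo, hi = compute_hdi(np.full(500, 3.2))
        assert lo == hi == 3.2

    @pytest.mark.parametrize("mass", [0.0, 1.0, -0.5, 1.7])
    def test_invalid_mass(self, mass):
        with pytest.raises(ValueError):
            compute_hdi(np.zeros(500), mass)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            compute_hdi(np.zeros(50))


class TestFitModel:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_fit_inputs():
        model = ModelSpec.from_name("parabolic_2k1b")
        schedule = generate_schedule(25, seed=11)
        config = AgentPopulationConfig(n_subjects=4, model=model, seed=12)
        data = simulate_dataset(sample_population(config), schedule, config, seed=13)
        return data, model

    def test_seeded_fit_determinism(self, tiny_fit_inputs):
        data, model = tiny_fit_inputs
        sampler = SamplerConfig(n_chains=2, n_warmup=150, n_samples=150, seed=77)
        a = fit_model(data, model, sampler=sampler)
        b = fit_model(data, model, sampler=sampler)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.rhat == b.rhat

    def test_fit_metadata(self, small_fit, small_data):
        assert small_fit.n_draws == 600
        assert small_fit.n_nonresponse_dropped == int(
            (small_data["choice"] == "nonresponse").sum()
        )
        assert len(small_fit.subject_ids) == 12
        assert set(small_fit.rhat) >= {"mu_k", "mu_ke", "mu_b"}
        assert any(k.startswith("kappa_self[") for k in small_fit.rhat)

    def test_posterior_concentrates_near_truth(self, small_fit, small_population):
        _, agents = small_population
        true_mean = np.mean([abs(a.kappa_self) for a in agents])
        post = small_fit.group_param_draws()["group_abs_kappa_self"]
        assert abs(post.mean() - true_mean) < 0.05

    def test_save_load_roundtrip(self, small_fit, tmp_path):
        save_fit(small_fit, tmp_path / "fit")
        back = load_fit(tmp_path / "fit")
        np.testing.assert_allclose(back.theta, small_fit.theta, rtol=1e-9)
        assert back.model == small_fit.model
        assert back.subject_ids == small_fit.subject_ids
        assert back.rhat == pytest.approx(small_fit.rhat)
        assert len(back.data) == len(small_fit.data)

    def test_exclusion_boundary_threshold(self, small_fit):
        kept, log = exclude_nonconvergent_subjects(small_fit, threshold=np.inf)
        assert log == []
        assert len(kept) == len(small_fit.data)

    def test_exclusion_flags_offenders(self, small_fit):
        doctored = small_fit
        worst_key = f"kappa_self[{doctored.subject_ids[0]}]"
        old = doctored.rhat[worst_key]
        doctored.rhat[worst_key] = 1.2
        try:
            kept, log = exclude_nonconvergent_subjects(doctored, threshold=1.05)
            assert [e["subject_id"] for e in log] == [doctored.subject_ids[0]]
            assert 0.0 <= log[0]["work_rate_self"] <= 1.0
            assert doctored.subject_ids[0] not in set(kept["subject_id"])
        finally:
            doctored.rhat[worst_key] = old
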
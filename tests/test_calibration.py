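import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deha_pbk.calibration import (HierarchicalModel, mcmc_run,
                                  mode_fit_report, posterior_predictive,
                                  posterior_summary, truncated_normal_loglik)
from deha_pbk.mcmc import BlockSpec, Chain, block_rwm


class TestTruncatedNormalLoglik:
    def test_peak_density_far_from_truncation(self):
        # y = mu with sigma 1 and mu >> 0: the truncation term vanishes
        # and the density is the standard normal peak
        assert truncated_normal_loglik([50.0], [50.0], 1.0) == \
            pytest.approx(-0.9189385, abs=1e-6)

    def test_zero_truncated_closed_form_at_origin(self):
        # mu = 0, sigma = 1, y = 0: density 2*phi(0) = 0.79788
        assert truncated_normal_loglik([0.0], [0.0], 1.0) == \
            pytest.approx(np.log(2 / np.sqrt(2 * np.pi)), abs=1e-9)

    def test_scale_property(self):
        a = truncated_normal_loglik([50.0], [50.0], 1.0)
        b = truncated_normal_loglik([50.0], [50.0], 2.0)
        assert a - b == pytest.approx(np.log(2.0), abs=1e-6)

    def test_matches_scipy_truncnorm(self):
        y = np.array([0.1, 0.5, 2.0])
        mu, sigma = 0.8, 0.6
        expected = stats.truncnorm(
            -mu / sigma, np.inf, loc=mu, scale=sigma).logpdf(y).sum()
        assert truncated_normal_loglik(y, np.full(3, mu), sigma) == \
            pytest.approx(expected, rel=1e-9)

    def test_zero_sigma_is_invalid(self):
        assert truncated_normal_loglik([1.0], [1.0], 0.0) == -np.inf


@pytest.fixture(scope="module")
def model(noisy_study):
    return HierarchicalModel(noisy_study.datasets)


class TestHierarchy:
    def test_dimension_is_15_globals_plus_2_sigmas_plus_4x11_locals(
            self, model):
        assert len(model.param_names) == 15 + 2 + 4 * 11
        assert len(set(model.param_names)) == 61

    def test_log_prior_outside_support(self, model):
        x = model.initial_point()
        i = model.param_names.index("FracAbsorbed[A]")
        x[i] = 1.2
        assert model.log_prior(x) == -np.inf

    def test_log_prior_additivity_at_medians(self, model):
        x = model.initial_point()
        expected = sum(float(s.logpdf(v))
                       for s, v in zip(model._specs_by_index, x))
        assert model.log_prior(x) == pytest.approx(expected, rel=1e-12)

    def test_halfnormal_prior_closed_form(self, model):
        x = model.initial_point()
        i = model.param_names.index("sigma_cx_U")
        base = model.log_prior(x)
        x2 = x.copy()
        x2[i] = 0.5
        delta = model.log_prior(x2) - base
        hn = stats.halfnorm(scale=1.0)
        assert delta == pytest.approx(
            hn.logpdf(0.5) - hn.logpdf(x[i]), rel=1e-9)

    def test_likelihood_finite_at_generating_parameters(
            self, noisy_study, model):
        truth = noisy_study.truths[0]
        theta = {n: model.base.get(n) for n in model.global_names}
        ll_true = model.log_likelihood(theta, truth.local_params,
                                       np.array([2e-4, 4e-4]), 0)
        assert np.isfinite(ll_true)


class TestSampler:
    def test_identical_seeds_give_identical_chains(self, model):
        a = mcmc_run(model, n_iter=60, thin=10, seed=5)
        b = mcmc_run(model, n_iter=60, thin=10, seed=5)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        c = mcmc_run(model, n_iter=60, thin=10, seed=6)
        assert not a.draws.equals(c.draws)

    def test_chain_storage_round_trip(self, model, tmp_path):
        ch = mcmc_run(model, n_iter=40, thin=10, seed=5)
        path = tmp_path / "chain.csv"
        ch.to_csv(path)
        text = path.read_text()
        assert text.startswith("# n_iter=40 thin=10 seed=5")
        df = pd.read_csv(path, comment="#")
        assert len(df) == 4
        assert "log_posterior" in df.columns


class TestPosteriorSummary:
    def test_constant_chain_collapses(self):
        draws = pd.DataFrame({"a": np.full(100, 3.0)})
        ch = Chain(draws=draws, logpost=np.zeros(100), n_iter=1000, thin=10,
                   seed=0, burn_frac=0.0, acceptance={}, param_names=["a"])
        s = posterior_summary(ch)
        assert s.loc["a", "median"] == s.loc["a", "q2.5"] == \
            s.loc["a", "q97.5"] == 3.0

    def test_uniform_pseudo_chain_quantiles(self):
        rng = np.random.default_rng(8)
        draws = pd.DataFrame({"u": rng.uniform(size=100_000)})
        ch = Chain(draws=draws, logpost=np.zeros(100_000), n_iter=10, thin=1,
                   seed=0, burn_frac=0.0, acceptance={}, param_names=["u"])
        s = posterior_summary(ch)
        assert s.loc["u", "median"] == pytest.approx(0.5, abs=0.005)
        assert s.loc["u", "q2.5"] == pytest.approx(0.025, abs=0.005)

    def test_empty_retained_sample_rejected(self):
        ch = Chain(draws=pd.DataFrame({"a": []}), logpost=np.array([]),
                   n_iter=10, thin=1, seed=0, burn_frac=0.0, acceptance={},
                   param_names=["a"])
        with pytest.raises(ValueError):
            posterior_summary(ch)


@pytest.fixture(scope="module")
def short_chain(model):
    return mcmc_run(model, n_iter=300, thin=10, seed=9)


class TestPredictiveAndModeFit:
    def test_bands_are_ordered_pointwise(self, short_chain, model):
        bands = posterior_predictive(short_chain, model, duration=24.0,
                                     grid_step=0.5, n_draws=10, seed=1)
        for vid, d in bands.items():
            for key, frame in d.items():
                assert np.all(frame["lo"] <= frame["hi"] + 1e-15)

    def test_mode_fit_reports_all_volunteers_and_analytes(self, short_chain,
                                                          model):
        rep = mode_fit_report(short_chain, model, duration=48.0)
        assert len(rep) == 8
        assert set(rep["analyte"]) == {"5OH-MEHA", "5cx-MEPA"}
        assert (rep["measured_mg"] > 0).all()
        assert (rep["predicted_mg"] > 0).all()

    def test_mode_fit_self_consistent_on_noise_free_study(self):
        """With noise-free data and the mode fixed at the generating
        parameters, predicted 48-h excretion matches the measured totals
        up to the mass deposited after the last void."""
        from deha_pbk.synthetic import GeneratorConfig, generate_study
        study = generate_study(GeneratorConfig(noise=False), seed=31)
        model = HierarchicalModel(study.datasets)
        x = []
        for name in model.global_names:
            x.append(model.base.get(name))
        x.extend([1e-4, 1e-4])                      # error SDs (unused here)
        for truth in study.truths:
            x.extend(truth.local_params[n] for n in model.local_names)
        chain = Chain(draws=pd.DataFrame([x], columns=model.param_names),
                      logpost=np.array([0.0]), n_iter=1, thin=1, seed=0,
                      burn_frac=0.0, acceptance={},
                      param_names=model.param_names)
        rep = mode_fit_report(chain, model)
        assert np.all(rep["ratio"] > 0.97)
        assert np.all(rep["ratio"] < 1.10)


class TestGenericSampler:
    def test_single_gaussian_target(self):
        """Direct check of the Metropolis core on a known density."""
        def parts(x, dirty, old):
            return np.array([-0.5 * ((x[0] - 2.0) / 0.5) ** 2])
        ch = block_rwm(parts, np.array([0.0]),
                       [BlockSpec(indices=np.array([0]),
                                  affected_parts=(0,))],
                       n_parts=1, param_names=["x"], n_iter=40_000, thin=4,
                       seed=11, scales=np.array([0.5]))
        kept = ch.retained()["x"]
        assert kept.mean() == pytest.approx(2.0, abs=0.02)
        assert kept.std() == pytest.approx(0.5, abs=0.02)

    def test_log_scale_block_targets_lognormal(self):
        # multiplicative proposals with the Hastings correction leave a
        # lognormal target invariant
        def parts(x, dirty, old):
            if x[0] <= 0:
                return np.array([-np.inf])
            return np.array([-np.log(x[0])
                             - 0.5 * (np.log(x[0]) / 0.7) ** 2])
        ch = block_rwm(parts, np.array([1.0]),
                       [BlockSpec(indices=np.array([0]),
                                  affected_parts=(0,), log_scale=True)],
                       n_parts=1, param_names=["x"], n_iter=60_000, thin=6,
                       seed=12, scales=np.array([0.8]))
        kept = np.log(ch.retained()["x"])
        assert kept.mean() == pytest.approx(0.0, abs=0.03)
        assert kept.std() == pytest.approx(0.7, abs=0.03)
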
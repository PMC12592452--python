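"""Mixing model: density, sampler, quadrature oracle, diagnostics, pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from midmix.mixing_model import (MixingModelSpec, SourceSummary,
                                 brute_force_posterior, diagnose,
                                 log_posterior, pool_fractions, run_mcmc,
                                 summarize_sources)
from midmix.synthetic import (StudyConfig, generate_source_samples,
                              source_summary_from_config)


def _two_source(sd=0.1):
    return SourceSummary(["a", "b"], ["t"], np.array([[0.0], [10.0]]),
                         np.array([[sd], [sd]]), np.array([5, 5]))


@pytest.fixture(scope="module")
def src3():
    return source_summary_from_config(StudyConfig(seed=0))


class TestSummarizeSources:
    def test_means_within_standard_error(self, config):
        tab = generate_source_samples(config)
        src = summarize_sources(tab, list(config.tracer_names))
        n = config.n_source_samples
        assert np.all(np.abs(src.means - config.source_means)
                      < 3 * config.source_sds / math.sqrt(n) + 1e-12)
        assert (src.counts == n).all()

    def test_row_order_invariance(self, config):
        tab = generate_source_samples(config)
        a = summarize_sources(tab, list(config.tracer_names))
        b = summarize_sources(tab.sample(frac=1, random_state=1),
                              list(config.tracer_names))
        np.testing.assert_allclose(a.means, b.means)
        np.testing.assert_allclose(a.sds, b.sds)

    def test_constant_samples_get_sd_floor(self):
        tab = pd.DataFrame({"sample_id": list("abc"), "fraction": "small",
                            "tracer": "t", "value_permil": 5.0})
        tab = pd.concat([tab, tab.assign(fraction="large")], ignore_index=True)
        src = summarize_sources(tab, ["t"])
        assert (src.sds == 0.1).all()

    def test_underreplicated_fraction_rejected(self):
        tab = pd.DataFrame({"sample_id": ["a"], "fraction": ["small"],
                            "tracer": ["t"], "value_permil": [1.0]})
        with pytest.raises(ValueError, match="small"):
            summarize_sources(tab, ["t"])


class TestLogPosterior:
    def test_matches_hand_computed_density(self, src3):
        """Independent oracle: Normal + Dirichlet log densities from formulas."""
        spec = MixingModelSpec(dirichlet_alpha=np.array([1.0, 2.0, 0.5]))
        rng = np.random.default_rng(42)
        for _ in range(5):
            p = rng.dirichlet([1, 1, 1])
            x = rng.normal(size=3) * 5
            mu = p @ src3.means
            var = (p ** 2) @ (src3.sds ** 2) + 0.5 ** 2
            ll = np.sum(-0.5 * np.log(2 * np.pi * var) - (x - mu) ** 2 / (2 * var))
            a = np.array([1.0, 2.0, 0.5])
            lprior = (gammaln(a.sum()) - gammaln(a).sum()
                      + np.sum((a - 1) * np.log(p)))
            assert log_posterior(p, x, src3, spec) == pytest.approx(ll + lprior,
                                                                    rel=1e-10)

    def test_symmetric_sources_maximized_at_half(self):
        src = _two_source(sd=1.0)
        spec = MixingModelSpec()
        x = np.array([5.0])
        mid = log_posterior([0.5, 0.5], x, src, spec)
        for p1 in (0.2, 0.35, 0.65, 0.8):
            assert log_posterior([p1, 1 - p1], x, src, spec) < mid

    def test_flat_dirichlet_prior_is_constant(self, src3):
        spec = MixingModelSpec()  # alpha = 1
        x = np.zeros(3)
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(4):
            p = rng.dirichlet([1, 1, 1])
            mu = p @ src3.means
            var = (p ** 2) @ (src3.sds ** 2) + 0.25
            ll = np.sum(-0.5 * np.log(2 * np.pi * var) - (x - mu) ** 2 / (2 * var))
            vals.append(log_posterior(p, x, src3, spec) - ll)
        assert np.ptp(vals) < 1e-10  # the prior contribution is constant

    def test_off_simplex_rejected(self, src3):
        with pytest.raises(ValueError, match="simplex"):
            log_posterior([0.5, 0.2, 0.2], np.zeros(3), src3, MixingModelSpec())


class TestQuadratureOracle:
    def test_linear_mixing_inversion(self):
        src = _two_source()
        spec = MixingModelSpec(measurement_sd=0.1)
        # mean p1 -> (x - m2)/(m1 - m2) as all variances shrink
        for x, expect in ((5.0, 0.5), (7.0, 0.3)):
            q = brute_force_posterior(np.array([x]), src, spec)
            assert q["mean"][0] == pytest.approx(expect, abs=0.02)

    def test_flat_posterior_mean_is_centroid(self, src3):
        spec = MixingModelSpec(measurement_sd=1e6)
        q = brute_force_posterior(np.zeros(3), src3, spec, grid_step=0.01)
        np.testing.assert_allclose(q["mean"], 1 / 3, atol=0.01)

    def test_grid_refinement_converged(self, src3):
        spec = MixingModelSpec()
        x = np.array([0.4, 0.3, 0.3]) @ src3.means
        coarse = brute_force_posterior(x, src3, spec, grid_step=0.01)
        fine = brute_force_posterior(x, src3, spec, grid_step=0.005)
        assert np.abs(coarse["mean"] - fine["mean"]).max() < 1e-3

    def test_coarse_grid_rejected(self, src3):
        with pytest.raises(ValueError, match="coarse"):
            brute_force_posterior(np.zeros(3), src3, MixingModelSpec(),
                                  grid_step=0.25)

    def test_monotone_in_tracer_direction(self):
        """Pulling the observation toward source 1 raises its posterior mean."""
        src = _two_source(sd=1.0)
        spec = MixingModelSpec()
        means = [brute_force_posterior(np.array([x]), src, spec)["mean"][0]
                 for x in np.linspace(9.0, 1.0, 7)]
        assert np.all(np.diff(means) > 0)


class TestSampler:
    def test_sharp_data_recovers_truth(self, src3):
        truth = np.array([0.7, 0.2, 0.1])
        sharp = SourceSummary(src3.fractions, src3.tracers, src3.means,
                              np.full((3, 3), 0.1), src3.counts)
        x = truth @ src3.means
        spec = MixingModelSpec.reduced(measurement_sd=0.1, seed=4)
        post = run_mcmc(x, sharp, spec, pooling=None)
        np.testing.assert_allclose(post.mean, truth, atol=0.03)

    def test_matches_quadrature_oracle(self, src3):
        spec = MixingModelSpec.reduced(seed=9)
        x = np.array([0.3, 0.45, 0.25]) @ src3.means + np.array([0.3, -0.2, 0.4])
        post = run_mcmc(x, src3, spec, pooling=None)
        q = brute_force_posterior(x, src3, spec)
        assert np.abs(post.mean - q["mean"]).max() < 0.02

    def test_schedule_bookkeeping_default_spec(self):
        spec = MixingModelSpec()
        assert spec.draws_per_chain == 2000
        src = _two_source()
        post = run_mcmc(np.array([5.0]), src, MixingModelSpec(seed=0),
                        pooling=None)
        assert post.draws.shape == (3, 2000, 2)
        assert post.flat.shape[0] == 6000

    def test_every_draw_on_simplex(self, src3):
        post = run_mcmc(np.zeros(3), src3, MixingModelSpec.reduced(seed=2),
                        pooling=None)
        assert np.abs(post.draws.sum(axis=2) - 1).max() < 1e-10
        assert (post.draws >= 0).all()

    def test_rerun_is_byte_identical(self, src3):
        spec = MixingModelSpec.reduced(seed=77)
        a = run_mcmc(np.zeros(3), src3, spec, pooling=None)
        b = run_mcmc(np.zeros(3), src3, spec, pooling=None)
        assert np.array_equal(a.draws, b.draws)

    def test_incomplete_tracer_vector_rejected(self, src3):
        with pytest.raises(ValueError, match="complete"):
            run_mcmc(np.array([1.0, np.nan, 2.0]), src3,
                     MixingModelSpec.reduced(seed=0))

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError, match="thin"):
            MixingModelSpec(n_iter=100, thin=33).validate(3, 3)
        with pytest.raises(ValueError, match="positive"):
            MixingModelSpec(thin=-5).validate(3, 3)


class TestDiagnostics:
    def test_independent_chains_look_converged(self):
        rng = np.random.default_rng(0)
        draws = rng.dirichlet([2, 2, 2], size=(3, 500))
        d = diagnose(draws)
        assert np.all(d["rhat"] < 1.01)
        assert np.all(d["ess"] > 500)

    def test_offset_chain_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0, 0.05, size=(3, 500, 2))
        draws[0] += 5.0  # one chain stuck elsewhere
        assert np.nanmax(diagnose(draws)["rhat"]) > 1.1

    def test_constant_chains_give_nan_rhat(self):
        draws = np.full((3, 500, 2), 0.5)
        rhat = diagnose(draws)["rhat"]
        assert np.all(~np.isfinite(rhat) | (rhat > 1.05)) or np.all(np.isnan(rhat))

    def test_single_chain_rhat_undefined(self):
        rng = np.random.default_rng(2)
        d = diagnose(rng.normal(size=(1, 500, 2)))
        assert d["rhat"] is None and d["ess"] is not None

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            diagnose(np.zeros((2, 50, 2)))


class TestPooling:
    def _post(self, seed=0):
        src = source_summary_from_config(StudyConfig(seed=seed))
        return run_mcmc(np.zeros(3), src, MixingModelSpec.reduced(seed=seed),
                        pooling=None)

    def test_identity_mapping_unchanged(self):
        post = self._post()
        pooled = pool_fractions(post, {"small": ("small",),
                                       "medium": ("medium",),
                                       "large": ("large",)})
        np.testing.assert_allclose(pooled.draws, post.draws)

    def test_pooled_draws_sum_to_one(self):
        pooled = pool_fractions(self._post())
        np.testing.assert_allclose(pooled.draws.sum(axis=2), 1.0, atol=1e-12)

    def test_pooled_mean_is_sum_of_component_means(self):
        post = self._post()
        pooled = pool_fractions(post)
        i_m, i_l = post.fractions.index("medium"), post.fractions.index("large")
        assert pooled.mean[pooled.fractions.index("large")] == pytest.approx(
            post.mean[i_m] + post.mean[i_l], abs=1e-12)

    def test_non_partition_mapping_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            pool_fractions(self._post(), {"small": ("small",),
                                          "large": ("large",)})
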
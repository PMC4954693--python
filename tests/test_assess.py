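"""Posterior-predictive model assessment and gene filters."""

import numpy as np
import pytest

from hetmix.assess import (
    ad_two_sample_p,
    assess_concat,
    assess_default,
    assess_ppp,
    condition_subchain,
    posterior_predictive_draws,
    prefilter_on_cells,
)
from hetmix.model import CHParams, Dataset, DetectionParams, GeneModel
from hetmix.simulate import simulate_dataset

from conftest import synthetic_chain

PARAMS = ("pi", "mu", "sigma", "c", "m")


def chain_around(truth, n=2000, jitter=(0.02, 0.1, 0.05, 0.1, 0.02), seed=0):
    """Synthetic posterior concentrated near a known truth."""
    rng = np.random.default_rng(seed)
    base = np.array(truth, dtype=float)
    draws = base + rng.normal(0, jitter, size=(n, 5))
    draws[:, 0] = np.clip(draws[:, 0], 0.01, 0.99)
    draws[:, 2] = np.clip(draws[:, 2], 0.05, 39.0)
    draws[:, 4] = np.clip(draws[:, 4], 0.01, 5.0)
    return synthetic_chain(draws, PARAMS)


@pytest.fixture
def truth_model():
    return GeneModel(CHParams(0.6, 10.0, 1.0), DetectionParams(9.0, 0.25))


@pytest.fixture
def truth_vector(truth_model):
    ch, det = truth_model.ch, truth_model.det
    return (ch.pi, ch.mu, ch.sigma, det.c, det.m)


@pytest.fixture
def observed(truth_model):
    rng = np.random.default_rng(77)
    return simulate_dataset(truth_model, 200, 200, 10, rng)


class TestADTest:
    def test_identical_samples_max_p(self, rng):
        x = rng.normal(size=200)
        assert ad_two_sample_p(x, x) >= 0.25

    def test_type_one_error_near_nominal(self, rng):
        # same continuous distribution: rejection rate at the 0.1 level
        # should be ~10% over replicates
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 100))
            rejections += ad_two_sample_p(a, b) < 0.1
        rate = rejections / n_rep
        assert 0.04 <= rate <= 0.17

    def test_large_separation_rejected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)
        assert ad_two_sample_p(a, b) <= 0.001

    def test_handles_zero_inflation_ties(self, rng):
        a = np.where(rng.random(300) < 0.5, 0.0, rng.lognormal(7, 1, 300))
        b = np.where(rng.random(300) < 0.5, 0.0, rng.lognormal(7, 1, 300))
        assert ad_two_sample_p(a, b) > 0.01
        c = np.where(rng.random(300) < 0.95, 0.0, rng.lognormal(7, 1, 300))
        assert ad_two_sample_p(a, c) <= 0.001

    def test_small_sample_warns(self, rng):
        with pytest.warns(RuntimeWarning):
            ad_two_sample_p(rng.normal(size=3), rng.normal(size=100))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ad_two_sample_p([], [1.0])


class TestPosteriorPredictiveDraws:
    def test_shapes_match_observed(self, truth_vector, observed):
        chain = chain_around(truth_vector)
        sims = posterior_predictive_draws(chain, observed, 20, rng=1)
        assert len(sims) == 20
        for s in sims:
            assert int((s.k == 1).sum()) == 200
            assert int((s.k == 10).sum()) == 200

    def test_detect_fraction_brackets_observed(self, truth_vector, observed):
        chain = chain_around(truth_vector)
        sims = posterior_predictive_draws(chain, observed, 100, rng=2)
        fracs = np.array([(s.values[s.k == 1] > 0).mean() for s in sims])
        obs_frac = (observed.values[observed.k == 1] > 0).mean()
        assert fracs.min() - 0.03 <= obs_frac <= fracs.max() + 0.03

    def test_one_draw_chain_varies_only_by_noise(self, truth_vector, observed):
        chain = synthetic_chain(np.array([truth_vector]), PARAMS)
        sims = posterior_predictive_draws(chain, observed, 5, rng=3)
        means = {tuple(np.round(s.values[:5], 3)) for s in sims}
        assert len(means) == 5  # different simulation noise, same parameters


class TestAssessDefault:
    def test_well_specified_model_passes(self, truth_model):
        # data simulated from the model, fitted by MCMC, then assessed:
        # the fitted posterior must regenerate its own data
        from hetmix.mcmc import MCMCConfig, fit_single_condition

        data = simulate_dataset(truth_model, 100, 100, 10, np.random.default_rng(77))
        cfg = MCMCConfig(adapt_max_iters=8000, burnin_iters=1000,
                         sample_iters=10_000, seed=4)
        chain = fit_single_condition(data, cfg)
        res = assess_default(chain, data, rng=11)
        assert res.passed
        assert res.pass_fraction > 0.75
        assert res.reason is None

    def test_sigma_cap_overrides_ad(self, truth_vector, observed):
        inflated = list(truth_vector)
        inflated[2] = 6.0
        chain = chain_around(inflated, jitter=(0.01, 0.05, 0.05, 0.05, 0.01))
        res = assess_default(chain, observed, rng=12)
        assert not res.passed
        assert res.reason == "sigma_cap"

    def test_misspecified_bimodal_data_fails(self, truth_vector):
        # observed ON cells are strongly bimodal; a unimodal fit cannot
        # regenerate them
        rng = np.random.default_rng(5)
        comp = rng.random(400) < 0.5
        on = np.where(comp, rng.normal(6.0, 0.3, 400), rng.normal(14.0, 0.3, 400))
        values = np.where(rng.random(400) < 0.6, np.exp2(on), 0.0)
        data = Dataset("g", values, np.ones(400, int), np.full(400, "A", object))
        chain = chain_around((0.6, 10.0, 4.0, 5.0, 0.25))
        res = assess_default(chain, data, rng=6)
        assert not res.passed
        assert res.reason == "ad_fraction"

    def test_monotone_in_fraction_threshold(self, truth_vector, observed):
        chain = chain_around(truth_vector)
        res_lo = assess_default(chain, observed, fraction_threshold=0.5, rng=13)
        res_hi = assess_default(chain, observed, fraction_threshold=0.95, rng=13)
        # raising the threshold can only flip pass -> fail
        assert res_lo.pass_fraction == res_hi.pass_fraction
        if res_hi.passed:
            assert res_lo.passed


class TestAssessVariants:
    def test_concat_matches_default_at_one_draw(self, truth_vector, observed):
        chain = chain_around(truth_vector)
        d = assess_default(chain, observed, n_draws=1, fraction_threshold=0.5, rng=21)
        c = assess_concat(chain, observed, n_draws=1, rng=21)
        assert d.passed == c.passed

    def test_concat_helps_sparse_genes(self, rng):
        # few ON cells: the pooled AD test passes more often than the
        # stringent per-draw criterion at equal settings
        truth = GeneModel(CHParams(0.08, 10.0, 1.0), DetectionParams(9.0, 0.25))
        tv = (0.08, 10.0, 1.0, 9.0, 0.25)
        default_pass = concat_pass = 0
        for seed in range(8):
            data = simulate_dataset(truth, 60, 0, 10, np.random.default_rng(seed))
            chain = chain_around(tv, jitter=(0.01, 0.05, 0.05, 0.05, 0.01), seed=seed)
            default_pass += assess_default(chain, data, n_draws=40, rng=seed).passed
            concat_pass += assess_concat(chain, data, n_draws=40, rng=seed).passed
        assert concat_pass >= default_pass

    def test_concat_self_consistency(self, truth_vector, observed):
        chain = chain_around(truth_vector)
        passes = sum(
            assess_concat(chain, observed, n_draws=30, rng=s).passed
            for s in range(10)
        )
        assert passes >= 9

    def test_ppp_calibrated_and_sensitive(self, truth_vector, truth_model):
        chain = chain_around(truth_vector)
        ok = 0
        for seed in range(10):
            data = simulate_dataset(
                truth_model, 150, 150, 10, np.random.default_rng(100 + seed)
            )
            ppp = assess_ppp(chain, data, "mean_on", rng=seed)
            if all(v is None or v >= 0.05 for v in ppp.values()):
                ok += 1
        assert ok >= 9
        # shifting the observed ON-cell mean by +5 Et must be flagged
        data = simulate_dataset(truth_model, 200, 200, 10, np.random.default_rng(1))
        shifted = data.values.copy()
        shifted[shifted > 0] *= 2.0**5
        data_shift = Dataset("g", shifted, data.k, data.condition)
        ppp = assess_ppp(chain, data_shift, "mean_on", rng=2)
        assert all(v < 0.01 for v in ppp.values())

    def test_ppp_constant_statistic_equal_obs(self):
        # pi = 1 and a saturating assay: detect_fraction is 1 in every
        # simulation and in the observed data, so ppp = 1
        tv = (1.0, 20.0, 0.5, 0.5, 0.01)
        chain = synthetic_chain(np.tile(tv, (200, 1)), PARAMS)
        data = simulate_dataset(
            GeneModel(CHParams(1.0, 20.0, 0.5), DetectionParams(0.5, 0.01)),
            100, 0, 10, np.random.default_rng(3),
        )
        ppp = assess_ppp(chain, data, "detect_fraction", rng=4)
        assert ppp["single"] == 1.0

    def test_ppp_undefined_statistic_explicit(self):
        tv = (0.5, 10.0, 1.0, 9.0, 0.25)
        chain = chain_around(tv)
        data = Dataset("g", np.zeros(50), np.ones(50, int), np.full(50, "A", object))
        ppp = assess_ppp(chain, data, "mean_on", rng=5)
        assert ppp["single"] is None


class TestPrefilter:
    @pytest.mark.parametrize("n_on,keep", [(4, False), (5, True), (0, False)])
    def test_boundary(self, n_on, keep, rng):
        values = np.concatenate([np.full(n_on, 1000.0), np.zeros(30 - n_on)])
        data = Dataset("g", values, np.ones(30, int), np.full(30, "A", object))
        decision = prefilter_on_cells(data)
        assert decision.keep is keep
        assert decision.n_on_single == n_on
        assert not decision.flagged

    def test_no_singles_deferred(self):
        data = Dataset("g", [1000.0, 0.0], [10, 10], ["A", "A"])
        decision = prefilter_on_cells(data)
        assert decision.keep and decision.flagged


class TestConditionSubchain:
    def test_extracts_condition_columns(self, rng):
        names = ("pi_a", "mu_a", "sigma_a", "pi_b", "mu_b", "sigma_b", "c", "m")
        draws = rng.random((100, 8))
        chain = synthetic_chain(draws, names)
        sub = condition_subchain(chain, "b")
        assert sub.param_names == PARAMS
        assert (sub.column("pi") == draws[:, 3]).all()
        assert (sub.column("c") == draws[:, 6]).all()
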
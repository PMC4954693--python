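"""Core model: densities, detection, likelihoods, derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.special import expit

from hetmix.model import (
    LN2,
    CHParams,
    Dataset,
    DetectionParams,
    GeneModel,
    TwoConditionModel,
    detection_prob,
    fw_params,
    joint_loglik,
    kc_loglik,
    kc_loglik_empirical,
    log_mean_expression,
    nondetect_on_prob,
    on_cell_logdensity,
    on_fraction_entropy,
    sc_loglik,
    two_condition_loglik,
)

from conftest import random_gene_model


def dataset(values, k=1, condition="A"):
    values = np.asarray(values, dtype=float)
    return Dataset("g", values, np.full(len(values), k), np.full(len(values), condition, dtype=object))


class TestTypes:
    @pytest.mark.parametrize(
        "bad", [dict(pi=-0.1, mu=10, sigma=1), dict(pi=1.1, mu=10, sigma=1),
                dict(pi=0.5, mu=41, sigma=1), dict(pi=0.5, mu=10, sigma=-1)]
    )
    def test_chparams_bounds(self, bad):
        with pytest.raises(ValueError):
            CHParams(**bad)

    @pytest.mark.parametrize("bad", [dict(c=-1, m=1), dict(c=41, m=1),
                                     dict(c=10, m=0), dict(c=10, m=5.1)])
    def test_detection_bounds(self, bad):
        with pytest.raises(ValueError):
            DetectionParams(**bad)

    def test_dataset_rejects_negative_and_bad_k(self):
        with pytest.raises(ValueError):
            dataset([-1.0])
        with pytest.raises(ValueError):
            dataset([1.0], k=0)


class TestDetectionProb:
    def test_midpoint_and_zero(self):
        det = DetectionParams(10.0, 0.7)
        assert detection_prob(2.0**10, det) == pytest.approx(0.5)
        assert detection_prob(0.0, det) == 0.0

    def test_two_logit_units_above_intercept(self):
        # log2 g = c + 2m puts the logistic two logit units up: 1/(1+e^-2)
        det = DetectionParams(8.0, 0.5)
        assert detection_prob(2.0 ** (8.0 + 2 * 0.5), det) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), abs=1e-12
        )

    def test_monotone_nondecreasing(self, rng):
        det = DetectionParams(10.0, 0.4)
        g = np.sort(rng.uniform(0, 2**14, size=200))
        dp = detection_prob(g, det)
        assert (np.diff(dp) >= -1e-15).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            detection_prob(-1.0, DetectionParams(10, 1))


class TestOnCellDensity:
    def test_value_at_log_mode(self):
        ch = CHParams(0.5, 9.0, 1.3)
        expected = math.exp(-0.0) / (1.3 * math.sqrt(2 * math.pi)) / (2.0**9.0 * LN2)
        assert on_cell_logdensity(2.0**9.0, ch) == pytest.approx(math.log(expected))

    def test_normalizes_on_linear_scale(self):
        ch = CHParams(0.5, 6.0, 0.8)
        val, _ = integrate.quad(
            lambda x: math.exp(on_cell_logdensity(x, ch)), 1e-6, 2.0**12, limit=300
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mean_matches_lognormal_moment(self, rng):
        # E[X] = 2**(mu + sigma^2 ln2 / 2), the pi=1 case of log2 E(G)
        ch = CHParams(1.0, 8.0, 1.0)
        x = np.exp2(rng.normal(ch.mu, ch.sigma, size=200_000))
        expected = 2.0 ** (ch.mu + ch.sigma**2 * LN2 / 2)
        assert x.mean() == pytest.approx(expected, rel=0.02)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            on_cell_logdensity(0.0, CHParams(0.5, 10, 1))
        with pytest.raises(ValueError):
            on_cell_logdensity(1.0, CHParams(0.5, 10, 0.0))


class TestFentonWilkinson:
    def test_l1_identity(self):
        ch = CHParams(0.5, 9.5, 1.7)
        fw = fw_params(1, ch)
        assert (fw.mu_l, fw.sigma_l) == pytest.approx((ch.mu, ch.sigma))

    def test_sigma_zero_sum_of_constants(self):
        fw = fw_params(2, CHParams(0.5, 10.0, 0.0))
        assert fw.mu_l == pytest.approx(11.0)
        assert fw.sigma_l == 0.0

    @pytest.mark.parametrize("l,mu,sigma", [(10, 10.0, 1.0), (5, 8.0, 0.5), (3, 12.0, 2.0)])
    def test_matches_sum_moments(self, l, mu, sigma):
        # closed-form log-normal moments: the approximant must match the
        # mean and variance of the sum of l i.i.d. ON-cell levels exactly
        ch = CHParams(0.5, mu, sigma)
        fw = fw_params(l, ch)
        se2 = (sigma * LN2) ** 2
        mean_x = math.exp(mu * LN2 + se2 / 2)
        var_x = (math.exp(se2) - 1) * math.exp(2 * mu * LN2 + se2)
        sl2 = (fw.sigma_l * LN2) ** 2
        mean_fw = math.exp(fw.mu_l * LN2 + sl2 / 2)
        var_fw = (math.exp(sl2) - 1) * math.exp(2 * fw.mu_l * LN2 + sl2)
        assert mean_fw == pytest.approx(l * mean_x, rel=1e-12)
        assert var_fw == pytest.approx(l * var_x, rel=1e-10)

    def test_invalid_l(self):
        with pytest.raises(ValueError):
            fw_params(0, CHParams(0.5, 10, 1))


class TestSingleCellLikelihood:
    def test_all_off_population(self):
        model = GeneModel(CHParams(0.0, 10, 1), DetectionParams(9, 0.5))
        assert sc_loglik(dataset([0.0, 0.0, 0.0]), model) == pytest.approx(0.0)
        assert sc_loglik(dataset([0.0, 512.0]), model) == -np.inf

    def test_dropout_free_limit(self):
        # detection ~1 over the whole ON distribution: P(non-detect) -> 1-pi
        model = GeneModel(CHParams(0.7, 20.0, 0.5), DetectionParams(0.5, 0.01))
        ll = sc_loglik(dataset([0.0]), model)
        assert ll == pytest.approx(math.log(0.3), abs=1e-6)

    def test_measured_law_normalizes(self, rng):
        # point mass at zero plus the continuous part integrate to one
        model = random_gene_model(rng)
        ch, det = model.ch, model.det
        p0 = (1 - ch.pi) + ch.pi * nondetect_on_prob(ch.mu, ch.sigma, det)
        cont, _ = integrate.quad(
            lambda z: math.exp(sc_loglik(dataset([2.0**z]), model)) * 2.0**z * LN2,
            ch.mu - 12 * ch.sigma,
            ch.mu + 12 * ch.sigma,
            limit=300,
        )
        assert p0 + cont == pytest.approx(1.0, abs=1e-6)

    def test_contract_errors(self, medium_model):
        with pytest.raises(ValueError):
            sc_loglik(dataset([1.0], k=10), medium_model)
        with pytest.raises(ValueError):
            sc_loglik(dataset([]), medium_model)

    def test_nondetect_prob_monotone_in_pi_and_c(self):
        # P(non-detect) falls as more cells turn ON, rises as the assay
        # detection threshold c moves up
        mu, sigma, m = 10.0, 1.0, 0.5
        p_at = lambda pi, c: (1 - pi) + pi * nondetect_on_prob(
            mu, sigma, DetectionParams(c, m)
        )
        pis = np.linspace(0, 1, 11)
        assert (np.diff([p_at(p, 9.0) for p in pis]) <= 1e-12).all()
        cs = np.linspace(4, 16, 13)
        assert (np.diff([p_at(0.5, c) for c in cs]) >= -1e-12).all()


class TestKCellLikelihood:
    @pytest.mark.parametrize("seed", range(5))
    def test_k1_reduction(self, seed):
        rng = np.random.default_rng(seed)
        model = random_gene_model(rng)
        data = dataset(np.where(rng.random(40) < 0.4, 0.0, rng.uniform(1, 5000, 40)))
        assert kc_loglik(data, model) == pytest.approx(
            sc_loglik(data, model), abs=1e-10
        )

    def test_all_off_term(self):
        # dropout-free assay: non-detect only if all k cells are OFF
        model = GeneModel(CHParams(0.4, 20.0, 0.5), DetectionParams(0.5, 0.01))
        ll = kc_loglik(dataset([0.0], k=10), model)
        assert ll == pytest.approx(10 * math.log(0.6), abs=1e-5)

    def test_mixed_k_rejected(self, medium_model):
        data = Dataset("g", [0.0, 1.0], [1, 10], ["A", "A"])
        with pytest.raises(ValueError):
            kc_loglik(data, medium_model)

    def test_matches_empirical_kde(self, medium_model, rng):
        from hetmix.simulate import simulate_dataset

        data = simulate_dataset(medium_model, 0, 80, 10, rng)
        analytic = kc_loglik(data, medium_model)
        reps = [
            kc_loglik_empirical(data, medium_model, 10_000, np.random.default_rng(s))
            for s in range(6)
        ]
        assert abs(analytic - np.mean(reps)) < 3 * max(np.std(reps, ddof=1), 0.5)

    def test_empirical_all_off(self):
        model = GeneModel(CHParams(0.0, 10, 1), DetectionParams(9, 0.5))
        ll = kc_loglik_empirical(dataset([0.0], k=10), model, 1000, 0)
        assert ll == pytest.approx(0.0)

    def test_empirical_seed_reproducible(self, medium_model, rng):
        from hetmix.simulate import simulate_dataset

        data = simulate_dataset(medium_model, 0, 30, 10, rng)
        a = kc_loglik_empirical(data, medium_model, 2000, 42)
        b = kc_loglik_empirical(data, medium_model, 2000, 42)
        assert a == b

    def test_large_k_collapse_nonidentifiable(self):
        # at k = 200 the k-cell mixture collapses: halving pi while shifting
        # mu by 1 + delta and shrinking sigma to preserve the first two
        # moments of the per-cell expression G gives an essentially
        # indistinguishable k-cell likelihood (pi, mu, sigma inseparable
        # from k-cell data alone)
        from hetmix.simulate import simulate_dataset

        k = 200
        ch = CHParams(0.8, 10.0, 2.0)
        det = DetectionParams(9.0, 0.5)
        rng = np.random.default_rng(5)
        data = simulate_dataset(GeneModel(ch, det), 0, 200, k, rng)

        se2 = (ch.sigma * LN2) ** 2
        pi2 = ch.pi / 2
        # matching E[G] and E[G^2] with pi halved: sigma_e'^2 = sigma_e^2-ln2
        s2e2 = se2 - LN2
        sigma2 = math.sqrt(s2e2) / LN2
        delta = (LN2 + (se2 - s2e2) / 2) / LN2 - 1.0
        mu2 = ch.mu + 1.0 + delta
        ll1 = kc_loglik(data, GeneModel(ch, det))
        ll2 = kc_loglik(data, GeneModel(CHParams(pi2, mu2, sigma2), det))
        assert abs(ll1 - ll2) < 1.0


class TestJointAndTwoCondition:
    def test_joint_reduces_and_adds(self, medium_model, rng):
        from hetmix.simulate import simulate_dataset

        sc = simulate_dataset(medium_model, 40, 0, 10, rng)
        kc = simulate_dataset(medium_model, 0, 40, 10, rng)
        both = Dataset(
            "g",
            np.concatenate([sc.values, kc.values]),
            np.concatenate([sc.k, kc.k]),
            np.concatenate([sc.condition, kc.condition]),
        )
        assert joint_loglik(sc, medium_model) == pytest.approx(sc_loglik(sc, medium_model))
        assert joint_loglik(kc, medium_model) == pytest.approx(kc_loglik(kc, medium_model))
        assert joint_loglik(both, medium_model) == pytest.approx(
            sc_loglik(sc, medium_model) + kc_loglik(kc, medium_model)
        )

    def test_two_condition_doubles_and_separates(self, medium_model, rng):
        from hetmix.simulate import simulate_dataset

        d = simulate_dataset(medium_model, 30, 30, 10, rng)
        data = Dataset(
            "g",
            np.concatenate([d.values, d.values]),
            np.concatenate([d.k, d.k]),
            np.array(["A"] * len(d) + ["B"] * len(d), dtype=object),
        )
        same = TwoConditionModel(medium_model.ch, medium_model.ch, medium_model.det)
        assert two_condition_loglik(data, same) == pytest.approx(
            2 * joint_loglik(d, medium_model)
        )
        # perturbing condition B leaves the A contribution unchanged
        other = TwoConditionModel(
            medium_model.ch, CHParams(0.3, 12.0, 1.5), medium_model.det
        )
        la = joint_loglik(d, medium_model)
        assert two_condition_loglik(data, other) - la == pytest.approx(
            joint_loglik(d, GeneModel(CHParams(0.3, 12.0, 1.5), medium_model.det))
        )

    def test_requires_two_conditions(self, medium_model, sckc_data):
        same = TwoConditionModel(medium_model.ch, medium_model.ch, medium_model.det)
        with pytest.raises(ValueError):
            two_condition_loglik(sckc_data, same)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "ch,expected",
        [
            (CHParams(1.0, 10.0, 0.0), 10.0),
            (CHParams(0.5, 10.0, 0.0), 9.0),
        ],
    )
    def test_log_mean_expression_closed_forms(self, ch, expected):
        assert log_mean_expression(ch) == pytest.approx(expected)

    def test_log_mean_expression_matches_simulation(self, rng):
        ch = CHParams(0.8, 10.0, 1.0)
        on = rng.random(400_000) < ch.pi
        g = np.where(on, np.exp2(rng.normal(ch.mu, ch.sigma, size=on.size)), 0.0)
        assert log_mean_expression(ch) == pytest.approx(np.log2(g.mean()), abs=0.05)

    def test_log_mean_all_off(self):
        assert log_mean_expression(CHParams(0.0, 10, 1)) == -np.inf

    @given(pi=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_entropy_symmetric_bounded(self, pi):
        h = on_fraction_entropy(pi)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(on_fraction_entropy(1.0 - pi), abs=1e-12)

    def test_entropy_extremes(self):
        assert on_fraction_entropy(0.5) == pytest.approx(1.0)
        assert on_fraction_entropy(0.0) == 0.0
        assert on_fraction_entropy(1.0) == 0.0
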
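"""Likelihoods, the grid oracle, posterior summaries and sampler mechanics."""

import math

import numpy as np
import pytest

from crcapture import (
    CaptureHistory,
    ModelSpec,
    MthParams,
    SamplerConfig,
    bma_summarize,
    capture_prob,
    grid_posterior_oracle,
    log_likelihood,
    run_mcmc,
    to_cell_counts,
)
from crcapture.bayes import MODEL_LABELS, PosteriorDraws, _pattern_loglik
from crcapture.capture_data import CaptureDataError
from crcapture.synthetic import SimulationScenario, simulate


class TestCaptureProb:
    def test_zero_logit_is_half(self):
        assert capture_prob(0.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_log_four_gives_point_eight(self):
        assert capture_prob(math.log(4.0)) == pytest.approx(0.8, abs=1e-9)

    def test_strictly_monotone_in_each_argument(self):
        base = capture_prob(0.3, -0.2, 0.1)
        assert capture_prob(0.4, -0.2, 0.1) > base
        assert capture_prob(0.3, -0.1, 0.1) > base
        assert capture_prob(0.3, -0.2, 0.2) > base

    def test_saturates_without_overflow(self):
        assert capture_prob(900.0) == 1.0
        assert capture_prob(-900.0) == 0.0


class TestLogLikelihood:
    def test_single_individual_fully_observed(self):
        h = CaptureHistory(np.array([[1]]), ("A",))
        p = MthParams(mu=0.0, alpha=None, sigma2_gamma=0.0, N=1)
        assert log_likelihood(h, p, ModelSpec(False, False)) == pytest.approx(
            math.log(0.5)
        )

    def test_combinatorial_term_counts_unseen_individuals(self):
        h = CaptureHistory(np.array([[1]]), ("A",))
        p = MthParams(mu=0.0, alpha=None, sigma2_gamma=0.0, N=2)
        expected = math.log(2) + 2 * math.log(0.5)
        assert log_likelihood(h, p, ModelSpec(False, False)) == pytest.approx(expected)

    def test_matches_term_by_term_product(self, rng):
        """Brute-force oracle: scalar loop over every (i, t) Bernoulli factor."""
        h = CaptureHistory(np.array([[1, 0], [1, 1], [0, 1]]), ("A", "B"))
        mu, alpha, N = 0.4, np.array([0.7, -0.7]), 5
        gamma = rng.normal(0, 1.0, size=N)
        x = np.zeros((N, 2))
        x[:3] = h.matrix
        brute = math.lgamma(N + 1) - math.lgamma(N - 3 + 1)
        for i in range(N):
            for t in range(2):
                pit = 1.0 / (1.0 + math.exp(-(mu + alpha[t] + gamma[i])))
                brute += math.log(pit) if x[i, t] else math.log(1.0 - pit)
        p = MthParams(mu=mu, alpha=alpha, sigma2_gamma=1.0, N=N, gamma=gamma)
        got = log_likelihood(h, p, ModelSpec(True, True))
        assert got == pytest.approx(brute, abs=1e-10)

    def test_population_below_observed_rejected(self):
        h = CaptureHistory(np.array([[1], [1]]), ("A",))
        p = MthParams(mu=0.0, alpha=None, sigma2_gamma=0.0, N=1)
        with pytest.raises(CaptureDataError, match="below the observed count"):
            log_likelihood(h, p, ModelSpec(False, False))

    def test_alpha_must_vanish_without_time_effect(self):
        h = CaptureHistory(np.array([[1]]), ("A",))
        p = MthParams(mu=0.0, alpha=np.array([0.5]), sigma2_gamma=0.0, N=1)
        with pytest.raises(CaptureDataError, match="identically zero"):
            log_likelihood(h, p, ModelSpec(False, False))

    def test_zero_variance_heterogeneity_reduces_to_m0(self):
        h = CaptureHistory(np.array([[1, 0], [1, 1]]), ("A", "B"))
        p0 = MthParams(mu=0.3, alpha=None, sigma2_gamma=0.0, N=4)
        ph = MthParams(
            mu=0.3, alpha=None, sigma2_gamma=0.0, N=4, gamma=np.zeros(4)
        )
        # explicit-gamma path at gamma = 0 equals the homogeneous model exactly
        a = log_likelihood(h, p0, ModelSpec(False, False))
        b = log_likelihood(h, ph, ModelSpec(False, True))
        assert a == b


class TestMarginalPatternLikelihood:
    def test_sigma_zero_limit_matches_quadrature(self):
        pats = np.array([[1.0, 0.0], [1.0, 1.0]])
        nodes, w = np.polynomial.hermite.hermgauss(31)
        quad = (nodes, np.log(w) - 0.5 * np.log(np.pi))
        lp0, z0 = _pattern_loglik(pats, 0.3, np.array([0.4, -0.4]), 0.0, quad)
        lp_eps, z_eps = _pattern_loglik(pats, 0.3, np.array([0.4, -0.4]), 1e-9, quad)
        assert lp_eps == pytest.approx(lp0, abs=1e-10)
        assert z_eps == pytest.approx(z0, abs=1e-10)

    def test_pattern_probabilities_normalize(self):
        T = 3
        pats = np.array(
            [[int(d) for d in format(i, f"0{T}b")] for i in range(2**T)], float
        )
        nodes, w = np.polynomial.hermite.hermgauss(31)
        quad = (nodes, np.log(w) - 0.5 * np.log(np.pi))
        lp, _ = _pattern_loglik(pats, 0.2, np.array([0.5, 0.0, -0.5]), 1.3, quad)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-10)


class TestGridOracle:
    def test_posterior_normalizes(self):
        h = CaptureHistory(np.array([[1, 0], [1, 1], [0, 1], [1, 0], [1, 1]]), "AB")
        Ns, probs = grid_posterior_oracle(h, ModelSpec(False, False), n_max=40)
        assert probs.sum() == pytest.approx(1.0)
        assert Ns[0] == h.n

    def test_refuses_heterogeneity(self):
        h = CaptureHistory(np.array([[1, 0]]), "AB")
        with pytest.raises(CaptureDataError, match="without heterogeneity"):
            grid_posterior_oracle(h, ModelSpec(False, True))

    def test_two_list_mode_near_lincoln_petersen(self):
        """With well-captured two-list data the posterior mode sits at the
        classical n1*n2/m estimate."""
        sc = SimulationScenario(N_true=25, T=2, mu=1.0, alpha=(0.3, -0.3))
        h = simulate(sc, seed=11).observed
        cc = to_cell_counts(h)
        n1, n2 = cc.source_total("S1"), cc.source_total("S2")
        m = cc.overlap("S1", "S2")
        Ns, probs = grid_posterior_oracle(h, ModelSpec(True, False), n_max=80)
        assert abs(Ns[np.argmax(probs)] - n1 * n2 / m) <= 1.0


def _toy_draws(N, model=None, **kw):
    N = np.asarray(N)
    K = N.size
    model = np.zeros(K, dtype=np.int8) if model is None else np.asarray(model)
    defaults = dict(
        mu=np.zeros(K), alpha=np.zeros((K, 3)), sigma_gamma=np.zeros(K),
        burn_in=0, kept_iterations=K, seed=0,
        n=int(N.min()) if K else 0, T=3,
        m_aug=int(N.max()) + 10 if K else 10, config={}, acceptance={},
    )
    defaults.update(kw)
    return PosteriorDraws(model=model, N=N, **defaults)


class TestBmaSummarize:
    def test_constant_chain_degenerates(self):
        est = bma_summarize(_toy_draws(np.full(100, 100)))
        assert est.N_mean == est.N_median == 100
        assert est.N_sd == 0.0
        assert est.hpdi == (100.0, 100.0)
        assert est.model_posteriors["M0"] == 1.0
        assert set(est.per_model_summaries) == {"M0"}

    def test_weighted_average_identity(self):
        N = np.concatenate([np.full(60, 100), np.full(40, 200)])
        model = np.concatenate([np.zeros(60, np.int8), np.ones(40, np.int8)])
        est = bma_summarize(_toy_draws(N, model))
        assert est.model_posteriors["M0"] == pytest.approx(0.6)
        assert est.model_posteriors["Mt"] == pytest.approx(0.4)
        per = est.per_model_summaries
        weighted = 0.6 * per["M0"]["mean"] + 0.4 * per["Mt"]["mean"]
        assert est.N_mean == pytest.approx(weighted)

    def test_hpdi_matches_exhaustive_window_search(self, rng):
        """Oracle: scan every window of ceil(level*K) sorted draws."""
        N = np.round(rng.gamma(40, 5, size=4000))
        est = bma_summarize(_toy_draws(N), level=0.9)
        srt = np.sort(N)
        k = int(np.ceil(0.9 * srt.size))
        widths = srt[k - 1:] - srt[: srt.size - k + 1]
        i = int(np.argmin(widths))
        assert est.hpdi[0] == pytest.approx(srt[i], abs=1e-9)
        assert est.hpdi[1] == pytest.approx(srt[i + k - 1], abs=1e-9)

    def test_empty_draws_rejected(self):
        with pytest.raises(CaptureDataError):
            bma_summarize(_toy_draws(np.array([], dtype=int)))


class TestSampler:
    def _toy_history(self):
        sc = SimulationScenario(N_true=60, T=3, mu=0.5, alpha=(0.6, 0.0, -0.6))
        return simulate(sc, seed=17).observed

    def test_seed_determinism_is_bitwise(self):
        h = self._toy_history()
        cfg = SamplerConfig(iterations=400, burn_in=100)
        a = run_mcmc(h, cfg, seed=5)
        b = run_mcmc(h, cfg, seed=5)
        assert np.array_equal(a.N, b.N)
        assert np.array_equal(a.model, b.model)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.sigma_gamma, b.sigma_gamma)

    def test_draws_respect_invariants(self):
        h = self._toy_history()
        d = run_mcmc(h, SamplerConfig(iterations=500, burn_in=100), seed=2)
        assert (d.N >= h.n).all()
        assert (d.N <= d.m_aug).all()
        est = bma_summarize(d)
        assert sum(est.model_posteriors.values()) == pytest.approx(1.0, abs=1e-12)
        assert est.hpdi[0] <= est.N_median <= est.hpdi[1]
        assert est.N_mean >= h.n

    def test_restricted_model_space_is_respected(self):
        h = self._toy_history()
        d = run_mcmc(h, SamplerConfig(iterations=300, burn_in=50, models=("Mt",)), seed=3)
        assert set(d.model_labels()) == {"Mt"}

    def test_single_list_is_not_identifiable(self):
        h = CaptureHistory(np.ones((30, 1), dtype=int), ("only",))
        d = run_mcmc(
            h, SamplerConfig(iterations=800, burn_in=200, m_aug=300), seed=1
        )
        est = bma_summarize(d)
        # posterior spreads over most of the allowed range instead of peaking
        assert est.hpdi[1] - est.hpdi[0] > 0.5 * (300 - h.n)

    def test_ceiling_warning_reported_in_draws(self, breast_history):
        with pytest.warns(UserWarning, match="increase m_aug"):
            d = run_mcmc(
                breast_history,
                SamplerConfig(iterations=300, burn_in=100, m_aug=790, models=("Mt",)),
                seed=4,
            )
        assert d.warnings

    def test_mcmc_matches_grid_oracle_marginal(self):
        """Total-variation distance between the sampler's N marginal and the
        brute-force grid posterior stays small on a toy M0 instance."""
        sc = SimulationScenario(N_true=25, T=3, mu=0.4)
        h = simulate(sc, seed=8).observed
        Ns, probs = grid_posterior_oracle(h, ModelSpec(False, False), n_max=60)
        d = run_mcmc(
            h,
            SamplerConfig(iterations=12_000, burn_in=1_500, models=("M0",), m_aug=60),
            seed=9,
        )
        emp = np.bincount(d.N, minlength=61)[h.n: 61] / d.N.size
        tv = 0.5 * np.abs(emp - probs).sum()
        assert tv < 0.05


class TestModelSpec:
    def test_labels_follow_flags(self):
        assert ModelSpec(False, False).label == "M0"
        assert ModelSpec(True, False).label == "Mt"
        assert ModelSpec(False, True).label == "Mh"
        assert ModelSpec(True, True).label == "Mth"
        assert [ModelSpec.from_label(l).label for l in MODEL_LABELS] == list(MODEL_LABELS)

    def test_unknown_label_rejected(self):
        with pytest.raises(CaptureDataError):
            ModelSpec.from_label("Mb")
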
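"""Mixed-stock sampler: priors, conditionals, diagnostics, and an oracle."""

import numpy as np
import pandas as pd
import pytest

from mixstock import (
    MSAConfig,
    MixtureSimConfig,
    build_prior,
    gelman_rubin,
    run_msa,
    simulate_mixture,
    summarize,
)
from mixstock.msa import ConvergenceWarning, OrphanHaplotypeError, origin_probabilities
from mixstock.tables import MixtureSample, StockBaseline


def toy_baseline(counts, stocks=None, haps=None):
    stocks = stocks or [f"S{i}" for i in range(len(counts))]
    haps = haps or [f"h{j}" for j in range(len(counts[0]))]
    df = pd.DataFrame(counts, index=stocks, columns=haps)
    return StockBaseline(counts=df, weights=pd.Series(1.0, index=stocks))


class TestPrior:
    def test_flat_prior_is_uniform_simplex(self, baseline):
        alpha = build_prior(baseline, "flat")
        np.testing.assert_allclose(alpha, 1 / 7)
        assert alpha.sum() == pytest.approx(1.0)

    def test_weighted_prior_uses_nesting_females(self, baseline):
        alpha = build_prior(baseline, "weighted")
        w = dict(zip(baseline.stock_ids, alpha))
        # NFpy totals: BRA 50, NWCG 2610, STX 250, SECG 8055, GHA 100, GAB 5000, SAF 50
        assert w["GAB"] == pytest.approx(5000 / 16115, abs=1e-6)
        assert w["SECG"] == pytest.approx(8055 / 16115, abs=1e-6)
        assert alpha.sum() == pytest.approx(1.0)

    def test_single_stock_prior(self):
        b = toy_baseline([[5, 5]])
        np.testing.assert_allclose(build_prior(b, "flat"), [1.0])

    def test_weighted_requires_positive_weight(self):
        b = toy_baseline([[5, 5]])
        b.weights[:] = 0.0
        with pytest.raises(ValueError, match="positive"):
            build_prior(b, "weighted")


class TestOriginConditional:
    def test_private_haplotype_assigns_deterministically(self):
        q = np.array([[1.0, 0.0], [0.0, 1.0]])  # stock 0 owns h0, stock 1 owns h1
        p = origin_probabilities(np.array([0.5, 0.5]), q)
        np.testing.assert_allclose(p, [[1.0, 0.0], [0.0, 1.0]])

    def test_identical_frequencies_reduce_to_theta(self):
        q = np.array([[0.3, 0.7], [0.3, 0.7]])
        theta = np.array([0.2, 0.8])
        p = origin_probabilities(theta, q)
        np.testing.assert_allclose(p, np.tile(theta, (2, 1)))

    def test_zero_likelihood_row_is_uniform(self):
        q = np.array([[1.0, 0.0], [1.0, 0.0]])  # nobody carries h1
        p = origin_probabilities(np.array([0.5, 0.5]), q)
        np.testing.assert_allclose(p[1], [0.5, 0.5])


class TestGelmanRubin:
    def test_identical_constant_chains(self):
        draws = np.ones((3, 100, 2))
        np.testing.assert_allclose(gelman_rubin(draws), 1.0)

    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(size=(2, 5000))
        assert gelman_rubin(draws)[0] < 1.05

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, size=(1, 2000))
        b = rng.normal(10, 1, size=(1, 2000))
        assert gelman_rubin(np.vstack([a, b]))[0] > 1.2

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))


class TestSampler:
    def test_unfiltered_orphans_raise_naming_the_haplotype(self, baseline):
        mix = MixtureSample(counts=pd.Series({"Dc1.1": 5, "DcZZ": 1}))
        with pytest.raises(OrphanHaplotypeError, match="DcZZ"):
            run_msa(mix, baseline, MSAConfig(chain_length=10, burn_in=5))

    def test_single_stock_posterior_is_degenerate(self):
        b = toy_baseline([[50, 50]])
        mix = MixtureSample(counts=pd.Series({"h0": 10, "h1": 10}))
        post = run_msa(mix, b, MSAConfig(n_chains=2, chain_length=200, burn_in=100, rng_seed=0))
        np.testing.assert_allclose(post.pooled, 1.0, atol=1e-12)
        summ = summarize(post)
        assert summ.loc["S0", "q2.5"] == pytest.approx(1.0, abs=1e-12)
        assert summ.loc["S0", "q97.5"] == pytest.approx(1.0, abs=1e-12)

    def test_every_draw_is_a_probability_vector(self, default_posterior):
        pooled = default_posterior.pooled
        np.testing.assert_allclose(pooled.sum(axis=1), 1.0, atol=1e-9)
        assert pooled.min() >= 0.0 and pooled.max() <= 1.0

    def test_kept_draw_count(self, default_posterior):
        cfg = default_posterior.config
        assert default_posterior.pooled.shape[0] == cfg.n_chains * cfg.kept_per_chain == 35_000

    def test_reproducible_given_seed(self):
        b = toy_baseline([[90, 10], [10, 90]])
        mix = MixtureSample(counts=pd.Series({"h0": 12, "h1": 8}))
        cfg = MSAConfig(n_chains=2, chain_length=500, burn_in=100, rng_seed=77)
        p1 = run_msa(mix, b, cfg)
        p2 = run_msa(mix, b, cfg)
        np.testing.assert_array_equal(p1.draws, p2.draws)

    def test_stock_order_exchangeability(self):
        """Permuting stock order permutes the posterior summaries."""
        counts = [[95, 3, 2], [2, 90, 8]]
        mix = MixtureSample(counts=pd.Series({"h0": 30, "h1": 70}, dtype=int))
        cfg = MSAConfig(n_chains=4, chain_length=4000, burn_in=1000, rng_seed=5)
        b1 = toy_baseline(counts, stocks=["A", "B"], haps=["h0", "h1", "h2"])
        b2 = toy_baseline([counts[1], counts[0]], stocks=["B", "A"], haps=["h0", "h1", "h2"])
        m1 = run_msa(mix, b1, cfg).mean
        m2 = run_msa(mix, b2, cfg).mean
        assert m1["A"] == pytest.approx(m2["A"], abs=0.02)
        assert m1["B"] == pytest.approx(m2["B"], abs=0.02)

    def test_divergent_chains_warn_but_return(self):
        b = toy_baseline([[99, 1], [1, 99]])
        mix = MixtureSample(counts=pd.Series({"h0": 10, "h1": 10}))
        cfg = MSAConfig(n_chains=2, chain_length=4, burn_in=2, rng_seed=1, gr_threshold=1.0001)
        with pytest.warns(ConvergenceWarning):
            post = run_msa(mix, b, cfg)
        assert not post.converged

    def test_recovers_known_proportions_on_separated_stocks(self):
        q = pd.DataFrame(
            [[0.9, 0.05, 0.05], [0.05, 0.9, 0.05]],
            index=["A", "B"],
            columns=["h0", "h1", "h2"],
        )
        mix, truth = simulate_mixture(
            MixtureSimConfig(theta={"A": 0.7, "B": 0.3}, true_q=q, n=500, rng_seed=31)
        )
        b = toy_baseline([[900, 50, 50], [50, 900, 50]], stocks=["A", "B"], haps=["h0", "h1", "h2"])
        post = run_msa(mix, b, MSAConfig(n_chains=4, chain_length=3000, burn_in=1000, rng_seed=6))
        assert post.mean["A"] == pytest.approx(0.7, abs=0.05)
        assert post.mean["B"] == pytest.approx(0.3, abs=0.05)


def grid_oracle_mean(baseline_counts, mix_counts, alpha, beta, grid=160):
    """Posterior mean of theta_A for a 2-stock, 2-haplotype model by
    brute-force quadrature over (theta_A, q_A1, q_B1)."""
    b = np.asarray(baseline_counts, float)
    m = np.asarray(mix_counts, float)
    g = (np.arange(grid) + 0.5) / grid
    lt, l1t = np.log(g), np.log(1 - g)
    num = den = 0.0
    log_max = None
    # two passes: find max log-posterior, then accumulate stably
    for passno in range(2):
        for qa in g:
            f1 = g[None, :] * qa + (1 - g[None, :]) * g[:, None]  # (q_B, theta)
            lp = (
                (alpha[0] - 1) * lt[None, :]
                + (alpha[1] - 1) * l1t[None, :]
                + (beta + b[0, 0] - 1) * np.log(qa)
                + (beta + b[0, 1] - 1) * np.log(1 - qa)
                + (beta + b[1, 0] - 1) * np.log(g[:, None])
                + (beta + b[1, 1] - 1) * np.log(1 - g[:, None])
                + m[0] * np.log(f1)
                + m[1] * np.log(1 - f1)
            )
            if passno == 0:
                log_max = lp.max() if log_max is None else max(log_max, lp.max())
            else:
                w = np.exp(lp - log_max)
                num += (w * g[None, :]).sum()
                den += w.sum()
    return num / den


def test_two_stock_posterior_matches_quadrature_oracle():
    """Sampler mean agrees with brute-force numerical integration (+-0.01)."""
    b_counts = [[99, 1], [1, 99]]
    m_counts = [14, 6]
    oracle = grid_oracle_mean(b_counts, m_counts, alpha=[0.5, 0.5], beta=0.5)
    b = toy_baseline(b_counts)
    mix = MixtureSample(counts=pd.Series({"h0": m_counts[0], "h1": m_counts[1]}))
    # 2 chains x 25,000 kept = 50,000 kept draws
    cfg = MSAConfig(n_chains=2, chain_length=27_500, burn_in=2_500, rng_seed=13)
    post = run_msa(mix, b, cfg)
    assert post.mean["S0"] == pytest.approx(oracle, abs=0.01)
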
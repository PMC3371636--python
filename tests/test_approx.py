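"""Block-compressed sampling: emission moments, modified forward recursion,
block path law, block-level updates, and the weak-path error bound."""

import numpy as np
import pytest

from blockhmm.approx import (
    AssumptionViolationError,
    Lemma1Inputs,
    block_emission_loglik,
    block_forward,
    block_parameter_update,
    lemma1_bound,
    lemma1_inputs_for_block,
    run_approx_fbg,
    sample_block_path,
    symmetric_hmm,
    weak_path_ratio_oracle,
)
from blockhmm.approx import _block_statistics
from blockhmm.compression import Block, CompressedTrack, kd_compress
from blockhmm.gibbs import run_fbg, sample_state_path
from blockhmm.hmm import GaussianHMM, ObservationTrack, emission_logdensity, forward
from conftest import random_hmm
from test_gibbs import flat_hyper


def make_blocks(obs, sizes):
    obs = np.asarray(obs, dtype=float)
    blocks, pos = [], 0
    for n in sizes:
        seg = obs[pos : pos + n]
        blocks.append(Block(n, float(seg.sum()), float((seg**2).sum()), pos, pos + n))
        pos += n
    assert pos == len(obs)
    return blocks


class TestBlockEmission:
    def test_singleton_equals_pointwise_density(self):
        b = Block(1, 0.7, 0.49, 0, 1)
        assert block_emission_loglik(b, 0.2, 0.3) == pytest.approx(
            emission_logdensity(0.7, 0.2, 0.3), rel=1e-12
        )

    def test_equals_sum_of_densities(self, rng):
        obs = rng.normal(0.5, 1.0, size=20)
        (b,) = make_blocks(obs, [20])
        direct = sum(emission_logdensity(o, 0.3, 0.8) for o in obs)
        assert block_emission_loglik(b, 0.3, 0.8) == pytest.approx(direct, rel=1e-9)

    def test_centered_block_form(self):
        obs = np.array([1.0, 3.0])  # sum1 = n * mean for mean=2
        (b,) = make_blocks(obs, [2])
        expected = -np.log(2 * np.pi * 0.5) - (b.sum2 - 2 * 2.0**2) / (2 * 0.5)
        assert block_emission_loglik(b, 2.0, 0.5) == pytest.approx(expected, rel=1e-12)


class TestBlockForward:
    def test_singletons_match_exact_forward(self, rng):
        for _ in range(10):
            hmm = random_hmm(rng, rng.integers(1, 4))
            obs = rng.normal(0, 1, size=15)
            blocks = make_blocks(obs, [1] * 15)
            la, ll = forward(hmm, obs)
            lb, llb = block_forward(hmm, blocks)
            np.testing.assert_allclose(lb, la, rtol=1e-9)
            assert llb == pytest.approx(ll, rel=1e-9)

    def test_single_block_single_state(self, rng):
        hmm = GaussianHMM(A=[[1.0]], pi=[1.0], means=[0.1], variances=[0.4])
        obs = rng.normal(size=8)
        (b,) = make_blocks(obs, [8])
        _, ll = block_forward(hmm, [b])
        assert ll == pytest.approx(block_emission_loglik(b, 0.1, 0.4), rel=1e-12)

    def test_two_blocks_match_restricted_enumeration(self, rng):
        """Likelihood equals the sum over within-block-constant paths."""
        hmm = random_hmm(rng, 2)
        obs = rng.normal(0, 1, size=7)
        sizes = [3, 4]
        blocks = make_blocks(obs, sizes)
        terms = []
        for s1 in range(2):
            for s2 in range(2):
                lp = (
                    np.log(hmm.pi[s1])
                    + (sizes[0] - 1) * np.log(hmm.A[s1, s1])
                    + block_emission_loglik(blocks[0], hmm.means[s1], hmm.variances[s1])
                    + np.log(hmm.A[s1, s2])
                    + (sizes[1] - 1) * np.log(hmm.A[s2, s2])
                    + block_emission_loglik(blocks[1], hmm.means[s2], hmm.variances[s2])
                )
                terms.append(lp)
        m = max(terms)
        expected = m + np.log(sum(np.exp(t - m) for t in terms))
        _, ll = block_forward(hmm, blocks)
        assert ll == pytest.approx(expected, rel=1e-10)


class TestSampleBlockPath:
    def test_deterministic_chain_constant_path(self, rng):
        hmm = GaussianHMM(A=np.eye(2), pi=[1.0, 0.0], means=[0.0, 5.0], variances=[1, 1])
        blocks = make_blocks(rng.normal(size=6), [2, 2, 2])
        assert np.all(sample_block_path(hmm, blocks, rng) == 0)

    def test_singleton_law_matches_exact_sampler_law(self, rng):
        """With singleton blocks the block path law equals P(Q|O,theta):
        empirical frequencies from both samplers agree with enumeration."""
        from conftest import oracle_path_posterior

        hmm = random_hmm(rng, 2)
        obs = rng.normal(0, 1, size=3)
        blocks = make_blocks(obs, [1, 1, 1])
        truth = oracle_path_posterior(hmm, obs)
        M = 50_000
        for sampler in (
            lambda: tuple(sample_block_path(hmm, blocks, rng)),
            lambda: tuple(sample_state_path(hmm, obs, rng)),
        ):
            counts = {}
            for _ in range(M):
                q = sampler()
                counts[q] = counts.get(q, 0) + 1
            for path, p in truth.items():
                se = np.sqrt(p * (1 - p) / M)
                assert abs(counts.get(path, 0) / M - p) < 3 * se + 1e-4

    def test_single_block_law(self, rng):
        """State of a lone block drawn prop. to pi_i a_ii^(n-1) * emission."""
        hmm = random_hmm(rng, 2)
        obs = rng.normal(hmm.means[0], 1.0, size=4)
        blocks = make_blocks(obs, [4])
        logw = np.array(
            [
                np.log(hmm.pi[i])
                + 3 * np.log(hmm.A[i, i])
                + block_emission_loglik(blocks[0], hmm.means[i], hmm.variances[i])
                for i in range(2)
            ]
        )
        p = np.exp(logw - logw.max())
        p /= p.sum()
        M = 20_000
        draws = np.array([sample_block_path(hmm, blocks, rng, expand=False)[0] for _ in range(M)])
        se = np.sqrt(p[1] * (1 - p[1]) / M)
        assert abs(draws.mean() - p[1]) < 3 * se + 1e-4

    def test_expansion_repeats_block_states(self, rng):
        hmm = random_hmm(rng, 2)
        obs = rng.normal(size=5)
        blocks = make_blocks(obs, [2, 3])
        path = sample_block_path(hmm, blocks, rng)
        assert len(path) == 5
        assert len(set(path[:2])) == 1 and len(set(path[2:])) == 1


class TestBlockParameterUpdate:
    def test_transition_counts_by_rule(self, rng):
        obs = rng.normal(size=5)
        ct = CompressedTrack(["c1"], {"c1": make_blocks(obs, [3, 2])}, 5, 1.0)
        n, S, SS, trans, init = _block_statistics(ct, {"c1": np.array([0, 1])}, 2)
        # blocks sized (3,2) with states (1,2): {1->1: 2, 1->2: 1, 2->2: 1}
        assert np.array_equal(trans, [[2, 1], [0, 1]])
        assert np.array_equal(init, [1, 0])
        assert np.array_equal(n, [3, 2])

    def test_single_block_moments_are_sufficient(self, rng):
        obs = rng.normal(2.0, 0.5, size=10)
        ct = CompressedTrack(["c1"], {"c1": make_blocks(obs, [10])}, 10, 0.1)
        n, S, SS, trans, init = _block_statistics(ct, {"c1": np.array([1])}, 2)
        assert n[1] == 10 and S[1] == pytest.approx(obs.sum(), rel=1e-12)
        assert SS[1] == pytest.approx((obs**2).sum(), rel=1e-12)
        assert trans[1, 1] == 9

    def test_update_draws_match_exact_with_singletons(self, rng):
        obs = rng.normal(size=12)
        ct = CompressedTrack(["c1"], {"c1": make_blocks(obs, [1] * 12)}, 12, 1.0)
        states = rng.integers(0, 2, size=12)
        hyper = flat_hyper(2)
        r1 = np.random.default_rng(99)
        r2 = np.random.default_rng(99)
        th_block, _ = block_parameter_update(ct, {"c1": states}, hyper, np.ones(2), r1)
        from blockhmm.gibbs import _draw_theta, emission_statistics, transition_statistics
        from blockhmm.hmm import StatePath

        n, S, SS = emission_statistics(obs, states, 2)
        tc, ic = transition_statistics(StatePath({"c1": states}), ["c1"], 2)
        th_exact, _ = _draw_theta(n, S, SS, tc, ic, hyper, np.ones(2), r2)
        assert np.array_equal(th_block.means, th_exact.means)
        assert np.array_equal(th_block.variances, th_exact.variances)
        assert np.array_equal(th_block.A, th_exact.A)


class TestRunApproxFBG:
    def test_zero_width_chain_identical_to_exact(self, rng):
        track = ObservationTrack.from_array(rng.normal(size=300))
        hyper = flat_hyper(2, order=True)
        e = run_fbg(track, hyper, n_iterations=10, seed=5)
        a = run_approx_fbg(track, hyper, width=0.0, n_iterations=10, seed=5)
        for te, ta in zip(e.draws, a.draws):
            assert np.array_equal(te.means, ta.means)
            assert np.array_equal(te.variances, ta.variances)
            assert np.array_equal(te.A, ta.A)
            assert np.array_equal(te.pi, ta.pi)

    def test_records_width_and_gamma(self, rng):
        track = ObservationTrack.from_array(rng.normal(size=400))
        res = run_approx_fbg(track, flat_hyper(2), width=0.5, n_iterations=3, seed=1)
        assert res.width_used == 0.5
        assert res.model_kind == "approximate"
        assert 0 < res.compression_ratio <= 1

    def test_auto_width_selects_knee(self):
        from blockhmm.simulate import preset, sample_hmm_sequence

        track, _ = sample_hmm_sequence(preset("two_state").true_hmm, 2000, seed=3)
        res = run_approx_fbg(
            track, preset("two_state").make_hyperparameters(), width="auto",
            n_iterations=3, seed=4,
        )
        assert 0 < res.width_used < 4 * track.sigma_D


class TestLemma1:
    def test_remark_setting_evaluates_to_one_third_excess(self):
        """t=0.9, d=1, var=0.1, tau=0.25, alpha=1, N=2, n=10 -> about 1.33."""
        v = lemma1_bound(Lemma1Inputs(t=0.9, d=1.0, sigma2=0.1, tau=0.25, alpha=1.0, n=10, N=2))
        assert v == pytest.approx(1.3258401, rel=1e-6)
        assert v - 1.0 == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_n1_and_large_tau_limits(self):
        v = lemma1_bound(Lemma1Inputs(t=0.9, d=1.0, sigma2=0.1, tau=0.0, alpha=1.0, n=1, N=3))
        assert v == pytest.approx(1.0 + 2.0, rel=1e-12)  # c=1 at tau=0
        v = lemma1_bound(Lemma1Inputs(t=0.9, d=1.0, sigma2=0.1, tau=1e6, alpha=1.0, n=1, N=3))
        assert v == pytest.approx(1.0, rel=1e-9)

    def test_negative_tau_rejected(self):
        with pytest.raises(AssumptionViolationError):
            Lemma1Inputs(t=0.9, d=1.0, sigma2=0.1, tau=-0.1, alpha=1.0, n=2, N=2)

    def test_oracle_is_one_for_single_observation(self):
        hmm = symmetric_hmm([0.0, 1.0], 0.1, 0.9)
        r = weak_path_ratio_oracle(hmm, [0.5, 0.5], [0.2])
        assert r == pytest.approx(1.0, rel=1e-12)

    def test_oracle_near_one_far_from_other_means(self):
        hmm = symmetric_hmm([0.0, 50.0], 0.1, 0.9)
        r = weak_path_ratio_oracle(hmm, [0.5, 0.5], np.zeros(5))
        assert r == pytest.approx(1.0, rel=1e-9)

    def test_bound_dominates_enumeration(self, rng):
        """Analytic bound >= enumerated weak-path ratio on random instances."""
        checked = 0
        while checked < 30:
            N = int(rng.integers(2, 4))
            hmm = symmetric_hmm(np.arange(N) * rng.uniform(0.5, 2.0), rng.uniform(0.05, 0.5), rng.uniform(0.5, 0.99))
            n = int(rng.integers(1, 7))
            obs = rng.normal(hmm.means[rng.integers(0, N)], 0.3 * np.sqrt(hmm.variances[0]), size=n)
            rho = rng.dirichlet(np.ones(N))
            try:
                inp = lemma1_inputs_for_block(hmm, rho, obs)
            except AssumptionViolationError:
                continue
            assert lemma1_bound(inp) >= weak_path_ratio_oracle(hmm, rho, obs) - 1e-12
            checked += 1
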
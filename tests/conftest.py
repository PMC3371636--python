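"""Shared fixtures and brute-force oracles.

The enumeration oracle computes likelihoods, posterior marginals, Viterbi
scores and path posteriors by explicit summation over all N^T state paths;
it is the independent reference for the recursive implementations on tiny
instances.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from blockhmm.hmm import GaussianHMM, emission_logdensity


def logsumexp(v):
    v = np.asarray(v, dtype=float)
    m = v.max()
    return float(m + np.log(np.exp(v - m).sum()))


def enumerate_paths(hmm: GaussianHMM, obs):
    """All (path, log P(Q, O | theta)) pairs by explicit enumeration."""
    obs = np.asarray(obs, dtype=float)
    T, N = len(obs), hmm.n_states
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.A)
        logpi = np.log(hmm.pi)
    out = []
    for path in itertools.product(range(N), repeat=T):
        lp = logpi[path[0]] + emission_logdensity(obs[0], hmm.means[path[0]], hmm.variances[path[0]])
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + emission_logdensity(
                obs[t], hmm.means[path[t]], hmm.variances[path[t]]
            )
        out.append((path, lp))
    return out


def oracle_loglik(hmm, obs):
    return logsumexp([lp for _, lp in enumerate_paths(hmm, obs)])


def oracle_marginals(hmm, obs):
    paths = enumerate_paths(hmm, obs)
    T, N = len(obs), hmm.n_states
    ll = logsumexp([lp for _, lp in paths])
    g = np.zeros((T, N))
    for path, lp in paths:
        w = np.exp(lp - ll)
        for t, s in enumerate(path):
            g[t, s] += w
    return g


def oracle_viterbi_score(hmm, obs):
    return max(lp for _, lp in enumerate_paths(hmm, obs))


def oracle_path_posterior(hmm, obs):
    """dict path -> P(Q | O, theta)."""
    paths = enumerate_paths(hmm, obs)
    ll = logsumexp([lp for _, lp in paths])
    return {path: np.exp(lp - ll) for path, lp in paths}


def random_hmm(rng, n_states, ordered=False) -> GaussianHMM:
    A = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
    pi = rng.dirichlet(np.ones(n_states))
    means = np.sort(rng.normal(0, 2, n_states)) if ordered else rng.normal(0, 2, n_states)
    variances = rng.uniform(0.05, 1.5, n_states)
    return GaussianHMM(A=A, pi=pi, means=means, variances=variances, ordered=ordered)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
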
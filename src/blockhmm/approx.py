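"""Approximate forward-backward Gibbs sampling on compressed blocks.

After kd-tree compression every block is assumed to arise from a single
hidden state (state paths that switch inside a block -- "weak" paths -- are
ignored).  The forward recursion then advances block by block:

``P(q_t* = i, O'_1..b | theta) =
    sum_j P(q_{t*-n_b} = j, O'_1..b-1 | theta) * a_ji * a_ii^(n_b - 1)
    * prod_{o in block b} N(o; mu_i, var_i)``

where the block emission product is evaluated in constant time from the
precomputed moments.  Backward sampling draws one state per block; parameter
updates accumulate block moments and add ``n_b - 1`` self-transitions per
block plus one transition per adjacent block pair (chromosome junctions
excluded).  With singleton blocks (width 0 on distinct values) every formula
degenerates to the exact sampler and, because the two samplers share their
draw primitives, the chains are bit-identical for the same seed.

The error incurred by ignoring weak paths is controlled by an analytic bound
(:func:`lemma1_bound`) for symmetric HMMs: if a block of ``n`` observations
sits within the decision region of some state with margin ``tau``, the ratio
of the full path sum to the constant-path sum is at most

``alpha * ((1 + r c)^(n-1) + (N-1) c^(2n/N) (1 + r)^(n-1))``,

with ``r = (1-t)/t`` (``t`` the self-transition probability) and
``c = exp(-d tau / (2 var))`` (``d`` the minimal mean separation).  A brute
force enumeration oracle over all ``N^n`` partial paths is provided to
validate the bound on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .compression import (
    Block,
    CompressedTrack,
    compress_track,
    compression_curve,
    default_width_grid,
    select_width_lmethod,
)
from .gibbs import (
    ChainResult,
    Hyperparameters,
    _categorical_from_logits,
    _draw_theta,
    _window_average_marginals,
    draw_from_prior,
)
from .hmm import GaussianHMM, ObservationTrack, StatePath, _log_matvec, _logsumexp

__all__ = [
    "Lemma1Inputs",
    "block_emission_loglik",
    "block_forward",
    "sample_block_path",
    "block_parameter_update",
    "run_approx_fbg",
    "lemma1_bound",
    "lemma1_inputs_for_block",
    "weak_path_ratio_oracle",
    "symmetric_hmm",
]


class AssumptionViolationError(ValueError):
    """Raised when the geometric assumptions of the error bound fail."""


# ---------------------------------------------------------------------------
# block emission likelihoods


def block_emission_loglik(block: Block, mean: float, variance: float) -> float:
    """log prod_{o in block} N(o; mean, variance), from the stored moments."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    n = block.count
    quad = block.sum2 - 2.0 * mean * block.sum1 + n * mean**2
    return float(-(n / 2.0) * np.log(2.0 * np.pi * variance) - quad / (2.0 * variance))


def _block_arrays(blocks: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts = np.array([b.count for b in blocks], dtype=np.int64)
    sum1 = np.array([b.sum1 for b in blocks])
    sum2 = np.array([b.sum2 for b in blocks])
    return counts, sum1, sum2


def _block_emission_matrix(
    counts: np.ndarray, sum1: np.ndarray, sum2: np.ndarray, hmm: GaussianHMM
) -> np.ndarray:
    """(B, N) block emission log-likelihoods.

    Singleton blocks use the centered form ``-(o - mu)^2 / (2 var)`` -- it
    avoids the cancellation of the moment form and coincides operation for
    operation with the per-observation emission matrix of the exact sampler.
    """
    means, variances = hmm.means, hmm.variances
    nc = counts[:, None].astype(float)
    quad = sum2[:, None] - 2.0 * means * sum1[:, None] + nc * means**2
    logE = -(nc / 2.0) * np.log(2.0 * np.pi * variances) - quad / (2.0 * variances)
    single = counts == 1
    if np.any(single):
        logE[single] = -0.5 * np.log(2.0 * np.pi * variances) - (
            (sum1[single, None] - means) ** 2
        ) / (2.0 * variances)
    return logE


# ---------------------------------------------------------------------------
# block forward / backward sampling


def block_forward(hmm: GaussianHMM, blocks: list) -> tuple[np.ndarray, float]:
    """Modified forward recursion over blocks; returns (log table, loglik).

    The first block of a chromosome uses ``pi_i * a_ii^(n-1)`` (the interior
    formula with the initial distribution in place of the incoming
    transition).  Cost is O(T' N^2).
    """
    if len(blocks) == 0:
        raise ValueError("need at least one block")
    counts, sum1, sum2 = _block_arrays(blocks)
    logE = _block_emission_matrix(counts, sum1, sum2, hmm)
    B, N = logE.shape
    with np.errstate(divide="ignore"):
        log_diag = np.log(np.diag(hmm.A))
        log_pi = np.log(hmm.pi)
    log_alpha = np.empty((B, N))
    log_alpha[0] = log_pi + logE[0]
    if counts[0] > 1:
        log_alpha[0] = log_alpha[0] + (counts[0] - 1) * log_diag
    for b in range(1, B):
        v = _log_matvec(log_alpha[b - 1], hmm.A) + logE[b]
        if counts[b] > 1:
            v = v + (counts[b] - 1) * log_diag
        log_alpha[b] = v
    return log_alpha, _logsumexp(log_alpha[-1])


def sample_block_path(
    hmm: GaussianHMM, blocks: list, rng: np.random.Generator, expand: bool = True
):
    """Draw one state per block backward from the block forward table.

    With ``expand=True`` the block states are repeated out to one state per
    observation (the form the rest of the package consumes); ``expand=False``
    returns the per-block states, keeping the per-iteration cost O(T' N^2).
    """
    log_alpha, _ = block_forward(hmm, blocks)
    B, N = log_alpha.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.A)
    s = np.empty(B, dtype=np.int64)
    s[-1] = _categorical_from_logits(log_alpha[-1], rng)
    for b in range(B - 2, -1, -1):
        s[b] = _categorical_from_logits(log_alpha[b] + logA[:, s[b + 1]], rng)
    if not expand:
        return s
    counts = np.array([b.count for b in blocks], dtype=np.int64)
    return np.repeat(s, counts)


# ---------------------------------------------------------------------------
# block-level parameter update


def _block_statistics(compressed: CompressedTrack, block_states: dict, n_states: int):
    """Sufficient statistics from blocks and one state per block.

    Emission moments accumulate the stored block moments; transition counts
    add ``n_b - 1`` self-transitions per block and one between-block
    transition per adjacent pair within a chromosome.
    """
    N = n_states
    n = np.zeros(N)
    S = np.zeros(N)
    SS = np.zeros(N)
    trans = np.zeros((N, N))
    init = np.zeros(N)
    for c in compressed.chromosomes:
        bl = compressed.blocks[c]
        s = np.asarray(block_states[c], dtype=np.int64)
        counts, sum1, sum2 = _block_arrays(bl)
        n += np.bincount(s, weights=counts.astype(float), minlength=N)
        S += np.bincount(s, weights=sum1, minlength=N)
        SS += np.bincount(s, weights=sum2, minlength=N)
        self_counts = (counts - 1).astype(float)
        np.add.at(trans, (s, s), self_counts)
        if len(s) > 1:
            trans += np.bincount(s[:-1] * N + s[1:], minlength=N * N).reshape(N, N)
        init[s[0]] += 1.0
    return n, S, SS, trans, init


def block_parameter_update(
    compressed: CompressedTrack,
    block_states: dict,
    hyper: Hyperparameters,
    current_variances: np.ndarray,
    rng: np.random.Generator,
):
    """Conjugate parameter sweep from block statistics.

    Returns ``(theta, sort_fallback_used)``; the draws are the same
    primitives the exact sampler uses, applied to the block-level sufficient
    statistics.
    """
    n, S, SS, trans, init = _block_statistics(compressed, block_states, hyper.n_states)
    return _draw_theta(n, S, SS, trans, init, hyper, current_variances, rng)


def run_approx_fbg(
    track: ObservationTrack,
    hyper: Hyperparameters,
    width="auto",
    n_iterations: int = 100,
    seed=None,
    hmm0: GaussianHMM | None = None,
    posterior_window: int = 10,
    delta: float = 1.25,
    keep_final_path: bool = True,
    compute_marginals: bool = True,
    rng: np.random.Generator | None = None,
) -> ChainResult:
    """Approximate FBG sampling: compress once, then sample on blocks.

    ``width`` is in observation units; ``"auto"`` selects the knee of the
    compression curve over the default grid (0.25..4 sigma_D in steps of
    0.25 sigma_D) with the L-method.  Posterior summaries in the returned
    chain are evaluated exactly on the uncompressed observations.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    if width == "auto":
        curve = compression_curve(track, default_width_grid(track.sigma_D), delta=delta)
        width = select_width_lmethod(curve).width
    width = float(width)
    compressed = compress_track(track, width, delta=delta)
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = hmm0 if hmm0 is not None else draw_from_prior(hyper, rng)
    draws: list[GaussianHMM] = []
    fallbacks = 0
    block_states = None
    for _ in range(n_iterations):
        block_states = {
            c: sample_block_path(theta, compressed.blocks[c], rng, expand=False)
            for c in compressed.chromosomes
        }
        theta, fell_back = block_parameter_update(
            compressed, block_states, hyper, theta.variances, rng
        )
        fallbacks += int(fell_back)
        draws.append(theta)

    final_path = None
    if keep_final_path and block_states is not None:
        final_path = StatePath(
            {
                c: np.repeat(
                    block_states[c],
                    [b.count for b in compressed.blocks[c]],
                )
                for c in compressed.chromosomes
            }
        )
    marginals = (
        _window_average_marginals(draws, track, posterior_window) if compute_marginals else {}
    )
    return ChainResult(
        draws=draws,
        posterior_mean_marginals=marginals,
        seed=seed,
        model_kind="approximate",
        width_used=width,
        posterior_window=posterior_window,
        ordering_fallbacks=fallbacks,
        final_path=final_path,
        compression_ratio=compressed.gamma,
    )


# ---------------------------------------------------------------------------
# weak-state-path error bound


@dataclass
class Lemma1Inputs:
    """Inputs of the weak-path bound for a symmetric Gaussian HMM.

    ``t``: self-transition probability; ``d``: minimal mean separation;
    ``sigma2``: shared emission variance; ``tau``: margin between the block's
    value range and the decision midpoints toward the neighboring means;
    ``alpha``: bound on the prefix-posterior ratio; ``n``: block length;
    ``N``: state count.
    """

    t: float
    d: float
    sigma2: float
    tau: float
    alpha: float
    n: int
    N: int

    def __post_init__(self) -> None:
        if not 0.0 < self.t < 1.0:
            raise ValueError("self-transition probability must lie in (0, 1)")
        if self.d <= 0 or self.sigma2 <= 0:
            raise ValueError("mean separation and variance must be positive")
        if self.tau < 0:
            raise AssumptionViolationError("margin tau must be nonnegative")
        if self.alpha < 1:
            raise ValueError("alpha is a ratio against the maximizing state, so >= 1")
        if self.n < 1 or self.N < 2:
            raise ValueError("need n >= 1 observations and N >= 2 states")


def lemma1_bound(inp: Lemma1Inputs) -> float:
    """Upper bound on (all-path mass) / (constant-path mass) for one block."""
    r = (1.0 - inp.t) / inp.t
    c = np.exp(-inp.d * inp.tau / (2.0 * inp.sigma2))
    return float(
        inp.alpha
        * ((1.0 + r * c) ** (inp.n - 1) + (inp.N - 1) * c ** (2.0 * inp.n / inp.N) * (1.0 + r) ** (inp.n - 1))
    )


def symmetric_hmm(means, sigma2: float, t: float) -> GaussianHMM:
    """The symmetric HMM of the bound: shared variance, uniform off-diagonals."""
    means = np.sort(np.asarray(means, dtype=float))
    N = len(means)
    A = np.full((N, N), (1.0 - t) / (N - 1))
    np.fill_diagonal(A, t)
    return GaussianHMM(
        A=A, pi=np.full(N, 1.0 / N), means=means, variances=np.full(N, sigma2), ordered=True
    )


def _check_symmetric(hmm: GaussianHMM) -> float:
    t = hmm.A[0, 0]
    N = hmm.n_states
    off = (1.0 - t) / (N - 1)
    expected = np.full((N, N), off)
    np.fill_diagonal(expected, t)
    if not np.allclose(hmm.A, expected, atol=1e-12):
        raise AssumptionViolationError("bound requires a symmetric transition matrix")
    if not np.allclose(hmm.variances, hmm.variances[0], atol=1e-12):
        raise AssumptionViolationError("bound requires a shared emission variance")
    return float(t)


def lemma1_inputs_for_block(
    hmm: GaussianHMM, prefix_posterior, block_obs
) -> Lemma1Inputs:
    """Assemble the bound's inputs for a concrete block.

    Picks the state whose decision region contains the block with the largest
    margin ``tau``; raises :class:`AssumptionViolationError` if no state
    yields ``tau >= 0``.  ``alpha`` is the largest prefix-posterior ratio
    against that state.
    """
    t = _check_symmetric(hmm)
    mu = hmm.means
    rho = np.asarray(prefix_posterior, dtype=float)
    obs = np.asarray(block_obs, dtype=float)
    omin, omax = obs.min(), obs.max()
    N = hmm.n_states
    lower_mid = np.concatenate(([-np.inf], (mu[:-1] + mu[1:]) / 2.0))
    upper_mid = np.concatenate(((mu[:-1] + mu[1:]) / 2.0, [np.inf]))
    taus = np.minimum(omin - lower_mid, upper_mid - omax)
    x = int(np.argmax(taus))
    if taus[x] < 0:
        raise AssumptionViolationError("block straddles a decision boundary (tau < 0)")
    d = float(np.min(np.diff(mu)))
    alpha = float(np.max(rho) / rho[x])
    return Lemma1Inputs(
        t=t,
        d=d,
        sigma2=float(hmm.variances[0]),
        tau=float(taus[x]),
        alpha=alpha,
        n=len(obs),
        N=N,
    )


def weak_path_ratio_oracle(hmm: GaussianHMM, prefix_posterior, block_obs) -> float:
    """Exact (all paths) / (constant paths) probability ratio by enumeration.

    Enumerates all ``N^n`` partial state paths over the block, weighting the
    first position by the prefix posterior.  Intended as the independent
    check of :func:`lemma1_bound` on small instances (``N^n <= 1e6``).
    """
    _check_symmetric(hmm)
    obs = np.asarray(block_obs, dtype=float)
    rho = np.asarray(prefix_posterior, dtype=float)
    n, N = len(obs), hmm.n_states
    if N**n > 1_000_000:
        raise ValueError("enumeration too large (N^n > 1e6)")
    logE = -0.5 * np.log(2.0 * np.pi * hmm.variances) - (
        (obs[:, None] - hmm.means) ** 2
    ) / (2.0 * hmm.variances)
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.A)
        log_rho = np.log(rho)
    all_terms = []
    const_terms = []
    for path in itertools.product(range(N), repeat=n):
        lp = log_rho[path[0]] + logE[0, path[0]]
        for k in range(1, n):
            lp += logA[path[k - 1], path[k]] + logE[k, path[k]]
        all_terms.append(lp)
        if all(s == path[0] for s in path):
            const_terms.append(lp)
    return float(np.exp(_logsumexp(np.array(all_terms)) - _logsumexp(np.array(const_terms))))
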
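"""Gaussian-emission hidden Markov models and exact inference primitives.

A :class:`GaussianHMM` is an ``N``-state chain with univariate Gaussian
emissions ``N(mu_i, var_i)``, a row-stochastic transition matrix ``A`` and an
initial distribution ``pi``.  All inference here is carried out in the log
domain so that sequences of several hundred thousand observations (high
density SNP arrays) can be processed without underflow.

The module also defines the two in-memory containers used throughout the
package: :class:`ObservationTrack` (per-chromosome ordered sequences of real
valued observations, e.g. log2 ratios) and :class:`StatePath` (one hidden
state per observation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianHMM",
    "ObservationTrack",
    "StatePath",
    "emission_logdensity",
    "emission_logdensity_matrix",
    "forward",
    "backward",
    "loglikelihood",
    "viterbi",
    "posterior_marginals",
]

_ATOL = 1e-9


class InvalidParameterError(ValueError):
    """Raised when HMM parameters violate their invariants."""


@dataclass
class GaussianHMM:
    """Parameter set ``theta = (A, pi, means, variances)`` of a Gaussian HMM.

    Parameters
    ----------
    A : (N, N) array
        Transition probabilities; each row sums to one.
    pi : (N,) array
        Initial state distribution.
    means, variances : (N,) arrays
        Emission means and variances (variances, not standard deviations).
    ordered : bool
        If set, ``means`` must be non-decreasing (the label-switching
        constraint used during sampling).
    """

    A: np.ndarray
    pi: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    ordered: bool = False

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.means)

    def validate(self) -> None:
        N = self.n_states
        if N < 1:
            raise InvalidParameterError("need at least one state")
        if self.A.shape != (N, N) or self.pi.shape != (N,):
            raise InvalidParameterError("A/pi shape inconsistent with state count")
        if np.any(self.A < 0) or np.any(self.pi < 0):
            raise InvalidParameterError("negative probabilities")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=_ATOL):
            raise InvalidParameterError("rows of A must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=_ATOL):
            raise InvalidParameterError("pi must sum to 1")
        if np.any(self.variances <= 0):
            raise InvalidParameterError("variances must be positive")
        if self.ordered and np.any(np.diff(self.means) < 0):
            raise InvalidParameterError("means must be non-decreasing when ordered")


@dataclass
class ObservationTrack:
    """Ordered per-chromosome sequences of real-valued observations.

    ``observations`` maps a chromosome label to a 1-D float array; the
    ``chromosomes`` list fixes iteration order.  ``positions`` optionally
    stores integer probe coordinates per chromosome.
    """

    chromosomes: list[str]
    observations: dict[str, np.ndarray]
    positions: dict[str, np.ndarray] | None = None
    _sigma_D: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.observations = {
            c: np.asarray(self.observations[c], dtype=float) for c in self.chromosomes
        }
        for c in self.chromosomes:
            o = self.observations[c]
            if o.ndim != 1 or len(o) == 0:
                raise ValueError(f"chromosome {c!r} must hold a nonempty 1-D sequence")
            if not np.all(np.isfinite(o)):
                raise ValueError(f"non-finite observation on chromosome {c!r}")

    @classmethod
    def from_array(cls, obs, chrom: str = "chr1") -> "ObservationTrack":
        """Wrap a single sequence as a one-chromosome track."""
        return cls([chrom], {chrom: np.asarray(obs, dtype=float)})

    @property
    def total_length(self) -> int:
        return sum(len(self.observations[c]) for c in self.chromosomes)

    @property
    def sigma_D(self) -> float:
        """Standard deviation of all observations pooled across chromosomes."""
        if self._sigma_D is None:
            self._sigma_D = float(np.std(self.concat()))
        return self._sigma_D

    def concat(self) -> np.ndarray:
        return np.concatenate([self.observations[c] for c in self.chromosomes])


@dataclass
class StatePath:
    """One hidden-state index (0-based) per observation, per chromosome."""

    states: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.states = {c: np.asarray(q, dtype=np.int64) for c, q in self.states.items()}

    def concat(self, chromosomes=None) -> np.ndarray:
        order = chromosomes if chromosomes is not None else list(self.states)
        return np.concatenate([self.states[c] for c in order])

    def matches(self, track: ObservationTrack) -> bool:
        return all(
            c in self.states and len(self.states[c]) == len(track.observations[c])
            for c in track.chromosomes
        )


# ---------------------------------------------------------------------------
# emission densities


def emission_logdensity(value: float, mean: float, variance: float) -> float:
    """log N(value; mean, variance)."""
    if variance <= 0:
        raise InvalidParameterError("variance must be positive")
    return float(-0.5 * np.log(2.0 * np.pi * variance) - (value - mean) ** 2 / (2.0 * variance))


def emission_logdensity_matrix(obs: np.ndarray, hmm: GaussianHMM) -> np.ndarray:
    """(T, N) matrix of per-observation, per-state Gaussian log densities."""
    obs = np.asarray(obs, dtype=float)
    return -0.5 * np.log(2.0 * np.pi * hmm.variances) - (
        (obs[:, None] - hmm.means) ** 2
    ) / (2.0 * hmm.variances)


def _log_matvec(logv: np.ndarray, A: np.ndarray) -> np.ndarray:
    """log(sum_j exp(logv_j) * A_ji) computed stably; shared by the exact and
    the block-compressed forward recursions so that both perform identical
    floating point operations on identical inputs."""
    m = logv.max()
    if not np.isfinite(m):  # all -inf: dead prefix
        return np.full(A.shape[1], -np.inf)
    with np.errstate(divide="ignore"):
        return m + np.log(np.exp(logv - m) @ A)


def _check_obs(obs) -> np.ndarray:
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observation sequence must be nonempty and 1-D")
    return obs


# ---------------------------------------------------------------------------
# exact recursions


def forward(hmm: GaussianHMM, obs) -> tuple[np.ndarray, float]:
    """Log-domain forward pass.

    Returns
    -------
    log_alpha : (T, N) array
        ``log P(q_t = i, o_1..t | theta)``.
    loglik : float
        ``log P(O | theta)``.
    """
    obs = _check_obs(obs)
    logE = emission_logdensity_matrix(obs, hmm)
    T, N = logE.shape
    log_alpha = np.empty((T, N))
    with np.errstate(divide="ignore"):
        log_alpha[0] = np.log(hmm.pi) + logE[0]
    for t in range(1, T):
        log_alpha[t] = _log_matvec(log_alpha[t - 1], hmm.A) + logE[t]
    return log_alpha, _logsumexp(log_alpha[-1])


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.exp(v - m).sum()))


def backward(hmm: GaussianHMM, obs) -> np.ndarray:
    """Log-domain backward pass: ``log P(o_{t+1}..T | q_t = i, theta)``."""
    obs = _check_obs(obs)
    logE = emission_logdensity_matrix(obs, hmm)
    T, N = logE.shape
    log_beta = np.zeros((T, N))
    for t in range(T - 2, -1, -1):
        v = log_beta[t + 1] + logE[t + 1]
        m = v.max()
        if not np.isfinite(m):
            log_beta[t] = -np.inf
            continue
        with np.errstate(divide="ignore"):
            log_beta[t] = m + np.log(hmm.A @ np.exp(v - m))
    return log_beta


def loglikelihood(hmm: GaussianHMM, track: ObservationTrack) -> float:
    """Pooled log-likelihood: chromosomes are independent chains sharing theta."""
    return sum(forward(hmm, track.observations[c])[1] for c in track.chromosomes)


def viterbi(hmm: GaussianHMM, obs) -> np.ndarray:
    """Most likely state path (0-based indices); ties break to the lowest index."""
    obs = _check_obs(obs)
    logE = emission_logdensity_matrix(obs, hmm)
    T, N = logE.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.A)
        score = np.log(hmm.pi) + logE[0]
    back = np.empty((T, N), dtype=np.int64)
    for t in range(1, T):
        cand = score[:, None] + logA  # cand[j, i]: best-so-far ending j then ->i
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(N)] + logE[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def posterior_marginals(hmm: GaussianHMM, obs) -> np.ndarray:
    """Per-position state posteriors ``P(q_t = i | O, theta)`` as a (T, N) array."""
    log_alpha, _ = forward(hmm, obs)
    log_beta = backward(hmm, obs)
    lg = log_alpha + log_beta
    lg -= lg.max(axis=1, keepdims=True)
    g = np.exp(lg)
    g /= g.sum(axis=1, keepdims=True)
    return g


def track_posterior_marginals(hmm: GaussianHMM, track: ObservationTrack) -> dict[str, np.ndarray]:
    return {c: posterior_marginals(hmm, track.observations[c]) for c in track.chromosomes}


def track_viterbi(hmm: GaussianHMM, track: ObservationTrack) -> StatePath:
    return StatePath({c: viterbi(hmm, track.observations[c]) for c in track.chromosomes})
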
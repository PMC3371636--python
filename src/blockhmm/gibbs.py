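"""Exact forward-backward Gibbs (FBG) sampling for Gaussian HMMs.

One sweep alternates (i) an exact draw of the hidden state path from
``P(Q | O, theta)`` -- forward recursion followed by backward sampling -- and
(ii) conjugate parameter draws:

* ``mu_i     ~ Normal``   posterior of a Normal prior ``N(mu0_i, v0_i)``
  (``v0_i`` is the prior *variance* of the mean),
* ``1/var_i  ~ Gamma(a_i + n_i/2, b_i + 0.5 * sum (o - mu_i)^2)``,
* row ``i`` of ``A ~ Dirichlet(lambda^A_i + transition counts)``,
* ``pi ~ Dirichlet(lambda^pi + initial-state counts)``.

Chromosomes are pooled: they share one parameter set, transitions never cross
a chromosome junction, and each chromosome contributes one initial-state
count to the ``pi`` update.  Label switching is prevented (when enabled) by
an ordering constraint on the means, enforced by rejection with a sort
fallback.

The parameter draws are written as functions of sufficient statistics
``(n_i, S_i = sum o, SS_i = sum o^2, transition counts, initial counts)`` so
that the block-compressed sampler in :mod:`blockhmm.approx` can reuse them
verbatim; with singleton blocks the two samplers then produce bit-identical
chains from the same seed.

Scan order within a sweep (fixed, for reproducibility): state paths per
chromosome in track order, then means, variances, transition rows, initial
distribution.  ``theta^0`` is drawn from the priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import (
    GaussianHMM,
    ObservationTrack,
    StatePath,
    forward,
    track_posterior_marginals,
)

__all__ = [
    "Hyperparameters",
    "ChainResult",
    "sample_state_path",
    "sample_emission_parameters",
    "sample_transition_rows",
    "enforce_mean_ordering",
    "run_fbg",
]

_MAX_ORDER_RETRIES = 100


@dataclass
class Hyperparameters:
    """Conjugate prior parameters for an ``N``-state Gaussian HMM.

    ``mu_prior_variances`` are the prior variances of the emission means
    (not standard deviations).  ``precision_shapes`` / ``precision_rates``
    parameterize Gamma priors on the emission precisions ``1/var_i``.
    """

    mu_prior_means: np.ndarray
    mu_prior_variances: np.ndarray
    precision_shapes: np.ndarray
    precision_rates: np.ndarray
    dirichlet_A: np.ndarray
    dirichlet_pi: np.ndarray
    order_means: bool = True

    def __post_init__(self) -> None:
        for name in (
            "mu_prior_means",
            "mu_prior_variances",
            "precision_shapes",
            "precision_rates",
            "dirichlet_A",
            "dirichlet_pi",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        N = self.n_states
        if self.dirichlet_A.shape != (N, N) or self.dirichlet_pi.shape != (N,):
            raise ValueError("Dirichlet parameter shapes inconsistent with state count")
        for name in ("mu_prior_variances", "precision_shapes", "precision_rates"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.dirichlet_A <= 0) or np.any(self.dirichlet_pi <= 0):
            raise ValueError("Dirichlet parameters must be strictly positive")

    @property
    def n_states(self) -> int:
        return len(self.mu_prior_means)


@dataclass
class ChainResult:
    """MCMC output: parameter draws plus per-position posterior summaries.

    ``posterior_mean_marginals[chrom]`` is the average of the exact
    per-position posteriors ``P(q_t = i | O, theta^m)`` over the trailing
    ``posterior_window`` parameter draws, evaluated on the *uncompressed*
    observations regardless of how the chain was produced.
    """

    draws: list
    posterior_mean_marginals: dict
    seed: object
    model_kind: str  # "exact" or "approximate"
    width_used: float | None
    posterior_window: int
    ordering_fallbacks: int = 0
    final_path: StatePath | None = None
    compression_ratio: float | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.draws)

    @property
    def theta_final(self) -> GaussianHMM:
        return self.draws[-1]

    def window_draws(self) -> list:
        return self.draws[-min(self.posterior_window, len(self.draws)):]


# ---------------------------------------------------------------------------
# shared low-level draws (also used by the block sampler)


def _categorical_from_logits(logp: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index proportional to ``exp(logp)`` using one uniform."""
    m = logp.max()
    p = np.exp(logp - m)
    u = rng.random() * p.sum()
    return int(min(np.searchsorted(np.cumsum(p), u, side="right"), len(p) - 1))


def enforce_mean_ordering(proposed: np.ndarray, redraw, max_retries: int = _MAX_ORDER_RETRIES):
    """Accept a mean vector only if non-decreasing, redrawing up to a cap.

    ``redraw`` must return a fresh joint draw of the full mean vector.  If
    every retry fails the last draw is sorted (logged by the caller through
    the returned flag).  Ties (equal adjacent means) are accepted: under a
    continuous posterior they occur with probability zero, so non-strict
    acceptance does not change the distribution.
    """
    mu = np.asarray(proposed, dtype=float)
    for _ in range(max_retries):
        if np.all(np.diff(mu) >= 0):
            return mu, False
        mu = np.asarray(redraw(), dtype=float)
    if np.all(np.diff(mu) >= 0):
        return mu, False
    return np.sort(mu), True


def _draw_means(
    n: np.ndarray,
    S: np.ndarray,
    hyper: Hyperparameters,
    variances: np.ndarray,
    rng: np.random.Generator,
):
    """Joint draw of all emission means from their Normal posteriors."""
    post_var = 1.0 / (1.0 / hyper.mu_prior_variances + n / variances)
    post_mean = (hyper.mu_prior_means / hyper.mu_prior_variances + S / variances) * post_var
    sd = np.sqrt(post_var)

    def draw():
        return post_mean + sd * rng.standard_normal(hyper.n_states)

    mu = draw()
    if not hyper.order_means:
        return mu, False
    return enforce_mean_ordering(mu, draw)


def _draw_variances(
    n: np.ndarray,
    S: np.ndarray,
    SS: np.ndarray,
    means: np.ndarray,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> np.ndarray:
    # sum (o - mu)^2 from the moments; clipped at 0 against rounding
    resid = np.maximum(SS - 2.0 * means * S + n * means**2, 0.0)
    shape = hyper.precision_shapes + 0.5 * n
    rate = hyper.precision_rates + 0.5 * resid
    precision = rng.gamma(shape, 1.0 / rate)
    return 1.0 / precision


def _draw_transition_params(
    trans_counts: np.ndarray,
    init_counts: np.ndarray,
    hyper: Hyperparameters,
    rng: np.random.Generator,
):
    N = hyper.n_states
    A = np.empty((N, N))
    for i in range(N):
        A[i] = rng.dirichlet(hyper.dirichlet_A[i] + trans_counts[i])
    pi = rng.dirichlet(hyper.dirichlet_pi + init_counts)
    return A, pi


def _draw_theta(
    n: np.ndarray,
    S: np.ndarray,
    SS: np.ndarray,
    trans_counts: np.ndarray,
    init_counts: np.ndarray,
    hyper: Hyperparameters,
    current_variances: np.ndarray,
    rng: np.random.Generator,
):
    """One full conjugate parameter sweep from sufficient statistics.

    Scan order: means (conditioned on the previous variances), variances
    (conditioned on the new means), transition rows, initial distribution.
    """
    means, fell_back = _draw_means(n, S, hyper, current_variances, rng)
    variances = _draw_variances(n, S, SS, means, hyper, rng)
    A, pi = _draw_transition_params(trans_counts, init_counts, hyper, rng)
    theta = GaussianHMM(A=A, pi=pi, means=means, variances=variances, ordered=hyper.order_means)
    return theta, fell_back


def draw_from_prior(hyper: Hyperparameters, rng: np.random.Generator) -> GaussianHMM:
    """theta^0: a draw from the prior (the zero-data conjugate update)."""
    N = hyper.n_states
    zeros = np.zeros(N)
    theta, _ = _draw_theta(
        zeros, zeros, zeros, np.zeros((N, N)), zeros, hyper, np.ones(N), rng
    )
    return theta


# ---------------------------------------------------------------------------
# sufficient statistics from raw data


def emission_statistics(obs: np.ndarray, path: np.ndarray, n_states: int):
    """Per-state counts, sums and sums of squares given a state path."""
    n = np.bincount(path, minlength=n_states).astype(float)
    S = np.bincount(path, weights=obs, minlength=n_states)
    SS = np.bincount(path, weights=obs * obs, minlength=n_states)
    return n, S, SS


def transition_statistics(paths: StatePath, chromosomes, n_states: int):
    """Pooled transition counts (junctions excluded) and initial-state counts."""
    N = n_states
    counts = np.zeros((N, N))
    init = np.zeros(N)
    for c in chromosomes:
        q = paths.states[c]
        init[q[0]] += 1.0
        if len(q) > 1:
            counts += np.bincount(q[:-1] * N + q[1:], minlength=N * N).reshape(N, N)
    return counts, init


# ---------------------------------------------------------------------------
# public sampling operations


def sample_state_path(hmm: GaussianHMM, obs, rng: np.random.Generator) -> np.ndarray:
    """Exact draw of ``Q ~ P(Q | O, theta)`` by backward sampling.

    ``q_T`` is drawn proportional to the final forward variables; for
    ``t < T``, ``q_t`` proportional to ``alpha_t(i) * a_{i, q_{t+1}}``.
    """
    log_alpha, _ = forward(hmm, obs)
    T, N = log_alpha.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.A)
    q = np.empty(T, dtype=np.int64)
    q[-1] = _categorical_from_logits(log_alpha[-1], rng)
    for t in range(T - 2, -1, -1):
        q[t] = _categorical_from_logits(log_alpha[t] + logA[:, q[t + 1]], rng)
    return q


def sample_emission_parameters(
    obs: np.ndarray,
    path: np.ndarray,
    hyper: Hyperparameters,
    current_variances: np.ndarray,
    rng: np.random.Generator,
):
    """Draw (means, variances) from their conjugate posteriors given a path.

    States with no assigned observations draw from their priors.  Returns
    ``(means, variances, sort_fallback_used)``.
    """
    n, S, SS = emission_statistics(np.asarray(obs, float), np.asarray(path), hyper.n_states)
    means, fell_back = _draw_means(n, S, hyper, np.asarray(current_variances, float), rng)
    variances = _draw_variances(n, S, SS, means, hyper, rng)
    return means, variances, fell_back


def sample_transition_rows(paths: StatePath, chromosomes, hyper: Hyperparameters, rng):
    """Draw (A, pi) from Dirichlet posteriors with pooled counts."""
    counts, init = transition_statistics(paths, chromosomes, hyper.n_states)
    return _draw_transition_params(counts, init, hyper, rng)


def run_fbg(
    track: ObservationTrack,
    hyper: Hyperparameters,
    n_iterations: int = 100,
    seed=None,
    hmm0: GaussianHMM | None = None,
    posterior_window: int = 10,
    keep_final_path: bool = True,
    compute_marginals: bool = True,
    rng: np.random.Generator | None = None,
) -> ChainResult:
    """Run exact forward-backward Gibbs sampling for ``n_iterations`` sweeps.

    Deterministic given ``seed``.  After the chain finishes, the exact
    per-position posteriors under the trailing ``posterior_window`` parameter
    draws are averaged into ``posterior_mean_marginals``.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = hmm0 if hmm0 is not None else draw_from_prior(hyper, rng)
    N = hyper.n_states
    draws: list[GaussianHMM] = []
    fallbacks = 0
    paths = None
    for _ in range(n_iterations):
        paths = StatePath(
            {c: sample_state_path(theta, track.observations[c], rng) for c in track.chromosomes}
        )
        n = np.zeros(N)
        S = np.zeros(N)
        SS = np.zeros(N)
        for c in track.chromosomes:
            nc, Sc, SSc = emission_statistics(track.observations[c], paths.states[c], N)
            n += nc
            S += Sc
            SS += SSc
        counts, init = transition_statistics(paths, track.chromosomes, N)
        theta, fell_back = _draw_theta(n, S, SS, counts, init, hyper, theta.variances, rng)
        fallbacks += int(fell_back)
        draws.append(theta)

    marginals = (
        _window_average_marginals(draws, track, posterior_window) if compute_marginals else {}
    )
    return ChainResult(
        draws=draws,
        posterior_mean_marginals=marginals,
        seed=seed,
        model_kind="exact",
        width_used=None,
        posterior_window=posterior_window,
        ordering_fallbacks=fallbacks,
        final_path=paths if keep_final_path else None,
    )


def _window_average_marginals(draws, track: ObservationTrack, window: int):
    tail = draws[-min(window, len(draws)):]
    acc = None
    for theta in tail:
        g = track_posterior_marginals(theta, track)
        if acc is None:
            acc = {c: g[c].copy() for c in g}
        else:
            for c in g:
                acc[c] += g[c]
    for c in acc:
        acc[c] /= len(tail)
    return acc
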
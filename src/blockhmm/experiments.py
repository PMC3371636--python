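"""Benchmark protocols used by the test-suite and the acceptance script.

Two self-contained experiments:

* :func:`two_state_experiment` -- sample a length-``T`` sequence from the
  2-state benchmark HMM, run the exact sampler and the approximate sampler
  at a grid of widths (multiples of the data standard deviation), and score
  each fitted model against the *generating* parameters: average posterior
  error (mean total-variation distance between the per-position posteriors
  under the final parameter draw and under the truth) and the Viterbi
  mismatch count.

* :func:`cgh_recovery_experiment` -- simulate array-CGH template profiles
  with controlled noise, segment with a 3-state model both exactly and
  approximately (knee-selected width), and score two-class F1 against the
  simulator truth plus the probe-level agreement between the two samplers.
"""

from __future__ import annotations

import numpy as np

from .approx import run_approx_fbg
from .evaluate import (
    average_posterior_error,
    calls_from_chain,
    calls_from_labels,
    two_class_metrics,
    viterbi_mismatch,
)
from .gibbs import run_fbg
from .hmm import track_posterior_marginals, track_viterbi
from .simulate import CGHTemplateSpec, preset, sample_hmm_sequence, simulate_cgh_template

__all__ = ["derive_seeds", "two_state_experiment", "cgh_recovery_experiment"]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def two_state_experiment(
    seed: int,
    T: int = 10_000,
    n_iterations: int = 100,
    width_multiples=(0.25, 0.5, 1.0, 1.5, 2.0),
    posterior_window: int = 10,
) -> dict:
    """One replicate of the 2-state benchmark.

    Returns a dict with the true-parameter log-likelihood, exact-sampler
    scores and per-width approximate-sampler scores.
    """
    data_seed, chain_seed = derive_seeds(seed, 2)
    pre = preset("two_state")
    hmm_true = pre.true_hmm
    hyper = pre.make_hyperparameters()
    track, _ = sample_hmm_sequence(hmm_true, T, seed=data_seed)

    post_true = track_posterior_marginals(hmm_true, track)
    vit_true = track_viterbi(hmm_true, track)
    from .hmm import loglikelihood

    result = {
        "seed": seed,
        "sigma_D": track.sigma_D,
        "loglik_true": loglikelihood(hmm_true, track),
        "approx": {},
    }

    def score(chain):
        theta = chain.theta_final
        return {
            "p_err": average_posterior_error(
                track_posterior_marginals(theta, track), post_true
            ),
            "mismatches": viterbi_mismatch(track_viterbi(theta, track), vit_true),
        }

    exact = run_fbg(
        track,
        hyper,
        n_iterations=n_iterations,
        seed=chain_seed,
        posterior_window=posterior_window,
        keep_final_path=False,
    )
    result["exact"] = score(exact)

    for mult in width_multiples:
        chain = run_approx_fbg(
            track,
            hyper,
            width=mult * track.sigma_D,
            n_iterations=n_iterations,
            seed=chain_seed,
            posterior_window=posterior_window,
            keep_final_path=False,
        )
        s = score(chain)
        s["gamma"] = chain.compression_ratio
        result["approx"][mult] = s
    return result


def cgh_recovery_experiment(
    seed: int,
    noise_sd: float = 0.2,
    n_iterations: int = 100,
    posterior_window: int = 10,
) -> dict:
    """One replicate of the template-simulation recovery benchmark.

    A 3-state model (loss / neutral / gain) is fitted with the exact sampler
    and with the approximate sampler at the L-method knee width; both call
    sets are scored against the simulator truth.
    """
    data_seed, exact_seed, approx_seed = derive_seeds(seed, 3)
    track, labels = simulate_cgh_template(CGHTemplateSpec(noise_sd=noise_sd, seed=data_seed))
    truth = calls_from_labels(labels, track.chromosomes)
    pre = preset("gbm3")
    hyper = pre.make_hyperparameters(sigma_D=track.sigma_D)

    exact = run_fbg(
        track, hyper, n_iterations=n_iterations, seed=exact_seed,
        posterior_window=posterior_window, keep_final_path=False,
    )
    approx_chain = run_approx_fbg(
        track, hyper, width="auto", n_iterations=n_iterations, seed=approx_seed,
        posterior_window=posterior_window, keep_final_path=False,
    )
    calls_exact = calls_from_chain(exact, pre.state_to_class)
    calls_approx = calls_from_chain(approx_chain, pre.state_to_class)
    agreement = float(np.mean(calls_exact.concat() == calls_approx.concat()))
    return {
        "seed": seed,
        "f1_exact": two_class_metrics(calls_exact, truth).f1,
        "f1_approx": two_class_metrics(calls_approx, truth).f1,
        "agreement": agreement,
        "width_used": approx_chain.width_used,
        "gamma": approx_chain.compression_ratio,
        "sigma_D": track.sigma_D,
    }
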
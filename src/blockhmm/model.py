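"""Model / Results front-end for Bayesian HMM segmentation.

:class:`HMMSegmentation` is constructed from an observation track and a
prior specification; :meth:`~HMMSegmentation.fit` runs either the exact
forward-backward Gibbs sampler or the block-compressed approximate sampler
and returns an :class:`HMMSegmentationResults` carrying the chain, posterior
parameter summaries, per-probe posteriors and call generation.

Example
-------
>>> from blockhmm import simulate, HMMSegmentation
>>> pre = simulate.preset("two_state")
>>> track, _ = simulate.sample_hmm_sequence(pre.true_hmm, 2000, seed=7)
>>> res = HMMSegmentation(track, pre.make_hyperparameters()).fit(
...     method="approx", width="auto", iterations=50, seed=7)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import approx, gibbs
from .evaluate import CallSet, calls_from_chain
from .gibbs import ChainResult, Hyperparameters
from .hmm import GaussianHMM, ObservationTrack, StatePath, loglikelihood, track_viterbi

__all__ = ["HMMSegmentation", "HMMSegmentationResults"]


class HMMSegmentation:
    """Bayesian Gaussian-HMM segmentation model for an observation track."""

    def __init__(self, track: ObservationTrack, hyperparameters: Hyperparameters):
        self.track = track
        self.hyperparameters = hyperparameters

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, hyperparameters: Hyperparameters):
        """Build from a DataFrame with ``chrom`` and ``value`` columns."""
        chroms = list(dict.fromkeys(df["chrom"].astype(str)))
        obs = {c: df.loc[df["chrom"].astype(str) == c, "value"].to_numpy(float) for c in chroms}
        return cls(ObservationTrack(chroms, obs), hyperparameters)

    def fit(
        self,
        method: str = "exact",
        width="auto",
        iterations: int = 100,
        posterior_window: int = 10,
        seed=None,
        hmm0: GaussianHMM | None = None,
    ) -> "HMMSegmentationResults":
        """Run the sampler and wrap the chain in a results object.

        ``method`` is ``"exact"`` (forward-backward Gibbs on every probe) or
        ``"approx"`` (kd-tree block compression at ``width``, which may be
        ``"auto"`` for L-method knee selection).
        """
        if method == "exact":
            chain = gibbs.run_fbg(
                self.track,
                self.hyperparameters,
                n_iterations=iterations,
                seed=seed,
                hmm0=hmm0,
                posterior_window=posterior_window,
            )
        elif method == "approx":
            chain = approx.run_approx_fbg(
                self.track,
                self.hyperparameters,
                width=width,
                n_iterations=iterations,
                seed=seed,
                hmm0=hmm0,
                posterior_window=posterior_window,
            )
        else:
            raise ValueError("method must be 'exact' or 'approx'")
        return HMMSegmentationResults(self, chain)


class HMMSegmentationResults:
    """Posterior summaries and diagnostics for a fitted segmentation."""

    def __init__(self, model: HMMSegmentation, chain: ChainResult):
        self.model = model
        self.chain = chain

    # -- posterior parameter summaries over the trailing window ------------

    def _window_stack(self, attr: str) -> np.ndarray:
        return np.stack([getattr(th, attr) for th in self.chain.window_draws()])

    @property
    def params(self) -> pd.DataFrame:
        """Posterior means and standard deviations of mu, var and A diagonal."""
        mus = self._window_stack("means")
        vars_ = self._window_stack("variances")
        diags = np.stack([np.diag(th.A) for th in self.chain.window_draws()])
        rows = []
        for i in range(mus.shape[1]):
            rows.append(
                {
                    "state": i + 1,
                    "mean": mus[:, i].mean(),
                    "mean_sd": mus[:, i].std(ddof=1) if len(mus) > 1 else 0.0,
                    "variance": vars_[:, i].mean(),
                    "variance_sd": vars_[:, i].std(ddof=1) if len(vars_) > 1 else 0.0,
                    "self_transition": diags[:, i].mean(),
                    "self_transition_sd": diags[:, i].std(ddof=1) if len(diags) > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows).set_index("state")

    @property
    def theta(self) -> GaussianHMM:
        """The final parameter draw of the chain."""
        return self.chain.theta_final

    @property
    def posterior_marginals(self) -> dict:
        return self.chain.posterior_mean_marginals

    # -- decodings ----------------------------------------------------------

    def viterbi(self, theta: GaussianHMM | None = None) -> StatePath:
        return track_viterbi(theta if theta is not None else self.theta, self.model.track)

    def loglikelihood(self, theta: GaussianHMM | None = None) -> float:
        return loglikelihood(theta if theta is not None else self.theta, self.model.track)

    def calls(self, state_to_class: dict) -> CallSet:
        return calls_from_chain(self.chain, state_to_class)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        c = self.chain
        head = [
            "Bayesian HMM segmentation",
            "=" * 60,
            f"sampler:            {c.model_kind}",
            f"iterations:         {c.n_iterations} (posterior window {c.posterior_window})",
            f"probes:             {self.model.track.total_length}"
            f" on {len(self.model.track.chromosomes)} chromosome(s)",
        ]
        if c.model_kind == "approximate":
            head.append(f"width w:            {c.width_used:.6g}")
            head.append(f"compression gamma:  {c.compression_ratio:.4g}")
        if c.ordering_fallbacks:
            head.append(f"ordering fallbacks: {c.ordering_fallbacks} (sorted after retry cap)")
        head.append(f"log L (final draw): {self.loglikelihood():.2f}")
        table = self.params.to_string(float_format=lambda v: f"{v:10.4f}")
        return "\n".join(head) + "\n" + "-" * 60 + "\n" + table
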
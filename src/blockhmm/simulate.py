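"""Synthetic data generators and model presets.

Two generators cover the package's self-contained experiments:

* :func:`sample_hmm_sequence` draws an observation sequence from an
  arbitrary Gaussian HMM -- in particular from the 2-state benchmark model
  ``lambda_2ST`` (self-transitions 0.9, means 0 and 1, variances 0.1,
  uniform start).

* :func:`simulate_cgh_template` emulates array-CGH profiles: three
  chromosomes of 500/750/1000 probes, non-overlapping aberrant regions
  (10 regions of 11-20 probes in the small chromosome, 15 regions of 11-25
  probes in each larger one), each independently a gain or a loss, with
  theoretical log2 ratios -1 (loss), 0 (neutral), 0.58 (gain) plus additive
  N(0, sigma) noise.  Signal-to-noise ratio is 0.58/sigma.

:func:`preset` returns the published hyperparameter configurations for the
2-state benchmark, the 4-state array-CGH models (template simulation and the
HBL-2 lymphoma variant), the 3-state glioma model (depends on the data
standard deviation sigma_D) and the 3-state SNP-array model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gibbs import Hyperparameters
from .hmm import GaussianHMM, ObservationTrack, StatePath

__all__ = [
    "CGHTemplateSpec",
    "Preset",
    "sample_hmm_sequence",
    "simulate_cgh_template",
    "preset",
    "two_state_hmm",
    "PRESET_NAMES",
]

LEVELS = {"loss": -1.0, "neutral": 0.0, "gain": 0.58}


def two_state_hmm() -> GaussianHMM:
    """The 2-state benchmark model lambda_2ST."""
    return GaussianHMM(
        A=np.array([[0.9, 0.1], [0.1, 0.9]]),
        pi=np.array([0.5, 0.5]),
        means=np.array([0.0, 1.0]),
        variances=np.array([0.1, 0.1]),
        ordered=True,
    )


def sample_hmm_sequence(
    hmm: GaussianHMM, T: int, seed=None, chrom: str = "chr1", rng=None
) -> tuple[ObservationTrack, StatePath]:
    """Sample ``(O, Q)`` of length ``T`` from a Gaussian HMM."""
    if T < 1:
        raise ValueError("need T >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    N = hmm.n_states
    q = np.empty(T, dtype=np.int64)
    q[0] = rng.choice(N, p=hmm.pi)
    for t in range(1, T):
        q[t] = rng.choice(N, p=hmm.A[q[t - 1]])
    obs = rng.normal(hmm.means[q], np.sqrt(hmm.variances[q]))
    return ObservationTrack([chrom], {chrom: obs}), StatePath({chrom: q})


@dataclass
class CGHTemplateSpec:
    """Layout of the synthetic array-CGH template profiles."""

    chrom_sizes: tuple = (500, 750, 1000)
    n_regions: tuple = (10, 15, 15)
    region_size_ranges: tuple = ((11, 20), (11, 25), (11, 25))
    levels: dict = field(default_factory=lambda: dict(LEVELS))
    noise_sd: float = 0.2
    seed: object = None
    max_placement_retries: int = 1000

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (len(self.chrom_sizes) == len(self.n_regions) == len(self.region_size_ranges)):
            raise ValueError("per-chromosome settings must have equal lengths")

    @property
    def snr(self) -> float:
        """Signal-to-noise ratio, gain level over noise standard deviation."""
        return self.levels["gain"] / self.noise_sd


def _place_regions(size: int, n_regions: int, len_range, rng, max_retries: int):
    """Rejection-sample non-overlapping (start, length) regions."""
    for _ in range(max_retries):
        lengths = rng.integers(len_range[0], len_range[1] + 1, size=n_regions)
        starts = rng.integers(0, size - lengths + 1)
        order = np.argsort(starts)
        starts, lengths = starts[order], lengths[order]
        if np.all(starts[1:] >= starts[:-1] + lengths[:-1]):
            return list(zip(starts.tolist(), lengths.tolist()))
    raise RuntimeError("could not place non-overlapping regions; chromosome too crowded")


def simulate_cgh_template(spec: CGHTemplateSpec):
    """Generate probe log-ratios and per-probe truth labels.

    Returns ``(track, labels)`` where ``labels[chrom]`` is an array of
    strings in {"loss", "neutral", "gain"}.  Each aberrant region is a gain
    or a loss with probability 1/2.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(len(spec.chrom_sizes))]
    obs = {}
    labels = {}
    for c, size, n_reg, len_range in zip(
        chroms, spec.chrom_sizes, spec.n_regions, spec.region_size_ranges
    ):
        lab = np.full(size, "neutral", dtype=object)
        for start, length in _place_regions(
            size, n_reg, len_range, rng, spec.max_placement_retries
        ):
            lab[start : start + length] = "gain" if rng.random() < 0.5 else "loss"
        level = np.array([spec.levels[l] for l in lab])
        obs[c] = level + rng.normal(0.0, spec.noise_sd, size=size)
        labels[c] = lab.astype(str)
    return ObservationTrack(chroms, obs), labels


# ---------------------------------------------------------------------------
# published model presets


@dataclass
class Preset:
    """A named model configuration: state count, priors, class mapping.

    ``hyperparameters`` may depend on the pooled data standard deviation
    (the glioma preset does); call :meth:`make_hyperparameters` with
    ``sigma_D`` in that case.  ``true_hmm`` is populated only for the
    2-state benchmark, whose generating parameters are part of the preset.
    """

    name: str
    n_states: int
    state_to_class: dict
    _hyper_factory: object
    needs_sigma_D: bool = False
    true_hmm: GaussianHMM | None = None

    def make_hyperparameters(self, sigma_D: float | None = None) -> Hyperparameters:
        if self.needs_sigma_D:
            if sigma_D is None:
                raise ValueError(f"preset {self.name!r} needs sigma_D")
            return self._hyper_factory(sigma_D)
        return self._hyper_factory()


def _ones(n):
    return np.ones(n)


def _two_state() -> Preset:
    def hyper():
        return Hyperparameters(
            mu_prior_means=[0.0, 1.0],
            mu_prior_variances=[0.5, 0.5],
            precision_shapes=[4.0, 4.0],
            precision_rates=[1.0, 1.0],
            dirichlet_A=np.ones((2, 2)),
            dirichlet_pi=[1.0, 1.0],
            order_means=True,
        )

    return Preset(
        name="two_state",
        n_states=2,
        state_to_class={0: "neutral", 1: "gain"},
        _hyper_factory=hyper,
        true_hmm=two_state_hmm(),
    )


def _cgh4(sigma_tilde, shapes) -> Preset:
    def hyper():
        return Hyperparameters(
            mu_prior_means=[-0.5, 0.0, 0.58, 1.0],
            mu_prior_variances=sigma_tilde,
            precision_shapes=shapes,
            precision_rates=_ones(4),
            dirichlet_A=np.ones((4, 4)),
            dirichlet_pi=_ones(4),
            order_means=True,
        )

    return Preset(
        name="cgh4",
        n_states=4,
        state_to_class={0: "loss", 1: "neutral", 2: "gain", 3: "gain"},
        _hyper_factory=hyper,
    )


def _gbm3() -> Preset:
    def hyper(sigma_D: float):
        return Hyperparameters(
            mu_prior_means=[-sigma_D / 2.0, 0.0, sigma_D / 2.0],
            mu_prior_variances=[0.2, 0.1, 0.2],
            precision_shapes=np.full(3, 1.0 / sigma_D**2),
            precision_rates=_ones(3),
            dirichlet_A=np.ones((3, 3)),
            dirichlet_pi=[1.0, 9.0, 1.0],
            order_means=True,
        )

    return Preset(
        name="gbm3",
        n_states=3,
        state_to_class={0: "loss", 1: "neutral", 2: "gain"},
        _hyper_factory=hyper,
        needs_sigma_D=True,
    )


def _snp3() -> Preset:
    def hyper():
        l = 5000.0
        diag = np.array([0.95, 0.99, 0.95])  # high self-transition weight, neutral highest
        A = np.empty((3, 3))
        for i in range(3):
            A[i] = (1.0 - diag[i]) / 2.0
            A[i, i] = diag[i]
        return Hyperparameters(
            mu_prior_means=[-0.66, 0.0, 0.54],
            mu_prior_variances=[0.001, 0.001, 0.001],
            precision_shapes=[12.0, 30.0, 25.0],
            precision_rates=[1.0, 1.0, 1.0],
            dirichlet_A=l * A,
            dirichlet_pi=[1.0, 9.0, 1.0],
            order_means=True,
        )

    return Preset(
        name="snp3",
        n_states=3,
        state_to_class={0: "loss", 1: "neutral", 2: "gain"},
        _hyper_factory=hyper,
    )


_PRESETS = {
    "two_state": _two_state,
    "cgh4_template": lambda: _cgh4([0.5, 0.001, 1.0, 1.0], [10.0, 100.0, 5.0, 5.0]),
    "cgh4_hbl2": lambda: _cgh4([0.2, 0.1, 0.2, 0.2], [15.0, 20.0, 10.0, 10.0]),
    "gbm3": _gbm3,
    "snp3": _snp3,
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> Preset:
    """Look up a published model configuration by name."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    p = factory()
    p.name = name
    return p
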
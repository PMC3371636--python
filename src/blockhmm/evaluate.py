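"""Segmentation metrics and call generation.

The evaluation convention treats copy-number calling as a two-class problem:
aberrant probes (loss or gain) are the positive class, neutral probes the
negative class.  ``recall = tp/(tp+fn)``, ``precision = tp/(tp+fp)`` and
``F1 = 2*recall*precision/(recall+precision)``; ratios with a zero
denominator are reported as NaN and flagged rather than coerced to 0.

The average posterior error between two per-position state posteriors is

``P_err = 1/(2T) sum_t sum_i |P_a(q_t = i) - P_b(q_t = i)|``

i.e. total-variation distance averaged over positions, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gibbs import ChainResult
from .hmm import StatePath

__all__ = [
    "CallSet",
    "TwoClassMetrics",
    "average_posterior_error",
    "two_class_metrics",
    "confusion_matrix3",
    "viterbi_mismatch",
    "calls_from_chain",
    "calls_from_labels",
]

CLASSES = ("loss", "neutral", "gain")


@dataclass
class CallSet:
    """Per-probe class labels plus the merged equal-class segments."""

    chromosomes: list
    classes: dict  # chrom -> array of str labels
    posterior: dict | None = None  # chrom -> per-probe mean posterior of the call

    def __post_init__(self) -> None:
        self.classes = {c: np.asarray(v, dtype=str) for c, v in self.classes.items()}

    def segments(self):
        """Maximal runs of equal class, 0-based half-open (chrom, start, end, class, mean_post)."""
        segs = []
        for c in self.chromosomes:
            lab = self.classes[c]
            post = self.posterior[c] if self.posterior is not None else None
            start = 0
            for k in range(1, len(lab) + 1):
                if k == len(lab) or lab[k] != lab[start]:
                    mp = float(np.mean(post[start:k])) if post is not None else np.nan
                    segs.append((c, start, k, str(lab[start]), mp))
                    start = k
        return segs

    def concat(self) -> np.ndarray:
        return np.concatenate([self.classes[c] for c in self.chromosomes])


def calls_from_labels(labels: dict, chromosomes=None) -> CallSet:
    """Wrap per-chromosome truth label arrays as a CallSet."""
    chroms = list(chromosomes) if chromosomes is not None else list(labels)
    return CallSet(chroms, {c: labels[c] for c in chroms})


def average_posterior_error(P_est, P_ref) -> float:
    """Positionwise total-variation distance averaged over positions.

    Accepts (T, N) arrays or per-chromosome dicts of them; symmetric in its
    arguments, in [0, 1].
    """
    if isinstance(P_est, dict):
        a = np.vstack([P_est[c] for c in P_est])
        b = np.vstack([P_ref[c] for c in P_est])
    else:
        a, b = np.asarray(P_est, float), np.asarray(P_ref, float)
    if a.shape != b.shape:
        raise ValueError("posterior arrays must have matching shapes")
    return float(np.abs(a - b).sum() / (2.0 * a.shape[0]))


@dataclass
class TwoClassMetrics:
    f1: float
    recall: float
    precision: float
    tp: int
    fp: int
    tn: int
    fn: int
    undefined: tuple = ()  # names of ratios with zero denominators


def two_class_metrics(calls: CallSet, truth: CallSet) -> TwoClassMetrics:
    """Aberrant-vs-neutral F1/recall/precision against truth labels."""
    a = calls.concat()
    b = truth.concat()
    if a.shape != b.shape:
        raise ValueError("call and truth probe sets differ")
    pos_call = a != "neutral"
    pos_true = b != "neutral"
    tp = int(np.sum(pos_call & pos_true))
    fp = int(np.sum(pos_call & ~pos_true))
    fn = int(np.sum(~pos_call & pos_true))
    tn = int(np.sum(~pos_call & ~pos_true))
    undefined = []
    recall = tp / (tp + fn) if tp + fn else np.nan
    if tp + fn == 0:
        undefined.append("recall")
    precision = tp / (tp + fp) if tp + fp else np.nan
    if tp + fp == 0:
        undefined.append("precision")
    if np.isnan(recall) or np.isnan(precision) or recall + precision == 0:
        f1 = np.nan
        undefined.append("f1")
    else:
        f1 = 2.0 * recall * precision / (recall + precision)
    return TwoClassMetrics(f1, recall, precision, tp, fp, tn, fn, tuple(undefined))


def confusion_matrix3(calls: CallSet, truth: CallSet) -> np.ndarray:
    """Row-normalized 3x3 confusion matrix, rows indexed by truth class.

    Rows/columns are ordered (loss, neutral, gain); a truth class absent
    from the data yields a NaN row.
    """
    a = calls.concat()
    b = truth.concat()
    if a.shape != b.shape:
        raise ValueError("call and truth probe sets differ")
    M = np.zeros((3, 3))
    for i, ct in enumerate(CLASSES):
        mask = b == ct
        if not mask.any():
            M[i] = np.nan
            continue
        for j, cc in enumerate(CLASSES):
            M[i, j] = np.sum(a[mask] == cc) / mask.sum()
    return M


def viterbi_mismatch(path_a: StatePath, path_b: StatePath) -> int:
    """Hamming distance between two state paths over all chromosomes."""
    if set(path_a.states) != set(path_b.states):
        raise ValueError("paths cover different chromosomes")
    total = 0
    for c in path_a.states:
        qa, qb = path_a.states[c], path_b.states[c]
        if len(qa) != len(qb):
            raise ValueError(f"path lengths differ on {c}")
        total += int(np.sum(qa != qb))
    return total


def calls_from_chain(chain: ChainResult, state_to_class: dict) -> CallSet:
    """Per-probe class calls from the window-averaged posterior marginals.

    Each probe gets the class with the largest summed posterior mass of its
    mapped states; exact ties break toward "neutral".
    """
    chroms = list(chain.posterior_mean_marginals)
    classes = {}
    posterior = {}
    n_states = chain.theta_final.n_states
    weight = np.zeros((n_states, 3))
    for s, cls in state_to_class.items():
        weight[s, CLASSES.index(cls)] = 1.0
    neutral_idx = CLASSES.index("neutral")
    for c in chroms:
        mass = chain.posterior_mean_marginals[c] @ weight  # (T, 3)
        best = np.argmax(mass, axis=1)
        top = mass[np.arange(len(best)), best]
        ties_neutral = np.isclose(mass[:, neutral_idx], top, rtol=0, atol=0)
        best = np.where(ties_neutral, neutral_idx, best)
        classes[c] = np.array([CLASSES[k] for k in best])
        posterior[c] = top
    return CallSet(chroms, classes, posterior)
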
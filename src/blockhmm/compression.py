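"""kd-tree style compression of observation sequences into moment blocks.

An observation sequence is recursively partitioned, alternating between the
value dimension (split the segment into maximal consecutive runs lying
entirely on one side of the segment's median value) and the index dimension
(split at the largest adjacent value gap).  A segment is emitted as a block
-- storing its count, first and second moment -- once its value range falls
below a width threshold that starts at ``w`` and shrinks by a factor
``delta`` per level, or once it contains a single observation.

A follow-up merge pass combines adjacent blocks whose means are within ``w``
(and block triples whose outer means are within ``w`` when the inner block
holds a single observation), which absorbs isolated outliers.

The compression ratio ``gamma = T'/T`` drops roughly exponentially in ``w``;
the knee of that curve, found with the L-method (two least-squares lines,
split minimizing the count-weighted total RMSE), is the recommended width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import ObservationTrack

__all__ = [
    "Block",
    "CompressedTrack",
    "KneeResult",
    "kd_compress",
    "merge_blocks",
    "compress_track",
    "compression_curve",
    "default_width_grid",
    "select_width_lmethod",
    "plot_compression_curve",
]

DEFAULT_DELTA = 1.25  # per-level shrink factor of the stop width


@dataclass
class Block:
    """A run of ``count`` consecutive observations summarized by moments.

    ``sum1``/``sum2`` are the raw first/second moment sums; ``start``/``end``
    index the original sequence (0-based, half-open).
    """

    count: int
    sum1: float
    sum2: float
    start: int
    end: int

    @property
    def mean(self) -> float:
        return self.sum1 / self.count

    @property
    def variance(self) -> float:
        return max(self.sum2 / self.count - self.mean**2, 0.0)

    def merged(self, other: "Block") -> "Block":
        return Block(
            count=self.count + other.count,
            sum1=self.sum1 + other.sum1,
            sum2=self.sum2 + other.sum2,
            start=self.start,
            end=other.end,
        )


@dataclass
class CompressedTrack:
    """Per-chromosome ordered block lists tiling the original track."""

    chromosomes: list
    blocks: dict
    total_obs: int
    width_used: float

    @property
    def total_blocks(self) -> int:
        return sum(len(self.blocks[c]) for c in self.chromosomes)

    @property
    def gamma(self) -> float:
        return self.total_blocks / self.total_obs


def _emit(obs: np.ndarray, start: int, end: int) -> Block:
    seg = obs[start:end]
    return Block(
        count=end - start,
        sum1=float(np.sum(seg)),
        sum2=float(np.sum(seg * seg)),
        start=start,
        end=end,
    )


def kd_compress(obs, w: float, delta: float = DEFAULT_DELTA, return_depth: bool = False):
    """Compress a sequence into ordered blocks by the alternating recursion.

    Splits on the value dimension use the lower median; observations equal to
    the median attach to the run in progress (greedy left to right).  Splits
    on the index dimension use the leftmost largest gap.  The stop threshold
    at recursion level ``L`` (root level 1) is ``w / delta**(L-1)``; a
    zero-range (constant) segment always stops, as does a single observation.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observation sequence must be nonempty and 1-D")
    if w < 0:
        raise ValueError("width must be nonnegative")
    blocks: list[Block] = []
    max_depth = 0
    # stack of (start, end, level, dim, depth); children pushed reversed to
    # keep left-to-right emission order
    stack = [(0, len(obs), 1, 1, 1)]
    while stack:
        start, end, level, dim, depth = stack.pop()
        max_depth = max(max_depth, depth)
        seg = obs[start:end]
        if end - start == 1:
            blocks.append(_emit(obs, start, end))
            continue
        lo = seg.min()
        hi = seg.max()
        rng = hi - lo
        if rng == 0.0 or rng < w / delta ** (level - 1):
            blocks.append(_emit(obs, start, end))
            continue
        if dim == 1:
            m = np.sort(seg)[(len(seg) - 1) // 2]  # lower median
            side = np.sign(seg - m)
            nz = np.nonzero(side)[0]
            # run boundaries: where the (nonzero) side flips
            flips = nz[1:][side[nz[1:]] != side[nz[:-1]]]
            bounds = [0, *flips.tolist(), end - start]
            for i in range(len(bounds) - 2, -1, -1):
                stack.append((start + bounds[i], start + bounds[i + 1], level + 1, 0, depth + 1))
        else:
            gap_idx = int(np.argmax(np.abs(np.diff(seg))))  # leftmost largest gap
            cut = start + gap_idx + 1
            stack.append((cut, end, level, 1, depth + 1))
            stack.append((start, cut, level, 1, depth + 1))
    if return_depth:
        return blocks, max_depth
    return blocks


def merge_blocks(blocks: list, w: float) -> list:
    """One left-to-right merge pass over an ordered block list.

    The pass operates on the evolving list: a merged block takes part in
    later comparisons with its pooled mean.  At each incoming block the pair
    rule (previous block's mean within ``w``) is checked before the triple
    rule (previous block is a lone singleton and the mean of the block
    before it is within ``w`` of the incoming one).  Moments add exactly;
    single pass, no iteration to a fixpoint.
    """
    out: list[Block] = []
    for b in blocks:
        if out and abs(out[-1].mean - b.mean) < w:
            out[-1] = out[-1].merged(b)
        elif len(out) >= 2 and out[-1].count == 1 and abs(out[-2].mean - b.mean) < w:
            out[-2] = out[-2].merged(out[-1]).merged(b)
            out.pop()
        else:
            out.append(b)
    return out


def compress_track(
    track: ObservationTrack, w: float, delta: float = DEFAULT_DELTA, merge: bool = True
) -> CompressedTrack:
    """kd-compress plus merge pass, applied per chromosome."""
    blocks = {}
    for c in track.chromosomes:
        bl = kd_compress(track.observations[c], w, delta)
        if merge:
            bl = merge_blocks(bl, w)
        blocks[c] = bl
    return CompressedTrack(
        chromosomes=list(track.chromosomes),
        blocks=blocks,
        total_obs=track.total_length,
        width_used=w,
    )


def default_width_grid(sigma_D: float, max_multiple: float = 4.0, step: float = 0.25) -> np.ndarray:
    """The conventional width grid 0.25*sigma_D, 0.5*sigma_D, ..., 4*sigma_D."""
    mult = np.arange(step, max_multiple + step / 2, step)
    return mult * sigma_D


def compression_curve(track: ObservationTrack, widths, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """(w, gamma) pairs for a grid of widths, gamma pooled over chromosomes."""
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0 or np.any(widths < 0):
        raise ValueError("need a nonempty grid of nonnegative widths")
    out = np.empty((len(widths), 2))
    for k, w in enumerate(widths):
        ct = compress_track(track, float(w), delta=delta)
        out[k] = (w, ct.gamma)
    return out


@dataclass
class KneeResult:
    """L-method knee: the selected width and the split that produced it."""

    width: float
    split_index: int
    low_confidence: bool
    total_rmse: float

    def __float__(self) -> float:
        return self.width


def _line_rmse(x: np.ndarray, y: np.ndarray) -> float:
    coef = np.polyfit(x, y, 1)
    res = y - np.polyval(coef, x)
    return float(np.sqrt(np.mean(res**2)))


def select_width_lmethod(curve) -> KneeResult:
    """Find the knee of a (w, gamma) curve with the L-method.

    For every split index the left and right parts (sharing the split point)
    are fitted with least-squares lines; the split minimizing the
    count-weighted total RMSE wins (ties go to the larger split, so an exact
    piecewise-linear corner is returned exactly).  A split adjacent to either
    boundary is flagged ``low_confidence`` -- the curve then looks like a
    single straight line.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or len(curve) < 4:
        raise ValueError("need at least 4 (w, gamma) points")
    order = np.argsort(curve[:, 0])
    x, y = curve[order, 0], curve[order, 1]
    K = len(x)
    best = None
    for c in range(1, K - 1):  # both sides keep >= 2 points; split point shared
        n_l, n_r = c + 1, K - c
        rmse = (n_l * _line_rmse(x[: c + 1], y[: c + 1]) + n_r * _line_rmse(x[c:], y[c:])) / (
            n_l + n_r
        )
        if best is None or rmse <= best[1]:
            best = (c, rmse)
    c, rmse = best
    # degenerate curve: a single line fits (almost) as well as two, or the
    # split hugs a boundary -- the "knee" is then not trustworthy
    full_rmse = _line_rmse(x, y)
    low_confidence = c == 1 or c == K - 2 or full_rmse <= 2.0 * rmse + 1e-12
    return KneeResult(
        width=float(x[c]),
        split_index=c,
        low_confidence=low_confidence,
        total_rmse=rmse,
    )


def plot_compression_curve(curve, knee: KneeResult | None = None, ax=None):
    """Minimal gamma-vs-width figure with the selected knee marked."""
    import matplotlib.pyplot as plt

    curve = np.asarray(curve, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve[:, 0], curve[:, 1], "o-", label="compression ratio")
    if knee is not None:
        ax.axvline(knee.width, linestyle="--", color="gray", label=f"knee w={knee.width:.3g}")
    ax.set_xlabel("width w")
    ax.set_ylabel(r"$\gamma = T'/T$")
    ax.legend()
    return ax
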
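"""File formats: probe tables, calls, posteriors, chain dumps, configs.

Probe tables are tab-delimited with a header ``chrom, position, value`` (the
position column is optional).  Calls are written BED-like with 0-based
half-open coordinates in probe index space.  Hyperparameter configs are YAML
mappings mirroring the :class:`~blockhmm.gibbs.Hyperparameters` fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .compression import CompressedTrack
from .evaluate import CallSet
from .gibbs import ChainResult, Hyperparameters
from .hmm import ObservationTrack

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "write_calls",
    "read_calls",
    "write_posteriors",
    "write_blocks",
    "write_chain",
    "read_hyperparameters",
    "write_hyperparameters",
]


class ProbeTableError(ValueError):
    pass


def read_probe_table(path) -> ObservationTrack:
    """Read a tab-delimited (chrom, [position,] value) table."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "chrom" not in cols or "value" not in cols:
        raise ProbeTableError(f"{path}: need 'chrom' and 'value' columns, got {list(df.columns)}")
    values = pd.to_numeric(df[cols["value"]], errors="coerce")
    bad = values.index[~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))]
    if len(bad):
        raise ProbeTableError(f"{path}: malformed value on line {bad[0] + 2}")  # +2: header, 1-based
    chroms = list(dict.fromkeys(df[cols["chrom"]].astype(str)))
    obs = {c: values[df[cols["chrom"]].astype(str) == c].to_numpy(dtype=float) for c in chroms}
    positions = None
    if "position" in cols:
        pos = pd.to_numeric(df[cols["position"]], errors="coerce")
        if not pos.isna().any():
            positions = {
                c: pos[df[cols["chrom"]].astype(str) == c].to_numpy(dtype=np.int64)
                for c in chroms
            }
    return ObservationTrack(chroms, obs, positions)


def write_probe_table(track: ObservationTrack, path) -> None:
    rows = []
    for c in track.chromosomes:
        o = track.observations[c]
        pos = (
            track.positions[c]
            if track.positions is not None
            else np.arange(len(o), dtype=np.int64)
        )
        rows.append(pd.DataFrame({"chrom": c, "position": pos, "value": o}))
    pd.concat(rows).to_csv(path, sep="\t", index=False)


def write_calls(calls: CallSet, path) -> None:
    """BED-like calls: chrom, start, end, class, mean posterior of the call."""
    segs = calls.segments()
    df = pd.DataFrame(segs, columns=["chrom", "start", "end", "class", "mean_posterior"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_posteriors(chain: ChainResult, path, track: ObservationTrack | None = None) -> None:
    """Per-probe posterior table: one row per probe, one column per state."""
    rows = []
    for c, g in chain.posterior_mean_marginals.items():
        df = pd.DataFrame(g, columns=[f"state_{i + 1}" for i in range(g.shape[1])])
        df.insert(0, "index", np.arange(len(df)))
        df.insert(0, "chrom", c)
        rows.append(df)
    pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_blocks(compressed: CompressedTrack, path) -> None:
    rows = []
    for c in compressed.chromosomes:
        for b in compressed.blocks[c]:
            rows.append((c, b.start, b.end, b.count, b.mean, b.variance))
    pd.DataFrame(
        rows, columns=["chrom", "start_index", "end_index", "count", "mean", "variance"]
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_chain(chain: ChainResult, path) -> None:
    """Line-delimited chain dump: iteration plus flattened theta."""
    rows = []
    for m, theta in enumerate(chain.draws, start=1):
        row = {"iteration": m}
        for i in range(theta.n_states):
            row[f"mu_{i + 1}"] = theta.means[i]
            row[f"var_{i + 1}"] = theta.variances[i]
            row[f"pi_{i + 1}"] = theta.pi[i]
            for j in range(theta.n_states):
                row[f"a_{i + 1}{j + 1}"] = theta.A[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


_HYPER_KEYS = [
    "mu_prior_means",
    "mu_prior_variances",
    "precision_shapes",
    "precision_rates",
    "dirichlet_A",
    "dirichlet_pi",
]


def read_hyperparameters(path) -> Hyperparameters:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    missing = [k for k in _HYPER_KEYS if k not in cfg]
    if missing:
        raise ValueError(f"{path}: missing hyperparameter keys {missing}")
    return Hyperparameters(
        **{k: np.asarray(cfg[k], dtype=float) for k in _HYPER_KEYS},
        order_means=bool(cfg.get("order_means", True)),
    )


def write_hyperparameters(hyper: Hyperparameters, path) -> None:
    cfg = {k: np.asarray(getattr(hyper, k)).tolist() for k in _HYPER_KEYS}
    cfg["order_means"] = bool(hyper.order_means)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
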
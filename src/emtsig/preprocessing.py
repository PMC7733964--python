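"""Snapshot preprocessing: viability filtering, gating, scaling, subsampling.

Turns raw snapshot tables into modeling-ready data: dead/apoptotic cells are
removed by a cleaved-PARP count cutoff, phenotypes are gated on the
E-cadherin/vimentin axes, phospho channels are linearly rescaled so the
phosphorylated form cannot exceed its total, cells are subsampled across
replicates per time point, and log transforms are applied for the downstream
statistical analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import load_default_config, stable_seed
from .data import Snapshot, SnapshotDataset

__all__ = [
    "GateSpec",
    "filter_dead",
    "gate_phenotype",
    "scale_phospho_to_total",
    "subsample_across_replicates",
    "log_transform",
    "preprocess_dataset",
]

_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class GateSpec:
    """A two-channel rectangular gate: high marker above, low marker below."""

    marker_high: tuple[str, float]   # (channel, threshold): keep >= threshold
    marker_low: tuple[str, float]    # (channel, threshold): keep <  threshold
    label: str = "ungated"

    def __post_init__(self) -> None:
        if self.marker_high[1] <= 0 or self.marker_low[1] <= 0:
            raise ValueError("gate thresholds must be positive")

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any] | None = None,
                    label: str = "epithelial") -> "GateSpec":
        if cfg is None:
            cfg = load_default_config()
        g = cfg["preprocessing"]["gates"][label]
        return cls(
            marker_high=(g["marker_high"][0], float(g["marker_high"][1])),
            marker_low=(g["marker_low"][0], float(g["marker_low"][1])),
            label=label,
        )


def filter_dead(s: Snapshot, threshold: float = 20.0, channel: str = "cPARP") -> Snapshot:
    """Remove dead/apoptotic cells: retain cells with ``channel <= threshold`` counts."""
    if channel not in s.data.columns:
        raise KeyError(f"viability channel {channel!r} not present in snapshot")
    keep = s.data[channel].to_numpy(dtype=float) <= threshold
    if not keep.any():
        warnings.warn(
            f"all {s.n_cells} cells exceed {channel} > {threshold}; snapshot is empty",
            stacklevel=2,
        )
    return s.with_data(s.data.loc[keep].reset_index(drop=True))


def gate_phenotype(s: Snapshot, gate: GateSpec) -> Snapshot:
    """Select cells inside a marker-high/marker-low rectangular gate."""
    ch_hi, thr_hi = gate.marker_high
    ch_lo, thr_lo = gate.marker_low
    for ch in (ch_hi, ch_lo):
        if ch not in s.data.columns:
            raise KeyError(f"gate channel {ch!r} not present in snapshot")
    vals_hi = s.data[ch_hi].to_numpy(dtype=float)
    vals_lo = s.data[ch_lo].to_numpy(dtype=float)
    keep = (vals_hi >= thr_hi) & (vals_lo < thr_lo)
    return s.with_data(s.data.loc[keep].reset_index(drop=True), phenotype=gate.label)


def scale_phospho_to_total(
    d: SnapshotDataset,
    panel: Mapping[str, Any] | None = None,
    quantile: float = 0.999,
) -> tuple[SnapshotDataset, pd.DataFrame]:
    """Linearly rescale phospho channels so phospho <= total holds.

    For each phenotype and phospho channel, one global factor is chosen so the
    configured quantile of the pooled per-cell phospho/total ratio is <= 1
    (data already satisfying the constraint get factor 1); residual violating
    cells are clamped to just below their total.  Returns the rescaled dataset
    and a report of factors and clamp counts.
    """
    if panel is None:
        panel = load_default_config()["panel"]
    total_of: Mapping[str, str] = panel["totals"]
    phospho = list(panel["phospho"])

    phenotypes = sorted({s.phenotype for s in d})
    factors: dict[tuple[str, str], float] = {}
    rows = []
    for pheno in phenotypes:
        sub = d.select(phenotype=pheno)
        pooled = sub.pool()
        for p in phospho:
            tot = pooled[total_of[p]].to_numpy(dtype=float)
            if np.all(tot == 0):
                raise ValueError(f"total channel {total_of[p]!r} is entirely zero")
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = pooled[p].to_numpy(dtype=float) / tot
            q = float(np.nanquantile(ratio, quantile))
            factors[(pheno, p)] = min(1.0, 1.0 / q) if q > 0 else 1.0

    n_clamped = {k: 0 for k in factors}

    def rescale(s: Snapshot) -> Snapshot:
        df = s.data.copy()
        for p in phospho:
            f = factors[(s.phenotype, p)]
            vals = df[p].to_numpy(dtype=float) * f
            tot = df[total_of[p]].to_numpy(dtype=float)
            cap = (1.0 - _CLAMP_EPS) * tot
            over = vals > cap
            n_clamped[(s.phenotype, p)] += int(over.sum())
            df[p] = np.where(over, cap, vals)
        return s.with_data(df)

    scaled = d.map(rescale)
    for (pheno, p), f in factors.items():
        rows.append(
            {"phenotype": pheno, "channel": p, "factor": f,
             "n_clamped": n_clamped[(pheno, p)]}
        )
    if len(phenotypes) == 1:
        # single-phenotype dataset: record the factors as part of its
        # observation model so model-vs-data comparisons can apply them
        scaled.scale_factors = {p: factors[(phenotypes[0], p)] for p in phospho}
    return scaled, pd.DataFrame(rows)


def subsample_across_replicates(
    d: SnapshotDataset, n: int, seed: int = 0
) -> SnapshotDataset:
    """Draw ``n`` cells per (condition, time) across replicates.

    The draw is without replacement, allocated to replicates proportionally to
    their cell counts (largest-remainder rounding), and reproducible under
    ``seed``.  If fewer than ``n`` cells are pooled, all are kept with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    keys = sorted({(s.condition, s.time) for s in d})
    for condition, t in keys:
        group = d.select(condition=condition, time=t)
        counts = np.array([s.n_cells for s in group], dtype=int)
        total = int(counts.sum())
        if total <= n:
            if total < n:
                warnings.warn(
                    f"requested {n} cells at {condition} t={t} but only {total} "
                    "available; keeping all",
                    stacklevel=2,
                )
            out.extend(group)
            continue
        # proportional allocation with largest-remainder rounding
        quota = n * counts / total
        alloc = np.floor(quota).astype(int)
        remainder = quota - alloc
        short = n - int(alloc.sum())
        for i in np.argsort(-remainder, kind="stable")[:short]:
            alloc[i] += 1
        for snap, k in zip(group, alloc):
            rng = np.random.default_rng(stable_seed(seed, condition, t, snap.replicate))
            idx = np.sort(rng.choice(snap.n_cells, size=int(k), replace=False))
            out.append(snap.with_data(snap.data.iloc[idx].reset_index(drop=True)))
    return SnapshotDataset(out, scale_factors=d.scale_factors)


def log_transform(s: Snapshot, kind: str = "log1p", offset: float = 1.0) -> Snapshot:
    """Elementwise log transform: natural log(1+x) or log2(x + offset)."""
    vals = s.data.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("log transform requires non-negative data")
    if kind == "log1p":
        out = np.log1p(vals)
    elif kind == "log2":
        out = np.log2(vals + offset)
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    return s.with_data(pd.DataFrame(out, columns=s.data.columns))


def preprocess_dataset(
    d: SnapshotDataset,
    phenotype: str,
    cfg: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> tuple[SnapshotDataset, pd.DataFrame]:
    """Standard pipeline: dead-cell filter -> gate -> scale -> subsample.

    Returns the modeling-ready dataset (still on the linear intensity scale)
    and the scaling report.  Log transforms are applied downstream by the
    network and cost stages, which need different bases.
    """
    if cfg is None:
        cfg = load_default_config()
    pp = cfg["preprocessing"]
    gate = GateSpec.from_config(cfg, phenotype)
    filtered = d.map(
        lambda s: filter_dead(s, pp["dead_threshold_counts"], cfg["panel"]["viability"])
    )
    gated = filtered.map(lambda s: gate_phenotype(s, gate))
    scaled, report = scale_phospho_to_total(gated, cfg["panel"], pp["scale_quantile"])
    subsampled = subsample_across_replicates(scaled, pp["subsample_n"], seed=seed)
    return subsampled, report
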
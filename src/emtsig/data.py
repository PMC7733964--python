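"""Snapshot containers: cells x channels tables indexed by time/replicate/condition.

Mass-cytometry sampling is destructive, so a time course is a collection of
independent snapshots, each holding different cells.  ``Snapshot`` wraps one
cells x channels table with its acquisition metadata; ``SnapshotDataset`` is
the ordered collection that every analysis stage exchanges.  On disk a dataset
is one CSV per snapshot plus a tab-separated ``manifest.tsv`` recording time,
replicate, condition, phenotype and the generating seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Snapshot", "SnapshotDataset"]

STIMULATED = "stimulated"
CONTROL = "control"


@dataclass
class Snapshot:
    """One cells x channels intensity table at a single sampling time."""

    data: pd.DataFrame
    time: float
    replicate: int
    condition: str = STIMULATED
    phenotype: str = "ungated"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate channel names: {dupes}")
        # empty snapshots are representable (e.g. a fully apoptotic sample
        # after viability filtering); operations needing cells raise instead
        if self.condition not in (STIMULATED, CONTROL):
            raise ValueError(f"condition must be stimulated|control, got {self.condition!r}")
        vals = self.data.to_numpy(dtype=float, copy=False)
        if np.any(vals < 0):
            raise ValueError("negative intensities are not allowed in a snapshot")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def with_data(self, data: pd.DataFrame, **meta) -> "Snapshot":
        return replace(self, data=data, **meta)


@dataclass
class SnapshotDataset:
    """An ordered collection of snapshots (one phenotype's full time course).

    ``scale_factors`` records the per-channel linear factors applied by the
    phospho-to-total scaling step; they are part of the observation model, so
    downstream model-vs-data comparisons apply them to simulated observables
    as well.
    """

    snapshots: list[Snapshot] = field(default_factory=list)
    scale_factors: dict[str, float] | None = None

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    def __getitem__(self, i: int) -> Snapshot:
        return self.snapshots[i]

    def append(self, snap: Snapshot) -> None:
        self.snapshots.append(snap)

    # -- selection -----------------------------------------------------------
    def select(
        self,
        *,
        time: float | None = None,
        replicate: int | None = None,
        condition: str | None = None,
        phenotype: str | None = None,
        predicate: Callable[[Snapshot], bool] | None = None,
    ) -> "SnapshotDataset":
        out = []
        for s in self.snapshots:
            if time is not None and s.time != time:
                continue
            if replicate is not None and s.replicate != replicate:
                continue
            if condition is not None and s.condition != condition:
                continue
            if phenotype is not None and s.phenotype != phenotype:
                continue
            if predicate is not None and not predicate(s):
                continue
            out.append(s)
        return SnapshotDataset(out, scale_factors=self.scale_factors)

    def baseline(self) -> "SnapshotDataset":
        """Pre-stimulation snapshots (stimulated condition, t <= 0)."""
        return self.select(condition=STIMULATED, predicate=lambda s: s.time <= 0)

    def stimulated_times(self) -> list[float]:
        return sorted({s.time for s in self.snapshots if s.condition == STIMULATED and s.time > 0})

    def times(self) -> list[float]:
        return sorted({s.time for s in self.snapshots})

    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.snapshots})

    def pool(self, channels: Sequence[str] | None = None) -> pd.DataFrame:
        """All cells of all snapshots stacked into one table."""
        if not self.snapshots:
            raise ValueError("cannot pool an empty dataset")
        frames = [s.data if channels is None else s.data[list(channels)] for s in self.snapshots]
        return pd.concat(frames, ignore_index=True)

    def map(self, fn: Callable[[Snapshot], Snapshot]) -> "SnapshotDataset":
        return SnapshotDataset(
            [fn(s) for s in self.snapshots], scale_factors=self.scale_factors
        )

    @property
    def total_cells(self) -> int:
        return sum(s.n_cells for s in self.snapshots)

    # -- on-disk layout: one CSV per snapshot + manifest.tsv -------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, s in enumerate(self.snapshots):
            fname = (
                f"snapshot_{i:03d}_{s.phenotype}_{s.condition}"
                f"_t{s.time:+05.0f}_r{s.replicate}.csv"
            )
            s.data.to_csv(directory / fname, index=False, float_format="%.6g")
            rows.append(
                {
                    "file": fname,
                    "time": s.time,
                    "replicate": s.replicate,
                    "condition": s.condition,
                    "phenotype": s.phenotype,
                    "seed": "" if s.seed is None else s.seed,
                }
            )
        pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)
        if self.scale_factors is not None:
            pd.Series(self.scale_factors, name="factor").rename_axis("channel").to_csv(
                directory / "scale_factors.tsv", sep="\t"
            )

    @classmethod
    def load(cls, directory: str | Path) -> "SnapshotDataset":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
        snaps = []
        for row in manifest.itertuples(index=False):
            seed = None if pd.isna(row.seed) or row.seed == "" else int(row.seed)
            snaps.append(
                Snapshot(
                    data=pd.read_csv(directory / row.file),
                    time=float(row.time),
                    replicate=int(row.replicate),
                    condition=str(row.condition),
                    phenotype=str(row.phenotype),
                    seed=seed,
                )
            )
        factors = None
        fpath = directory / "scale_factors.tsv"
        if fpath.exists():
            table = pd.read_csv(fpath, sep="\t")
            factors = dict(zip(table["channel"], table["factor"].astype(float)))
        return cls(snaps, scale_factors=factors)
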
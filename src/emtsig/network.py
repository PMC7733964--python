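"""Partial-correlation network inference on single-cell snapshot data.

For each pair of phosphoproteins (X, Y) the full-order partial correlation
rho_XY.Z — the Pearson correlation of the residuals of X and Y after linear
regression on all remaining panel variables Z — measures their association
with confounding through the rest of the panel removed.  Pairs with
|rho| >= a threshold (default 0.1) are called as network edges; values are
Fisher z-transformed for display and comparison, rows/columns are ordered by
single-linkage hierarchical clustering, and a per-timepoint variant tracks
how edge strengths evolve after stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .data import Snapshot, SnapshotDataset

__all__ = [
    "PartialCorrNetwork",
    "fisher_z",
    "partial_correlation",
    "partial_correlation_matrix",
    "edge_dynamics_by_timepoint",
    "cluster_order",
]


def fisher_z(rho: float) -> float:
    """Variance-stabilizing Fisher transform, atanh(rho); requires |rho| < 1."""
    if abs(rho) >= 1.0:
        raise ValueError(f"Fisher z-transform undefined for |rho| >= 1 (got {rho})")
    return float(np.arctanh(rho))


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``v`` on ``[1, Z]``."""
    design = np.column_stack([np.ones(len(v)), Z]) if Z.size else np.ones((len(v), 1))
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "conditioning set is rank deficient; dependent columns contribute "
            "nothing to the regression",
            stacklevel=3,
        )
    return v - design @ coef


def partial_correlation(
    x: Sequence[float], y: Sequence[float], Z: np.ndarray | None = None
) -> float:
    """rho_XY.Z: correlation of the residuals of x and y regressed on Z.

    ``Z`` is an (n, k) matrix of conditioning variables (or None/empty for the
    plain Pearson correlation).  An intercept is always included.  If either
    residual has zero variance the value is undefined and NaN is returned with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.empty((len(x), 0)) if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(x):
        Z = Z.T
    if len(x) != len(y) or Z.shape[0] != len(x):
        raise ValueError("x, y and Z must have equal numbers of observations")
    if len(x) < Z.shape[1] + 3:
        raise ValueError(
            f"need at least |Z| + 3 = {Z.shape[1] + 3} observations, got {len(x)}"
        )
    ex = _residualize(x, Z)
    ey = _residualize(y, Z)
    sx = float(ex @ ex)
    sy = float(ey @ ey)
    # residuals from an exactly collinear variable are pure rounding noise
    tol_x = max(float(x @ x), 1.0) * 1e-24
    tol_y = max(float(y @ y), 1.0) * 1e-24
    if sx <= tol_x or sy <= tol_y:
        warnings.warn("zero residual variance: partial correlation undefined", stacklevel=2)
        return float("nan")
    return float((ex @ ey) / np.sqrt(sx * sy))


@dataclass
class PartialCorrNetwork:
    """Full-order partial-correlation matrix with thresholded edge calls."""

    variables: list[str]
    rho: np.ndarray
    threshold: float
    replicate_sd: np.ndarray | None = None
    z: np.ndarray = field(init=False)
    edges: list[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        p = len(self.variables)
        if self.rho.shape != (p, p):
            raise ValueError("rho must be square over the variable list")
        if not np.allclose(self.rho, self.rho.T, equal_nan=True):
            raise ValueError("rho must be symmetric")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.arctanh(np.clip(self.rho, -1.0, 1.0))
        np.fill_diagonal(z, 0.0)  # display convention; diagonal rho is 1
        self.z = z
        self.edges = [
            (self.variables[i], self.variables[j])
            for i in range(p)
            for j in range(i + 1, p)
            if np.abs(self.rho[i, j]) >= self.threshold
        ]

    def edge_table(self) -> pd.DataFrame:
        """All pairs with rho, Fisher z and the edge call."""
        p = len(self.variables)
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "var1": self.variables[i],
                        "var2": self.variables[j],
                        "rho": self.rho[i, j],
                        "z": self.z[i, j],
                        "passes_threshold": bool(abs(self.rho[i, j]) >= self.threshold),
                    }
                )
        return pd.DataFrame(rows)

    def save(self, directory: str | Path, prefix: str = "network") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.edge_table().to_csv(directory / f"{prefix}_edges.tsv", sep="\t", index=False)
        pd.DataFrame(self.rho, index=self.variables, columns=self.variables).to_csv(
            directory / f"{prefix}_rho.csv"
        )
        order = cluster_order(self)
        (directory / f"{prefix}_order.txt").write_text("\n".join(order) + "\n")


def partial_correlation_matrix(
    s: Snapshot | pd.DataFrame,
    variables: Sequence[str] | None = None,
    threshold: float = 0.1,
) -> PartialCorrNetwork:
    """Full-order partial correlations between all pairs of ``variables``.

    For each pair the conditioning set is every remaining variable in the
    list.  The input is expected on the log(1 + X) scale for intensity data.
    With two variables the conditioning set is empty and the result is the
    plain Pearson correlation.
    """
    df = s.data if isinstance(s, Snapshot) else s
    if variables is None:
        variables = list(df.columns)
    variables = list(variables)
    X = df[variables].to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"need at least p + 3 = {p + 3} cells, got {n}")
    rho = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            r = partial_correlation(X[:, i], X[:, j], X[:, others])
            rho[i, j] = rho[j, i] = r
    return PartialCorrNetwork(variables=variables, rho=rho, threshold=threshold)


def edge_dynamics_by_timepoint(
    d: SnapshotDataset,
    edges: Sequence[tuple[str, str]],
    variables: Sequence[str],
    transform=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-timepoint, per-replicate partial correlation of selected edges.

    Within each replicate's cells at each time point, rho for each listed edge
    is computed conditioning on all remaining ``variables``.  Returns the
    per-replicate table and a summary with across-replicate mean and sample
    standard deviation (SD is NaN when only one replicate is present).
    """
    variables = list(variables)
    rows = []
    for t in d.times():
        for rep in d.replicates():
            sub = d.select(time=t, replicate=rep)
            if len(sub) == 0:
                continue
            df = sub.pool(variables)
            if transform is not None:
                df = pd.DataFrame(transform(df.to_numpy()), columns=variables)
            X = df.to_numpy(dtype=float)
            for a, b in edges:
                i, j = variables.index(a), variables.index(b)
                others = [k for k in range(len(variables)) if k not in (i, j)]
                r = partial_correlation(X[:, i], X[:, j], X[:, others])
                rows.append(
                    {"edge": f"{a}-{b}", "time": t, "replicate": rep, "rho": r}
                )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["edge", "time"])["rho"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan)
        .reset_index()
    )
    return table, summary


def cluster_order(net: PartialCorrNetwork) -> list[str]:
    """Display ordering of variables by single-linkage hierarchical clustering.

    Euclidean distances between the variables' rows of the rho matrix; the
    dendrogram's leaf order is returned.  Ties break deterministically by
    input order (scipy's linkage is deterministic for fixed input).
    """
    if len(net.variables) < 2:
        return list(net.variables)
    if len(net.variables) == 2:
        return list(net.variables)
    Zl = linkage(net.rho, method="single", metric="euclidean")
    return [net.variables[i] for i in leaves_list(Zl)]
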
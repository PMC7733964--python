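"""Distribution-matching cost (maximum mean discrepancy) and parameter search.

Population parameters are estimated by minimizing the squared maximum mean
discrepancy (MMD, Gaussian kernel) between simulated and measured multivariate
phospho distributions, summed over post-stimulation time points:

    F(theta) = sum_t w_t * MMD^2( sim_t(theta), data_t )

where sim_t is the simulated ensemble (each cell initialized from a measured
baseline snapshot) and data_t the measured snapshot at time t, both on the
log2 scale.  The search is a two-stage procedure: a log-uniform global sample
over user-set ranges keeps the lowest-cost parameter sets, each is refined by
repeated rounds of Nelder-Mead simplex search (a round is re-initialized while
it still improves the cost by a set fraction), and the overall best set gets a
final refinement until the cost stabilizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .config import load_default_config, stable_seed
from .data import SnapshotDataset
from .model import (
    MEASURED_SPECIES,
    CellPopulation,
    SimulationError,
    derive_cell_rates,
    simulate_ensemble,
)
from .params import LINEAR_PARAMS, PARAM_NAMES, ParameterSet

__all__ = [
    "CostSpec",
    "FitSettings",
    "FitResult",
    "mmd2",
    "median_heuristic_bandwidth",
    "MMDCost",
    "baseline_cells",
    "default_search_ranges",
    "global_search",
    "local_refine",
    "fit",
]


# ---------------------------------------------------------------------------
# MMD primitives
# ---------------------------------------------------------------------------

def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    a2 = np.einsum("ij,ij->i", A, A)
    b2 = np.einsum("ij,ij->i", B, B)
    D = a2[:, None] + b2[None, :] - 2.0 * (A @ B.T)
    return np.maximum(D, 0.0)


def mmd2(
    A: np.ndarray,
    B: np.ndarray,
    bandwidth: float,
    estimator: str = "biased",
) -> float:
    """Squared MMD between samples A (n, d) and B (m, d).

    Gaussian kernel k(x, y) = exp(-||x - y||^2 / (2 * bandwidth^2)).  The
    biased V-statistic (kernel means including diagonals) is non-negative;
    the unbiased U-statistic excludes diagonal terms and can be negative.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("sample dimensions differ")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("both samples need at least 2 points")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if estimator not in ("biased", "unbiased"):
        raise ValueError(f"unknown estimator {estimator!r}")
    c = -0.5 / bandwidth**2
    Kaa = np.exp(c * _sq_dists(A, A))
    Kbb = np.exp(c * _sq_dists(B, B))
    Kab = np.exp(c * _sq_dists(A, B))
    n, m = len(A), len(B)
    if estimator == "biased":
        return float(Kaa.mean() + Kbb.mean() - 2.0 * Kab.mean())
    t_aa = (Kaa.sum() - n) / (n * (n - 1))
    t_bb = (Kbb.sum() - m) / (m * (m - 1))
    return float(t_aa + t_bb - 2.0 * Kab.mean())


def median_heuristic_bandwidth(
    pooled: np.ndarray, cap: int = 2000, seed: int = 0
) -> float:
    """Median pairwise Euclidean distance over a capped, seeded subsample."""
    X = np.atleast_2d(np.asarray(pooled, dtype=float))
    if len(X) < 2:
        raise ValueError("need at least 2 points for the median heuristic")
    if len(X) > cap:
        rng = np.random.default_rng(seed)
        X = X[np.sort(rng.choice(len(X), size=cap, replace=False))]
    med = float(np.median(pdist(X)))
    if med <= 0:
        raise ValueError("all points identical: bandwidth undefined")
    return med


# ---------------------------------------------------------------------------
# the cost functional
# ---------------------------------------------------------------------------

@dataclass
class CostSpec:
    """Settings of the distribution-matching cost."""

    channels: tuple[str, ...] = MEASURED_SPECIES
    transform: str = "log2"
    offset: float = 1.0
    bandwidth: float | None = None      # None: median heuristic, frozen per dataset
    bandwidth_cap: int = 2000
    estimator: str = "biased"
    time_weights: Mapping[float, float] | None = None  # None: uniform

    def apply_transform(self, X: np.ndarray) -> np.ndarray:
        if self.transform == "log2":
            return np.log2(np.maximum(X, 0.0) + self.offset)
        if self.transform == "log1p":
            return np.log1p(np.maximum(X, 0.0))
        if self.transform in (None, "none"):
            return X
        raise ValueError(f"unknown transform {self.transform!r}")


def baseline_cells(
    data: SnapshotDataset,
    n: int,
    seed: int = 0,
    panel: Mapping[str, Any] | None = None,
) -> CellPopulation:
    """Sample ``n`` model-initialization cells from the pooled pre-stimulation
    snapshots (t <= 0, stimulated arm), fixed for an entire optimization."""
    if panel is None:
        panel = load_default_config()["panel"]
    pool = data.baseline().pool()
    if len(pool) == 0:
        raise ValueError("dataset has no pre-stimulation cells to initialize from")
    rng = np.random.default_rng(seed)
    if len(pool) > n:
        idx = np.sort(rng.choice(len(pool), size=n, replace=False))
        pool = pool.iloc[idx].reset_index(drop=True)
    if data.scale_factors:
        # undo the observation-side linear scaling: the model state lives on
        # the latent intensity scale, observations on the rescaled one
        pool = pool.copy()
        for ch, f in data.scale_factors.items():
            if ch in pool.columns and f != 1.0:
                pool[ch] = pool[ch] / f
    return CellPopulation.from_dataframe(
        pool, phospho_channels=panel["phospho"], total_of=panel["totals"]
    )


class MMDCost:
    """F(theta): summed per-timepoint MMD^2 between simulation and data.

    The measured snapshots (pooled across replicates per stimulated time
    point), the kernel bandwidth (median heuristic on the pooled transformed
    data, frozen at construction) and the baseline cell ensemble are all fixed,
    so the cost is deterministic in ``theta``.
    """

    def __init__(
        self,
        data: SnapshotDataset,
        cells: CellPopulation,
        spec: CostSpec | None = None,
        seed: int = 0,
        robust: bool = False,
        max_rhs_evals: int | None = None,
        rtol: float = 1e-5,
    ) -> None:
        # robust=False keeps evaluations cheap during the global search by
        # failing fast (infinite cost) on stiff/pathological parameter draws;
        # robust=True engages the per-cell stiff fallback so extreme but valid
        # regimes (e.g. wide sensitivity-grid offsets) still evaluate finitely.
        # The cost integrates at rtol 1e-5: integration error (~1e-5 relative)
        # sits orders of magnitude below the MMD sampling floor.
        self.spec = spec or CostSpec()
        self.cells = cells
        self.robust = robust
        # the robust path still fails fast on the explicit integrator (well
        # above the ~500 steps tame solves need) before engaging the
        # per-cell stiff fallback
        self.max_rhs_evals = max_rhs_evals or (12_000 if robust else 10_000)
        self.rtol = rtol
        self.times = data.stimulated_times()
        if not self.times:
            raise ValueError("dataset has no post-stimulation time points")
        chans = list(self.spec.channels)
        self._chan_idx = np.array([MEASURED_SPECIES.index(c) for c in chans])
        # the data's phospho channels were linearly rescaled during
        # preprocessing; the same observation model applies to simulations
        factors = data.scale_factors or {}
        self._obs_factors = np.array([factors.get(c, 1.0) for c in chans])
        self._data: dict[float, np.ndarray] = {}
        for t in self.times:
            pooled = data.select(condition="stimulated", time=t).pool(chans)
            Y = self.spec.apply_transform(pooled.to_numpy(dtype=float))
            if len(Y) < 2:
                raise ValueError(f"fewer than 2 measured cells at t={t}")
            self._data[t] = Y
        if self.spec.bandwidth is None:
            pooled_all = np.vstack([self._data[t] for t in self.times])
            self.bandwidth = median_heuristic_bandwidth(
                pooled_all, cap=self.spec.bandwidth_cap, seed=seed
            )
        else:
            self.bandwidth = float(self.spec.bandwidth)
        self._c = -0.5 / self.bandwidth**2
        # frozen per-time data terms
        self._y2 = {t: np.einsum("ij,ij->i", Y, Y) for t, Y in self._data.items()}
        self._myy = {}
        for t, Y in self._data.items():
            K = np.exp(self._c * _sq_dists(Y, Y))
            n = len(Y)
            if self.spec.estimator == "biased":
                self._myy[t] = float(K.mean())
            else:
                self._myy[t] = float((K.sum() - n) / (n * (n - 1)))
        if self.spec.time_weights is None:
            self._w = {t: 1.0 for t in self.times}
        else:
            self._w = {t: float(self.spec.time_weights.get(t, 0.0)) for t in self.times}
            if all(w == 0 for w in self._w.values()):
                raise ValueError("time weights must not all be zero")
        self.n_evaluations = 0

    # -- evaluation ----------------------------------------------------------
    def simulate(self, theta: ParameterSet):
        cells = derive_cell_rates(theta, self.cells)
        return simulate_ensemble(
            theta,
            cells,
            self.times,
            rtol=self.rtol,
            max_rhs_evals=self.max_rhs_evals,
            allow_fallback=self.robust,
        )

    def mmd_profile(self, theta: ParameterSet) -> dict[float, float]:
        """Per-timepoint MMD^2 values (infinite on simulation failure)."""
        try:
            res = self.simulate(theta)
        except SimulationError:
            return {t: math.inf for t in self.times}
        out: dict[float, float] = {}
        for i, t in enumerate(res.times):
            S = self.spec.apply_transform(
                res.states[i][~res.failed][:, self._chan_idx] * self._obs_factors
            )
            if not np.all(np.isfinite(S)) or len(S) < 2:
                return {u: math.inf for u in self.times}
            Y, y2 = self._data[t], self._y2[t]
            Kss = np.exp(self._c * _sq_dists(S, S))
            s2 = np.einsum("ij,ij->i", S, S)
            D = s2[:, None] + y2[None, :] - 2.0 * (S @ Y.T)
            Ksy = np.exp(self._c * np.maximum(D, 0.0))
            n = len(S)
            if self.spec.estimator == "biased":
                t_ss = float(Kss.mean())
            else:
                t_ss = float((Kss.sum() - n) / (n * (n - 1)))
            out[t] = t_ss + self._myy[t] - 2.0 * float(Ksy.mean())
        return out

    def __call__(self, theta: ParameterSet) -> float:
        self.n_evaluations += 1
        profile = self.mmd_profile(theta)
        return float(sum(self._w[t] * profile[t] for t in self.times))

    # -- fit diagnostics -----------------------------------------------------
    def diagnostics(self, theta: ParameterSet) -> dict[str, pd.DataFrame]:
        """Per-timepoint simulated vs measured means and pairwise covariances."""
        res = self.simulate(theta)
        chans = list(self.spec.channels)
        mean_rows, cov_rows = [], []
        for i, t in enumerate(res.times):
            S = self.spec.apply_transform(
                res.states[i][~res.failed][:, self._chan_idx] * self._obs_factors
            )
            Y = self._data[t]
            for which, M in (("simulated", S), ("measured", Y)):
                mu = M.mean(axis=0)
                C = np.cov(M.T)
                mean_rows.extend(
                    {"time": t, "source": which, "channel": c, "mean": mu[k]}
                    for k, c in enumerate(chans)
                )
                cov_rows.extend(
                    {
                        "time": t,
                        "source": which,
                        "var1": chans[a],
                        "var2": chans[b],
                        "cov": C[a, b],
                    }
                    for a in range(len(chans))
                    for b in range(a, len(chans))
                )
        return {"means": pd.DataFrame(mean_rows), "covariances": pd.DataFrame(cov_rows)}


# ---------------------------------------------------------------------------
# parameter-vector transform (log scale for rates/magnitudes, linear delays)
# ---------------------------------------------------------------------------

def _theta_to_vec(theta: ParameterSet) -> np.ndarray:
    return np.array(
        [
            getattr(theta, n) if n in LINEAR_PARAMS else math.log10(getattr(theta, n))
            for n in PARAM_NAMES
        ]
    )


def _vec_to_theta(vec: np.ndarray) -> ParameterSet:
    vals = {}
    for i, n in enumerate(PARAM_NAMES):
        vals[n] = max(vec[i], 0.0) if n in LINEAR_PARAMS else 10.0 ** vec[i]
    return ParameterSet.from_dict(vals)


# ---------------------------------------------------------------------------
# global sampling and local refinement
# ---------------------------------------------------------------------------

def default_search_ranges(
    cfg: Mapping[str, Any] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-parameter search ranges from the config schema.

    Scale parameters span a symmetric log2 window around the reference
    epithelial values; input magnitudes, delays and decay rates use the
    explicit overrides (the two phenotypes' plausible inputs differ by more
    than the generic window).
    """
    from .params import _KINETIC_ORDERS

    if cfg is None:
        cfg = load_default_config()
    center = cfg["parameters"]["epithelial"]
    hw = float(cfg["fit"]["range_log2_halfwidth"])
    hw_orders = float(cfg["fit"].get("range_log2_halfwidth_orders", hw))
    overrides = cfg["fit"]["range_overrides"]
    ranges: dict[str, tuple[float, float]] = {}
    for n in PARAM_NAMES:
        if n in overrides:
            lo, hi = overrides[n]
        else:
            w = hw_orders if n in _KINETIC_ORDERS else hw
            c = float(center[n])
            lo, hi = c * 2.0**-w, c * 2.0**w
        ranges[n] = (float(lo), float(hi))
    return ranges


def global_search(
    costfn: Callable[[ParameterSet], float],
    ranges: Mapping[str, tuple[float, float]],
    n_samples: int = 50_000,
    n_keep: int = 200,
    seed: int = 0,
) -> list[tuple[ParameterSet, float]]:
    """Log-uniform global sampling; returns the ``n_keep`` lowest-cost sets.

    Each parameter is drawn log-uniformly within its range (delays uniformly
    on the linear scale).  The returned list is sorted by ascending cost.
    """
    for n in PARAM_NAMES:
        lo, hi = ranges[n]
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
            raise ValueError(f"invalid range for {n}: ({lo}, {hi})")
        if n not in LINEAR_PARAMS and lo <= 0:
            raise ValueError(f"range for {n} must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random((n_samples, len(PARAM_NAMES)))
    draws = np.empty_like(u)
    for j, n in enumerate(PARAM_NAMES):
        lo, hi = ranges[n]
        if n in LINEAR_PARAMS:
            draws[:, j] = lo + (hi - lo) * u[:, j]
        else:
            draws[:, j] = np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * u[:, j])
    scored: list[tuple[ParameterSet, float]] = []
    for row in draws:
        theta = ParameterSet.from_array(row)
        scored.append((theta, float(costfn(theta))))
    scored.sort(key=lambda tc: tc[1])
    kept = scored[: min(n_keep, n_samples)]
    if not math.isfinite(kept[0][1]):
        raise RuntimeError(
            "every sampled parameter set had infinite cost; widen or re-center "
            "the search ranges"
        )
    return kept


def _vec_bounds(ranges: Mapping[str, tuple[float, float]]) -> list[tuple[float, float]]:
    """Search-space bounds: log10 for scale parameters, linear for delays."""
    out = []
    for n in PARAM_NAMES:
        lo, hi = ranges[n]
        if n in LINEAR_PARAMS:
            out.append((float(lo), float(hi)))
        else:
            out.append((math.log10(lo), math.log10(hi)))
    return out


def local_refine(
    costfn: Callable[[ParameterSet], float],
    theta0: ParameterSet,
    round_iters: int = 300,
    improve_frac: float = 0.02,
    max_rounds: int = 25,
    stage: str = "local",
    simplex_step: float | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> "FitResult":
    """Repeated Nelder-Mead rounds, re-initialized at the incumbent.

    Each round runs the simplex search for ``round_iters`` iterations from the
    current best point (rebuilding the simplex, which acts as the restart the
    procedure relies on); another round starts only while the end-of-round
    cost has improved by at least ``improve_frac`` relative.  The search works
    on log10-transformed scale parameters and linear delays.  ``simplex_step``
    sets the initial per-coordinate simplex edge in that transformed space
    (the solver default is a tiny 5% perturbation, which descends too slowly
    from rough global candidates); ``ranges`` bounds the search to the prior
    box, which suppresses compensated parameter ridges running through
    implausible kinetic orders.
    """
    bounds = _vec_bounds(ranges) if ranges is not None else None
    start_vec = _theta_to_vec(theta0)
    if bounds is not None:
        start_vec = np.clip(
            start_vec, [b[0] for b in bounds], [b[1] for b in bounds]
        )
        theta0 = _vec_to_theta(start_vec)
    f0 = float(costfn(theta0))
    if not math.isfinite(f0):
        raise ValueError("starting cost must be finite for local refinement")
    trace = [{"stage": stage, "round": 0, "cost": f0}]
    best_vec = start_vec
    best_cost = f0

    def obj(v: np.ndarray) -> float:
        return float(costfn(_vec_to_theta(v)))

    for rnd in range(1, max_rounds + 1):
        options: dict[str, Any] = {"maxiter": round_iters, "adaptive": True}
        if simplex_step:
            sim = np.tile(best_vec, (len(best_vec) + 1, 1))
            for i in range(len(best_vec)):
                up = best_vec[i] + simplex_step
                if bounds is not None and up > bounds[i][1]:
                    sim[i + 1, i] = best_vec[i] - simplex_step
                else:
                    sim[i + 1, i] = up
            options["initial_simplex"] = sim
        res = minimize(
            obj,
            best_vec,
            method="Nelder-Mead",
            bounds=bounds,
            options=options,
        )
        new_cost = float(res.fun)
        if new_cost < best_cost:
            improvement = (best_cost - new_cost) / best_cost if best_cost > 0 else 0.0
            best_cost, best_vec = new_cost, np.asarray(res.x)
        else:
            improvement = 0.0
        trace.append({"stage": stage, "round": rnd, "cost": best_cost})
        if not improvement >= improve_frac:  # also stops on nan improvement
            break
    return FitResult(
        theta=_vec_to_theta(best_vec),
        cost=best_cost,
        trace=pd.DataFrame(trace),
        seed=None,
        settings={"round_iters": round_iters, "improve_frac": improve_frac},
    )


# ---------------------------------------------------------------------------
# the full two-stage fit
# ---------------------------------------------------------------------------

@dataclass
class FitSettings:
    """Budgets and ranges of the two-stage search."""

    n_samples: int = 2000
    n_keep: int = 10
    round_iters: int = 100
    max_rounds: int = 2
    n_deep: int = 3
    deep_max_rounds: int = 5
    final_round_iters: int = 100
    final_max_rounds: int = 4
    improve_frac: float = 0.02
    final_tol: float = 1e-4
    n_screen_cells: int = 40
    simplex_step: float = 0.15
    ranges: dict[str, tuple[float, float]] | None = None

    @classmethod
    def from_config(
        cls, cfg: Mapping[str, Any] | None = None, budget: str = "desk"
    ) -> "FitSettings":
        if cfg is None:
            cfg = load_default_config()
        b = cfg["fit"]["budgets"][budget]
        return cls(
            n_samples=int(b["n_samples"]),
            n_keep=int(b["n_keep"]),
            round_iters=int(b["round_iters"]),
            max_rounds=int(b["max_rounds"]),
            n_deep=int(b.get("n_deep", 0)),
            deep_max_rounds=int(b.get("deep_max_rounds", 0)),
            final_round_iters=int(b["final_round_iters"]),
            final_max_rounds=int(b["final_max_rounds"]),
            improve_frac=float(cfg["fit"]["improve_frac"]),
            final_tol=float(cfg["fit"]["final_tol"]),
            n_screen_cells=int(cfg["fit"].get("n_screen_cells", 40)),
            simplex_step=float(cfg["fit"].get("simplex_step", 0.15)),
            ranges=default_search_ranges(cfg),
        )

    def as_dict(self) -> dict[str, Any]:
        out = {
            k: getattr(self, k)
            for k in (
                "n_samples", "n_keep", "round_iters", "max_rounds",
                "n_deep", "deep_max_rounds",
                "final_round_iters", "final_max_rounds", "improve_frac", "final_tol",
                "n_screen_cells", "simplex_step",
            )
        }
        return out


@dataclass
class FitResult:
    """Best parameter set, final cost, and the logged search trajectory."""

    theta: ParameterSet
    cost: float
    trace: pd.DataFrame
    seed: int | None
    settings: dict[str, Any] = field(default_factory=dict)
    diagnostics: dict[str, pd.DataFrame] = field(default_factory=dict)

    def save(self, directory: str | Path, prefix: str = "fit") -> None:
        from .params import save_parameters

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_parameters(self.theta, directory / f"{prefix}_parameters.txt")
        self.trace.to_csv(directory / f"{prefix}_trace.csv", index=False)
        lines = [f"cost = {self.cost!r}", f"seed = {self.seed!r}"]
        lines += [f"{k} = {v!r}" for k, v in self.settings.items()]
        (directory / f"{prefix}_result.txt").write_text("\n".join(lines) + "\n")
        for name, table in self.diagnostics.items():
            table.to_csv(directory / f"{prefix}_{name}.csv", index=False)


def fit(
    data: SnapshotDataset,
    cells: CellPopulation | None,
    spec: CostSpec | None = None,
    settings: FitSettings | None = None,
    seed: int = 0,
    n_sim_cells: int | None = None,
    extra_starts: Sequence[ParameterSet] = (),
) -> FitResult:
    """Two-stage global/local fit of the population parameters to a dataset.

    ``cells`` (the simulation ensemble) defaults to a seeded subsample of the
    dataset's pooled pre-stimulation cells, fixed for the whole optimization
    so the cost stays deterministic.  All stages derive their randomness from
    ``seed``; rerunning with the same inputs reproduces the result exactly.

    ``extra_starts`` joins additional candidate parameter sets (e.g. the best
    fit of a related condition, for sequential multi-condition calibration)
    to the global survivors before local refinement; they compete on cost
    like any other candidate.
    """
    settings = settings or FitSettings.from_config()
    spec = spec or CostSpec()
    cfg = load_default_config()
    if cells is None:
        if n_sim_cells is None:
            n_sim_cells = int(cfg["cost"]["n_sim_cells"])
        cells = baseline_cells(data, n_sim_cells, seed=stable_seed(seed, "cells"))
    costfn = MMDCost(data, cells, spec, seed=stable_seed(seed, "bandwidth"))
    ranges = settings.ranges or default_search_ranges(cfg)

    # multi-fidelity screening: the global stage only ranks rough candidates,
    # so it scores them with a smaller simulated ensemble (same data, same
    # bandwidth); all refinement uses the full-size cost
    n_screen = min(settings.n_screen_cells, cells.n_cells)
    if n_screen < cells.n_cells:
        screen_cells = cells.subset(np.arange(n_screen))
        screen_costfn = MMDCost(
            data, screen_cells, spec, seed=stable_seed(seed, "bandwidth"),
            max_rhs_evals=5_000,
        )
    else:
        screen_costfn = costfn
    survivors = global_search(
        screen_costfn,
        ranges,
        n_samples=settings.n_samples,
        n_keep=settings.n_keep,
        seed=stable_seed(seed, "global"),
    )
    traces = [
        pd.DataFrame(
            {"stage": "global", "round": 0, "cost": [c for _, c in survivors]}
        )
    ]
    candidates = list(survivors) + [(th, float(costfn(th))) for th in extra_starts]
    refined: list[FitResult] = []
    for rank, (theta0, c_screen) in enumerate(candidates):
        # rescore at full fidelity; screening misjudgements are dropped
        if not math.isfinite(c_screen) or not math.isfinite(costfn(theta0)):
            continue
        r = local_refine(
            costfn,
            theta0,
            round_iters=settings.round_iters,
            improve_frac=settings.improve_frac,
            max_rounds=settings.max_rounds,
            stage=f"local[{rank}]",
            simplex_step=settings.simplex_step,
            ranges=ranges,
        )
        refined.append(r)
        traces.append(r.trace)
    if not refined:
        raise RuntimeError("no survivor had a finite cost")
    refined.sort(key=lambda r: r.cost)
    # deepen the most promising candidates: stalled basins stop early via the
    # improvement rule, so the budget flows to whichever basin keeps improving
    if settings.n_deep > 0 and settings.deep_max_rounds > 0:
        deepened = []
        for rank, r in enumerate(refined[: settings.n_deep]):
            d = local_refine(
                costfn,
                r.theta,
                round_iters=settings.round_iters,
                improve_frac=settings.improve_frac,
                max_rounds=settings.deep_max_rounds,
                stage=f"deep[{rank}]",
                simplex_step=settings.simplex_step,
                ranges=ranges,
            )
            deepened.append(d if d.cost <= r.cost else r)
            traces.append(d.trace)
        refined = deepened + refined[settings.n_deep:]
    best = min(refined, key=lambda r: r.cost)
    # final refinement of the overall best until the cost stabilizes
    final = local_refine(
        costfn,
        best.theta,
        round_iters=settings.final_round_iters,
        improve_frac=settings.final_tol,
        max_rounds=settings.final_max_rounds,
        stage="final",
        simplex_step=settings.simplex_step,
        ranges=ranges,
    )
    traces.append(final.trace)
    incumbent = final if final.cost <= best.cost else best
    result = FitResult(
        theta=incumbent.theta,
        cost=incumbent.cost,
        trace=pd.concat(traces, ignore_index=True),
        seed=seed,
        settings={**settings.as_dict(), "n_evaluations": costfn.n_evaluations,
                  "bandwidth": costfn.bandwidth},
        diagnostics=costfn.diagnostics(incumbent.theta),
    )
    return result
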
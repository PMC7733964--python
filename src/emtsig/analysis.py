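"""Parameter sensitivity grids and cross-phenotype parameter reconciliation.

Two analyses quantify how far one parameter set can serve both phenotypes:

* a grid-based univariate sensitivity analysis — each parameter of the
  epithelial best fit is scanned over log2 fold-changes in [-8, 3] with step
  0.25 (45 offsets) and the percent increase of each phenotype's cost is
  recorded;
* reconciliation — a constrained search for a pair of parameter sets, one per
  phenotype, that are as close as possible in log2 space while neither
  phenotype's distribution-matching cost degrades beyond a small slack
  (default 1%).  The report of parameters still differing after
  reconciliation is the analysis' headline output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import LINEAR_PARAMS, PARAM_NAMES, ParameterSet

__all__ = [
    "SensitivityGrid",
    "sensitivity_grid",
    "ReconciliationResult",
    "reconcile",
    "diff_report",
]

#: Parameters describing the aggregated pathway inputs (magnitude/delay/decay).
INPUT_PARAMS: frozenset[str] = frozenset({"I1", "tau1", "d1", "I2", "tau2", "d2"})

CostFn = Callable[[ParameterSet], float]


def _penalty_weights(input_weight: float = 0.25, order_weight: float = 2.0
                     ) -> dict[str, float]:
    """Class weights of the transfer penalty.

    The weights encode the biochemical prior underlying the whole analysis:
    reaction chemistry — above all kinetic orders — should be invariant
    across phenotypes, while the aggregated input magnitudes stand for
    unmodeled upstream state (receptor levels, membrane composition) that
    plausibly changes across an EMT.  Changing an input magnitude is
    therefore the cheap explanation, changing a kinetic order the expensive
    one.
    """
    from .params import _KINETIC_ORDERS

    weights = {n: 1.0 for n in PARAM_NAMES}
    for n in _KINETIC_ORDERS:
        weights[n] = order_weight
    weights["I1"] = input_weight
    weights["I2"] = input_weight
    return weights


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

def default_offsets(lo: float = -8.0, hi: float = 3.0, step: float = 0.25) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


@dataclass
class SensitivityGrid:
    """Percent cost increase per (parameter, log2 offset) for one phenotype."""

    phenotype: str
    anchor: ParameterSet
    offsets: np.ndarray
    percent: pd.DataFrame   # rows = parameters, columns = offsets
    reference_cost: float

    def __post_init__(self) -> None:
        if list(self.percent.index) != list(PARAM_NAMES):
            raise ValueError("grid rows must be the canonical parameter list")
        if self.percent.shape[1] != len(self.offsets):
            raise ValueError("grid columns must match the offset list")

    def save(self, path: str | Path) -> None:
        self.percent.to_csv(path)


def sensitivity_grid(
    anchor: ParameterSet,
    costfns: Mapping[str, CostFn],
    best_fits: Mapping[str, ParameterSet],
    offsets: np.ndarray | None = None,
) -> dict[str, SensitivityGrid]:
    """Univariate log2-grid sensitivity of each phenotype's cost.

    For parameter j and offset delta, parameter j of the phenotype's own best
    fit is replaced by ``anchor_j * 2**delta`` (the anchor is the epithelial
    best fit, so both phenotypes are scanned over the same absolute values)
    and the percent increase over the phenotype's reference cost is recorded.
    Simulation failures at a grid point yield an infinite entry.
    """
    if offsets is None:
        offsets = default_offsets()
    offsets = np.asarray(offsets, dtype=float)
    out: dict[str, SensitivityGrid] = {}
    for pheno, costfn in costfns.items():
        theta_best = best_fits[pheno]
        f_star = float(costfn(theta_best))
        if not math.isfinite(f_star) or f_star <= 0:
            raise ValueError(f"reference cost for {pheno} must be finite and positive")
        grid = np.empty((len(PARAM_NAMES), len(offsets)))
        for i, name in enumerate(PARAM_NAMES):
            a_j = getattr(anchor, name)
            for k, delta in enumerate(offsets):
                theta = theta_best.with_value(name, a_j * 2.0**delta)
                f = float(costfn(theta))
                grid[i, k] = 100.0 * (f - f_star) / f_star if math.isfinite(f) else math.inf
        out[pheno] = SensitivityGrid(
            phenotype=pheno,
            anchor=anchor,
            offsets=offsets,
            percent=pd.DataFrame(grid, index=list(PARAM_NAMES), columns=offsets),
            reference_cost=f_star,
        )
    return out


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

def _log2_gap(theta_a: ParameterSet, theta_b: ParameterSet) -> dict[str, float]:
    return theta_a.log2_differences(theta_b)


def _l1_log2(theta_a: ParameterSet, theta_b: ParameterSet) -> float:
    return float(sum(abs(v) for v in _log2_gap(theta_a, theta_b).values()))


@dataclass
class ReconciliationResult:
    """A reconciled parameter pair with cost certificates and audit trail."""

    theta_e: ParameterSet
    theta_m: ParameterSet
    cost_e: float
    cost_m: float
    bound_e: float
    bound_m: float
    slack: float
    log2_differences: dict[str, float] = field(default_factory=dict)
    merged: list[str] = field(default_factory=list)
    audit: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.log2_differences:
            self.log2_differences = _log2_gap(self.theta_e, self.theta_m)
        tol = 1e-12
        if self.cost_e > (1.0 + self.slack) * self.bound_e * (1 + tol) or self.cost_m > (
            1.0 + self.slack
        ) * self.bound_m * (1 + tol):
            raise ValueError("cost certificates violate the reconciliation constraints")

    def differing(self, tol_log2: float = 0.1) -> list[str]:
        return [n for n, v in self.log2_differences.items() if abs(v) > tol_log2]

    def save(self, directory: str | Path, prefix: str = "reconciliation") -> None:
        from .params import save_parameters

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_parameters(self.theta_e, directory / f"{prefix}_epithelial.txt")
        save_parameters(self.theta_m, directory / f"{prefix}_mesenchymal.txt")
        table = pd.DataFrame(
            {
                "parameter": list(PARAM_NAMES),
                "epithelial": [getattr(self.theta_e, n) for n in PARAM_NAMES],
                "mesenchymal": [getattr(self.theta_m, n) for n in PARAM_NAMES],
                "log2_difference": [self.log2_differences[n] for n in PARAM_NAMES],
            }
        )
        table.to_csv(directory / f"{prefix}_parameters.csv", index=False)
        lines = [
            f"cost_epithelial = {self.cost_e!r}",
            f"cost_mesenchymal = {self.cost_m!r}",
            f"bound_epithelial = {self.bound_e!r}",
            f"bound_mesenchymal = {self.bound_m!r}",
            f"slack = {self.slack!r}",
            f"merged = {','.join(self.merged)}",
        ]
        (directory / f"{prefix}_certificates.txt").write_text("\n".join(lines) + "\n")


def _expanded_bounds(
    ranges: Mapping[str, tuple[float, float]] | None,
    thetas: list[ParameterSet],
) -> list[tuple[float, float]] | None:
    """Prior-box bounds in search space, widened to include given points."""
    if ranges is None:
        return None
    from .mmd import _theta_to_vec, _vec_bounds

    bounds = _vec_bounds(ranges)
    vecs = [_theta_to_vec(t) for t in thetas]
    out = []
    for i, (lo, hi) in enumerate(bounds):
        vals = [v[i] for v in vecs]
        out.append((min([lo] + vals), max([hi] + vals)))
    return out


def _subset_polish(
    theta: ParameterSet,
    names: list[str],
    cost_fn: CostFn,
    bounds_map: Mapping[str, tuple[float, float]],
    maxiter: int,
    anchor: ParameterSet | None = None,
    anchor_weight: float = 0.0,
    cap: float | None = None,
) -> ParameterSet:
    """Bounded Nelder-Mead over the listed parameters only; the rest stay
    exactly as they are (so unselected coordinates remain bit-identical to
    the reference).  With an ``anchor``, the objective adds a class-weighted
    L1 pull toward the anchor's values and a hard penalty above ``cap``, so
    the polish spends any cost headroom on moving closer to the anchor."""
    weights = _penalty_weights() if anchor is not None else {}

    def unpack(v: np.ndarray) -> ParameterSet:
        th = theta
        for i, n in enumerate(names):
            val = v[i] if n in LINEAR_PARAMS else 10.0 ** v[i]
            th = th.with_value(n, max(val, 0.0) if n in LINEAR_PARAMS else val)
        return th

    x0 = np.array(
        [
            getattr(theta, n) if n in LINEAR_PARAMS else math.log10(getattr(theta, n))
            for n in names
        ]
    )
    bounds = []
    for i, n in enumerate(names):
        lo, hi = bounds_map[n]
        bounds.append((min(lo, x0[i]), max(hi, x0[i])))

    def obj(v: np.ndarray) -> float:
        th = unpack(v)
        f = cost_fn(th)
        if not math.isfinite(f):
            return 1e12
        val = float(f)
        if cap is not None and f > cap:
            val += 1e3 * (f / cap - 1.0)
        if anchor is not None and anchor_weight > 0:
            gaps = _log2_gap(th, anchor)
            val += anchor_weight * sum(weights[n] * abs(gaps[n]) for n in names)
        return val

    res = minimize(
        obj, x0, method="Nelder-Mead", bounds=bounds,
        options={"maxiter": maxiter, "adaptive": True},
    )
    return unpack(np.asarray(res.x)) if res.fun <= obj(x0) else theta


def _transfer_refit(
    theta_ref: ParameterSet,
    cost_fn: CostFn,
    cap: float,
    sparsity_weight: float,
    ranges: Mapping[str, tuple[float, float]] | None,
    max_selected: int = 10,
    n_grid: int = 9,
) -> ParameterSet | None:
    """Sparse refit of one phenotype's parameters from the other's anchor.

    Greedy coordinate selection: starting at the anchor itself, repeatedly
    pick the single parameter whose best value (scanned over its prior
    range) most reduces the phenotype's cost, charging a class-weighted
    activation price per newly moved parameter; after each selection the
    selected subset is re-polished jointly while every unselected parameter
    stays bit-identical to the anchor.  The result expresses the data's
    demands as a minimal, interpretable set of adjustments (the biochemical
    prior makes input magnitudes the cheap explanation and kinetic orders
    the expensive one).  Returns the refit if it satisfies the cost cap,
    else None.
    """
    if ranges is None:
        return None
    weights = _penalty_weights()
    # strict bound (cap without slack) as the descent target leaves the
    # slack untouched for the later merge phase
    target = cap / (1.0 + 1e-9)
    theta = theta_ref
    f_cur = float(cost_fn(theta))
    if not math.isfinite(f_cur):
        return None
    selected: list[str] = []
    for _ in range(max_selected):
        if f_cur <= target * 0.995 and selected:
            break
        best = None  # (penalized score, name, value, raw cost)
        for name in PARAM_NAMES:
            if name in selected:
                continue
            lo, hi = ranges[name]
            if name in LINEAR_PARAMS:
                grid = np.linspace(lo, hi, n_grid)
            else:
                grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
            for val in grid:
                f = float(cost_fn(theta.with_value(name, float(val))))
                if not math.isfinite(f):
                    continue
                score = f + sparsity_weight * weights[name]
                if best is None or score < best[0]:
                    best = (score, name, float(val), f)
        if best is None or best[3] >= f_cur * 0.99:
            break
        _, name, val, _ = best
        selected.append(name)
        theta = theta.with_value(name, val)
        theta = _subset_polish(
            theta, selected, cost_fn, ranges, maxiter=40 * len(selected)
        )
        f_cur = float(cost_fn(theta))
    return theta if f_cur <= cap else None


def reconcile(
    theta_e: ParameterSet,
    theta_m: ParameterSet,
    costfns: Mapping[str, CostFn],
    slack: float = 0.01,
    n_candidates: int = 11,
    polish_iters: int = 150,
    sparsity_weight: float = 0.0,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> ReconciliationResult:
    """Minimize the log2 distance between two best-fit parameter sets subject
    to neither phenotype's cost rising above ``(1 + slack)`` times its bound.

    Phase 0 re-expresses the mesenchymal set as a sparse adjustment of the
    epithelial anchor: an L1-penalized refit of the mesenchymal cost starting
    from the epithelial parameters (independent fits of a sloppy landscape
    land in different compensation basins, so their raw difference vastly
    overstates the physiologically required one; the penalized transfer refit
    finds a mesenchymal optimum in the anchor's basin, accepted only if it
    honors the mesenchymal cost bound).  The epithelial anchor is then held
    fixed and mesenchymal parameters are pulled toward it: phase 1
    line-searches each parameter over ``n_candidates`` points from the
    anchor's value toward the current mesenchymal value and accepts the
    first (anchor-nearest) feasible point; phase 2 performs backward
    elimination with re-polish — one differing parameter at a time is
    snapped to the anchor's value while the remaining differing parameters
    re-adjust by bounded simplex search to restore the mesenchymal fit.
    Certificates are always plain costs, recomputed at the final pair.
    """
    cost_e_fn, cost_m_fn = costfns["epithelial"], costfns["mesenchymal"]
    bound_e = float(cost_e_fn(theta_e))
    bound_m = float(cost_m_fn(theta_m))
    if not (math.isfinite(bound_e) and math.isfinite(bound_m)):
        raise ValueError("reconciliation requires finite costs at both inputs")
    cap_e = (1.0 + slack) * bound_e
    cap_m = (1.0 + slack) * bound_m

    cur_e, cur_m = theta_e, theta_m
    merged: list[str] = []
    audit_rows = [{"phase": "input", "parameter": "", "l1_log2": _l1_log2(cur_e, cur_m)}]
    if ranges is None:
        from .mmd import default_search_ranges

        ranges = default_search_ranges()
    if sparsity_weight > 0:
        transferred = _transfer_refit(
            theta_e, cost_m_fn, cap_m, sparsity_weight, ranges
        )
        weights = _penalty_weights()

        def weighted_l1(a: ParameterSet, b: ParameterSet) -> float:
            return sum(weights[n] * abs(g) for n, g in _log2_gap(a, b).items())

        if transferred is not None and weighted_l1(theta_e, transferred) < weighted_l1(
            theta_e, theta_m
        ):
            cur_m = transferred
            audit_rows.append(
                {"phase": "transfer", "parameter": "",
                 "l1_log2": _l1_log2(cur_e, cur_m)}
            )

    # The epithelial anchor is held fixed from here on (its certificate is
    # then exactly its bound): the minimal-difference pair is found by
    # pulling mesenchymal parameters toward the anchor while the mesenchymal
    # cost permits.
    weights = _penalty_weights()

    # phase 1: per-parameter line search toward the anchor, smallest
    # (class-weighted) gaps first; candidates run from the anchor's value
    # toward the current mesenchymal value, and the first feasible one wins
    gaps = _log2_gap(cur_e, cur_m)
    for name in sorted(PARAM_NAMES, key=lambda n: weights[n] * abs(gaps[n])):
        a, b = getattr(cur_e, name), getattr(cur_m, name)
        if a == b:
            merged.append(name)
            continue
        if name in LINEAR_PARAMS:
            seg = np.linspace(a, b, n_candidates)
        else:
            seg = np.exp(np.linspace(math.log(a), math.log(b), n_candidates))
        seg[0], seg[-1] = a, b  # exact endpoints despite rounding
        for cand in seg:
            trial_m = cur_m.with_value(name, float(cand))
            if cost_m_fn(trial_m) <= cap_m:
                cur_m = trial_m
                if float(cand) == a:
                    merged.append(name)
                audit_rows.append(
                    {"phase": "greedy", "parameter": name,
                     "l1_log2": _l1_log2(cur_e, cur_m)}
                )
                break

    if polish_iters > 0:
        def differing(tm: ParameterSet, tol: float = 1e-3) -> list[str]:
            g = _log2_gap(cur_e, tm)
            return [n for n in PARAM_NAMES if abs(g[n]) > tol]

        def pull_pass(tm: ParameterSet) -> ParameterSet:
            # per-parameter line search toward the anchor (phase-1 move)
            for name in sorted(
                differing(tm), key=lambda n: weights[n] * abs(_log2_gap(cur_e, tm)[n])
            ):
                a, b = getattr(cur_e, name), getattr(tm, name)
                if name in LINEAR_PARAMS:
                    seg = np.linspace(a, b, n_candidates)
                else:
                    seg = np.exp(np.linspace(math.log(a), math.log(b), n_candidates))
                seg[0], seg[-1] = a, b
                for cand in seg:
                    trial = tm.with_value(name, float(cand))
                    if cost_m_fn(trial) <= cap_m:
                        tm = trial
                        break
            return tm

        # phase 2a: continuation polish -- all differing parameters slide
        # jointly toward the anchor under a strong class-weighted L1 pull,
        # with a hard penalty keeping the mesenchymal cost under its cap
        for _ in range(2):
            free = differing(cur_m)
            if not free:
                break
            trial = _subset_polish(
                cur_m, free, cost_m_fn, ranges, maxiter=polish_iters,
                anchor=cur_e, anchor_weight=1e-2, cap=cap_m,
            )
            if cost_m_fn(trial) <= cap_m and _l1_log2(cur_e, trial) < _l1_log2(
                cur_e, cur_m
            ):
                cur_m = trial
                audit_rows.append(
                    {"phase": "polish", "parameter": "",
                     "l1_log2": _l1_log2(cur_e, cur_m)}
                )
            else:
                break
        cur_m = pull_pass(cur_m)

        # phase 2b: backward elimination with re-polish of the rest -- snap
        # one differing parameter to the anchor's value at a time
        for _pass in range(1):
            any_accepted = False
            for name in sorted(
                differing(cur_m),
                key=lambda n: weights[n] * abs(_log2_gap(cur_e, cur_m)[n]),
            ):
                rest = [n for n in differing(cur_m) if n != name]
                if not rest:
                    break
                trial = cur_m.with_value(name, getattr(cur_e, name))
                trial = _subset_polish(
                    trial, rest, cost_m_fn, ranges,
                    maxiter=min(polish_iters, 30 + 8 * len(rest)),
                    anchor=cur_e, anchor_weight=3e-3, cap=cap_m,
                )
                if cost_m_fn(trial) <= cap_m and _l1_log2(cur_e, trial) < _l1_log2(
                    cur_e, cur_m
                ):
                    cur_m = trial
                    merged.append(name)
                    any_accepted = True
                    audit_rows.append(
                        {"phase": "polish", "parameter": name,
                         "l1_log2": _l1_log2(cur_e, cur_m)}
                    )
            if not any_accepted:
                break

    return ReconciliationResult(
        theta_e=cur_e,
        theta_m=cur_m,
        cost_e=float(cost_e_fn(cur_e)),
        cost_m=float(cost_m_fn(cur_m)),
        bound_e=bound_e,
        bound_m=bound_m,
        slack=slack,
        merged=merged,
        audit=pd.DataFrame(audit_rows),
    )


def diff_report(res: ReconciliationResult, tol_log2: float = 0.1) -> pd.DataFrame:
    """Parameters still differing after reconciliation, largest gaps first.

    Each row is annotated as input-related (magnitude/delay/decay of the
    aggregated pathway inputs) or kinetic.
    """
    rows = [
        {
            "parameter": n,
            "log2_difference": v,
            "abs_log2_difference": abs(v),
            "category": "input" if n in INPUT_PARAMS else "kinetic",
        }
        for n, v in res.log2_differences.items()
        if abs(v) > tol_log2
    ]
    df = pd.DataFrame(rows, columns=["parameter", "log2_difference",
                                     "abs_log2_difference", "category"])
    return df.sort_values("abs_log2_difference", ascending=False,
                          kind="stable").reset_index(drop=True)
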
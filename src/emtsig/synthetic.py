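"""Synthetic single-cell snapshot data with known ground truth.

The generator emulates the statistical structure of a mass-cytometry EGF
time course: correlated lognormal total-protein abundances, baseline phospho
levels as noisy fractions of totals, bimodally separated phenotype markers
(E-cadherin / vimentin), a cleaved-PARP viability channel, destructive
sampling (an independent cell population per snapshot), multiplicative
lognormal measurement noise, and 3 replicates over the sampling grid
{-10, -5, 0, 1, 3, 5, 8, 12, 15, 20, 30, 50} min plus unstimulated controls.
Signaling dynamics come from the mechanistic model itself, so fitting,
sensitivity and reconciliation experiments have known answers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import load_default_config, stable_seed
from .data import CONTROL, STIMULATED, Snapshot, SnapshotDataset
from .model import (
    MEASURED_SPECIES,
    CellPopulation,
    SimulationError,
    derive_cell_rates,
    simulate_ensemble,
)
from .params import GroundTruth, ParameterSet, ground_truth_presets  # noqa: F401

__all__ = [
    "PhenotypeConfig",
    "generate_cell_population",
    "generate_timecourse",
    "generate_two_phenotype_study",
    "linear_gaussian_cascade",
]

_CLAMP_EPS = 1e-6
_DEAD_CUTOFF = 20  # counts; cells above are "dead" by construction


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class PhenotypeConfig:
    """Generator settings for one phenotype's cell populations."""

    label: str
    n_cells_per_snapshot: int
    total_means: Mapping[str, float]          # total channel -> mean level [a.u.]
    total_cv: float
    total_correlation: float                  # shared pairwise corr on log scale
    baseline_phospho_fraction: Mapping[str, float]  # phospho channel -> fraction
    baseline_cv: float
    ecad_vim_modes: tuple[float, float]       # (E-cadherin, vimentin) medians
    marker_cv: float
    dead_fraction: float
    noise_cv: float

    def __post_init__(self) -> None:
        if self.label not in ("epithelial", "mesenchymal"):
            raise ValueError(f"label must be epithelial|mesenchymal, got {self.label!r}")
        if self.n_cells_per_snapshot < 10:
            raise ValueError("n_cells_per_snapshot must be >= 10")
        if any(m <= 0 for m in self.total_means.values()):
            raise ValueError("total means must be positive")
        for f in self.baseline_phospho_fraction.values():
            if not (0 < f < 1):
                raise ValueError("baseline phospho fractions must lie in (0, 1)")
        if self.total_cv < 0 or self.baseline_cv < 0 or self.noise_cv < 0:
            raise ValueError("CVs must be non-negative")
        if not (0 <= self.total_correlation < 1):
            raise ValueError("total_correlation must lie in [0, 1)")
        if not (0 <= self.dead_fraction < 1):
            raise ValueError("dead_fraction must lie in [0, 1)")
        if any(m <= 0 for m in self.ecad_vim_modes):
            raise ValueError("ecad_vim_modes must be positive")

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any] | None = None, label: str = "epithelial",
                    **overrides) -> "PhenotypeConfig":
        """Build from an analysis config (packaged defaults if ``cfg`` is None)."""
        if cfg is None:
            cfg = load_default_config()
        shared = dict(cfg["generator"]["shared"])
        shared.update(cfg["generator"][label])
        shared["ecad_vim_modes"] = tuple(shared["ecad_vim_modes"])
        shared.update(overrides)
        return cls(label=label, **shared)


def _draw_cells(config: PhenotypeConfig, rng: np.random.Generator,
                panel: Mapping[str, Any]) -> tuple[CellPopulation, pd.DataFrame]:
    n = config.n_cells_per_snapshot
    phospho = list(panel["phospho"])
    total_of = panel["totals"]
    total_channels = [total_of[p] for p in phospho]
    means = np.array([config.total_means[t] for t in total_channels])

    # correlated multivariate lognormal totals: equicorrelated on the log scale
    d = len(total_channels)
    sigma = _lognormal_sigma(config.total_cv)
    corr = np.full((d, d), config.total_correlation)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, d)) @ chol.T
    mu = np.log(means) - 0.5 * sigma * sigma  # E[total] = configured mean
    totals = np.exp(mu[None, :] + sigma * z)

    # baseline phospho: fraction * total * lognormal jitter, clamped interior
    fracs = np.array([config.baseline_phospho_fraction[p] for p in phospho])
    s_b = _lognormal_sigma(config.baseline_cv)
    jitter = np.exp(rng.standard_normal((n, d)) * s_b - 0.5 * s_b * s_b)
    baseline = np.clip(
        fracs[None, :] * totals * jitter,
        _CLAMP_EPS * totals,
        (1.0 - _CLAMP_EPS) * totals,
    )
    pop = CellPopulation(totals=totals, baseline=baseline)

    # phenotype markers and viability channel
    s_m = _lognormal_sigma(config.marker_cv)
    ecad = config.ecad_vim_modes[0] * np.exp(rng.standard_normal(n) * s_m)
    vim = config.ecad_vim_modes[1] * np.exp(rng.standard_normal(n) * s_m)
    dead = rng.random(n) < config.dead_fraction
    cparp = np.minimum(rng.poisson(2.0, size=n), _DEAD_CUTOFF).astype(float)
    cparp[dead] = _DEAD_CUTOFF + 1 + rng.poisson(30.0, size=int(dead.sum()))
    ecad_ch, vim_ch = panel["phenotype_markers"]
    markers = pd.DataFrame({ecad_ch: ecad, vim_ch: vim, panel["viability"]: cparp})
    return pop, markers


def generate_cell_population(
    config: PhenotypeConfig, seed: int, panel: Mapping[str, Any] | None = None
) -> tuple[CellPopulation, pd.DataFrame]:
    """Draw one independent cell population.

    Returns the :class:`~emtsig.model.CellPopulation` (totals and baseline
    phospho, clamped to the interior of (0, T)) together with a table of the
    non-kinetic channels (phenotype markers and cleaved-PARP counts).
    """
    if panel is None:
        panel = load_default_config()["panel"]
    rng = np.random.default_rng(seed)
    return _draw_cells(config, rng, panel)


def _assemble_snapshot(
    states: np.ndarray,
    pop: CellPopulation,
    markers: pd.DataFrame,
    panel: Mapping[str, Any],
    noise_cv: float,
    rng: np.random.Generator,
    **meta,
) -> Snapshot:
    phospho = list(panel["phospho"])
    total_channels = [panel["totals"][p] for p in phospho]
    df = pd.DataFrame(states, columns=phospho)
    df[total_channels] = pop.totals
    df = pd.concat([df, markers.reset_index(drop=True)], axis=1)
    if noise_cv > 0:
        s = _lognormal_sigma(noise_cv)
        intensity = phospho + total_channels + list(panel["phenotype_markers"])
        noise = np.exp(rng.standard_normal((len(df), len(intensity))) * s - 0.5 * s * s)
        df[intensity] = df[intensity].to_numpy() * noise
    return Snapshot(data=df, **meta)


def generate_timecourse(
    truth: ParameterSet,
    config: PhenotypeConfig,
    time_grid: Sequence[float] | None = None,
    seed: int = 0,
    *,
    n_replicates: int = 3,
    control_times: Sequence[float] | None = None,
    panel: Mapping[str, Any] | None = None,
) -> SnapshotDataset:
    """Simulate a destructively sampled EGF time course for one phenotype.

    For every snapshot (time x replicate x condition) an independent cell
    population is drawn, its cell-specific deactivation rates are derived so
    each cell starts at its own steady state, the ensemble is simulated to the
    snapshot time, and multiplicative lognormal measurement noise is applied.
    Unstimulated controls (input held at the resting level) are emitted for
    ``control_times``.
    """
    cfg = load_default_config()
    if panel is None:
        panel = cfg["panel"]
    if time_grid is None:
        time_grid = cfg["design"]["time_grid"]
    if control_times is None:
        control_times = cfg["design"]["control_times"]
    times = [float(t) for t in time_grid]
    if times != sorted(times):
        raise ValueError("time_grid must be sorted ascending")
    if not any(t <= 0 for t in times):
        raise ValueError("time_grid must contain at least one pre-stimulus point")

    dataset = SnapshotDataset()
    plan = [(STIMULATED, t) for t in times] + [(CONTROL, float(t)) for t in control_times]
    for rep in range(1, n_replicates + 1):
        for condition, t in plan:
            snap_seed = stable_seed(seed, config.label, condition, rep, t)
            rng = np.random.default_rng(snap_seed)
            pop, markers = _draw_cells(config, rng, panel)
            pop = derive_cell_rates(truth, pop)
            try:
                res = simulate_ensemble(
                    truth, pop, [t], stimulated=(condition == STIMULATED)
                )
            except SimulationError as exc:
                raise SimulationError(
                    f"snapshot simulation failed at t={t} min, replicate {rep}, "
                    f"{condition}/{config.label}: {exc}"
                ) from exc
            if res.failed.any():
                bad = np.flatnonzero(res.failed)
                raise SimulationError(
                    f"cells {bad.tolist()} failed at t={t} min, replicate {rep} "
                    f"({config.label}); parameter set: {truth.to_dict()}"
                )
            dataset.append(
                _assemble_snapshot(
                    res.states[0],
                    pop,
                    markers,
                    panel,
                    config.noise_cv,
                    rng,
                    time=t,
                    replicate=rep,
                    condition=condition,
                    phenotype=config.label,
                    seed=snap_seed,
                )
            )
    return dataset


def generate_two_phenotype_study(
    seed: int,
    *,
    truth: GroundTruth | None = None,
    n_cells: int | None = None,
    noise_cv: float | None = None,
    n_replicates: int = 3,
    time_grid: Sequence[float] | None = None,
) -> dict[str, SnapshotDataset]:
    """Full two-phenotype synthetic study from the reference presets."""
    if truth is None:
        truth = ground_truth_presets()
    out: dict[str, SnapshotDataset] = {}
    for label, theta in (
        ("epithelial", truth.theta_epithelial),
        ("mesenchymal", truth.theta_mesenchymal),
    ):
        overrides: dict[str, Any] = {}
        if n_cells is not None:
            overrides["n_cells_per_snapshot"] = n_cells
        if noise_cv is not None:
            overrides["noise_cv"] = noise_cv
        config = PhenotypeConfig.from_config(label=label, **overrides)
        out[label] = generate_timecourse(
            theta,
            config,
            time_grid=time_grid,
            seed=stable_seed(seed, "study", label),
            n_replicates=n_replicates,
        )
    return out


def linear_gaussian_cascade(
    n: int,
    seed: int,
    *,
    strength: float = 0.85,
    location: float = 4.0,
    scale: float = 0.5,
) -> pd.DataFrame:
    """Positive-intensity sample whose log(1+X) is a linear-Gaussian cascade.

    The latent variables follow the canonical chain pMEK -> ppERK -> pRSK ->
    pS6 with an independent pAKT -> pGSK3b branch, each edge a standardized
    linear-Gaussian link with coefficient ``strength``.  Latents are placed at
    ``location +- scale`` so that ``log(1 + exp(latent))`` is essentially the
    latent itself, making this a ground-truth instance for partial-correlation
    network recovery.
    """
    rng = np.random.default_rng(seed)
    e = np.sqrt(1.0 - strength**2)
    z = {}
    z["pMEK"] = rng.standard_normal(n)
    z["ppERK"] = strength * z["pMEK"] + e * rng.standard_normal(n)
    z["pRSK"] = strength * z["ppERK"] + e * rng.standard_normal(n)
    z["pS6"] = strength * z["pRSK"] + e * rng.standard_normal(n)
    z["pAKT"] = rng.standard_normal(n)
    z["pGSK3b"] = strength * z["pAKT"] + e * rng.standard_normal(n)
    cols = ["pMEK", "ppERK", "pRSK", "pAKT", "pGSK3b", "pS6"]
    return pd.DataFrame({c: np.exp(location + scale * z[c]) for c in cols})
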
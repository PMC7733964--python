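"""Population-level kinetic parameters of the unified ERK/AKT pathway model.

The model couples two receptor-proximal inputs (EGF-driven, with magnitude
``I``, onset delay ``tau`` [min] and exponential decay ``d`` [1/min]) to the
RAF-MEK-ERK-RSK and PI3K-AKT-GSK3b branches, which converge on S6.  All
reactions are written in canonical power-law (generalized mass action) form:
activation terms ``k * upstream**g * (T - x)`` and deactivation terms
``gamma * x**h``.  The 38 parameters collected here are shared across every
cell of a population; cell-to-cell variability enters only through measured
totals, baseline phospho levels and the per-cell deactivation rates derived
from them (see :mod:`emtsig.model`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "SCALE_PARAMS",
    "LINEAR_PARAMS",
    "ParameterSet",
    "GroundTruth",
    "ground_truth_presets",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

#: Canonical ordering of the 38 population parameters.
PARAM_NAMES: tuple[str, ...] = (
    # aggregated pathway inputs
    "I1", "tau1", "d1", "I2", "tau2", "d2",
    # pRAF block (unmeasured modifier of the ERK branch)
    "kR", "gR", "gc1", "hR", "gammaR", "RT",
    # PI3K block (unmeasured modifier of the AKT branch)
    "kP", "gP", "hP", "gammaP",
    # measured single-input species: MEK, ERK, RSK, AKT
    "k1", "g1", "h1",
    "k2", "g2", "h2",
    "k3", "g3", "h3",
    "k4", "g4", "h4",
    # GSK3b: AKT branch (k5/g5) + RSK crosstalk branch (k12/g12)
    "k5", "g5", "h5", "k12", "g12",
    # S6: RSK branch (k6/g6) + AKT branch (k13/g13)
    "k6", "g6", "h6", "k13", "g13",
)

#: Parameters on the linear scale during optimization (onset delays, minutes).
LINEAR_PARAMS: frozenset[str] = frozenset({"tau1", "tau2"})

#: Strictly positive parameters searched on a log scale.
SCALE_PARAMS: tuple[str, ...] = tuple(n for n in PARAM_NAMES if n not in LINEAR_PARAMS)

_KINETIC_ORDERS = frozenset(
    {"gR", "gc1", "hR", "gP", "hP"}
    | {f"g{i}" for i in (1, 2, 3, 4, 5, 6, 12, 13)}
    | {f"h{i}" for i in (1, 2, 3, 4, 5, 6)}
)


@dataclass(frozen=True)
class ParameterSet:
    """The 38 population-level parameters of the unified pathway model."""

    I1: float
    tau1: float
    d1: float
    I2: float
    tau2: float
    d2: float
    kR: float
    gR: float
    gc1: float
    hR: float
    gammaR: float
    RT: float
    kP: float
    gP: float
    hP: float
    gammaP: float
    k1: float
    g1: float
    h1: float
    k2: float
    g2: float
    h2: float
    k3: float
    g3: float
    h3: float
    k4: float
    g4: float
    h4: float
    k5: float
    g5: float
    h5: float
    k12: float
    g12: float
    k6: float
    g6: float
    h6: float
    k13: float
    g13: float

    # -- container protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParameterSet":
        missing = set(PARAM_NAMES) - set(values)
        extra = set(values) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(
                f"parameter name mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        return cls(**{n: float(values[n]) for n in PARAM_NAMES})

    def to_array(self) -> np.ndarray:
        """Values in canonical :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "ParameterSet":
        vals = np.asarray(list(values), dtype=float)
        if vals.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {vals.shape}")
        return cls(**dict(zip(PARAM_NAMES, vals.tolist())))

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        return dataclasses.replace(self, **{name: float(value)})

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        """Check sign/range invariants; raises ``ValueError`` on violation.

        Rates, magnitudes and capacities must be strictly positive; kinetic
        orders lie in (0, 6]; delays are non-negative.  Validation is explicit
        (not enforced at construction) so that exploratory evaluations, e.g.
        extreme sensitivity-grid offsets, remain expressible.
        """
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v}")
            if name in LINEAR_PARAMS:
                if v < 0:
                    raise ValueError(f"delay {name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {v}")
            if name in _KINETIC_ORDERS and not (0 < v <= 6):
                raise ValueError(f"kinetic order {name} must be in (0, 6], got {v}")

    # -- comparisons ---------------------------------------------------------
    def log2_differences(self, other: "ParameterSet") -> dict[str, float]:
        """Per-parameter ``log2(self/other)``; delays compared on a log scale
        after a +1 offset so that zero delays are well defined."""
        out: dict[str, float] = {}
        for n in PARAM_NAMES:
            a, b = getattr(self, n), getattr(other, n)
            if n in LINEAR_PARAMS:
                out[n] = math.log2((a + 1.0) / (b + 1.0))
            else:
                out[n] = math.log2(a / b)
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Paired epithelial/mesenchymal parameter sets with a known difference set."""

    theta_epithelial: ParameterSet
    theta_mesenchymal: ParameterSet
    differing_parameters: tuple[str, ...]

    def __post_init__(self) -> None:
        for n in PARAM_NAMES:
            same = getattr(self.theta_epithelial, n) == getattr(self.theta_mesenchymal, n)
            if n in self.differing_parameters:
                if same:
                    raise ValueError(f"{n} listed as differing but values are equal")
            elif not same:
                raise ValueError(f"{n} differs but is not listed in differing_parameters")


def default_parameters() -> ParameterSet:
    """Epithelial-state defaults (documented in the packaged config schema)."""
    from .config import load_default_config

    cfg = load_default_config()
    return ParameterSet.from_dict(cfg["parameters"]["epithelial"])


def ground_truth_presets() -> GroundTruth:
    """Epithelial and mesenchymal reference parameter sets.

    The two phenotypes share every parameter except the four that the
    cross-phenotype reconciliation singles out: the two input magnitudes
    (I1: 5.3 vs 1.9; I2: 8.1 vs 55), the pGSK3b dephosphorylation order
    (h5: 0.3 vs 0.05) and the AKT-branch S6 activation rate
    (k13: 10^-7.8 vs 10^-9.5).
    """
    theta_e = default_parameters()
    theta_m = theta_e.replace(I1=1.9, I2=55.0, h5=0.05, k13=10.0 ** -9.5)
    return GroundTruth(
        theta_epithelial=theta_e,
        theta_mesenchymal=theta_m,
        differing_parameters=("I1", "I2", "h5", "k13"),
    )


# -- flat text serialization (name = value per line) -------------------------

def save_parameters(theta: ParameterSet, path: str | Path) -> None:
    lines = [f"{n} = {getattr(theta, n)!r}" for n in PARAM_NAMES]
    Path(path).write_text("\n".join(lines) + "\n")


def load_parameters(path: str | Path) -> ParameterSet:
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, raw = line.partition("=")
        values[name.strip()] = float(raw)
    return ParameterSet.from_dict(values)
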
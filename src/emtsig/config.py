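"""Analysis configuration: packaged defaults, loading, validation, hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "load_default_config",
    "load_config",
    "merge_config",
    "validate_config",
    "config_hash",
    "stable_seed",
]

_REQUIRED_SECTIONS = (
    "panel",
    "design",
    "parameters",
    "generator",
    "preprocessing",
    "network",
    "cost",
    "fit",
    "sensitivity",
    "reconciliation",
)


def load_default_config() -> dict[str, Any]:
    """The packaged default configuration (a fresh mutable copy)."""
    text = resources.files("emtsig").joinpath("defaults.yaml").read_text()
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a config file, overlaying it on the packaged defaults."""
    cfg = load_default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = merge_config(cfg, user)
        validate_config(cfg)
    return cfg


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursive dict merge; override wins, scalars/lists replace wholesale."""
    out = copy.deepcopy(dict(base))
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Schema check; raises ``ValueError`` naming the offending field."""
    for section in _REQUIRED_SECTIONS:
        if section not in cfg:
            raise ValueError(f"config missing section {section!r}")
    panel = cfg["panel"]
    for field in ("phospho", "totals", "phenotype_markers", "viability"):
        if field not in panel:
            raise ValueError(f"config missing field panel.{field}")
    missing = [p for p in panel["phospho"] if p not in panel["totals"]]
    if missing:
        raise ValueError(f"panel.totals missing role for phospho channels {missing}")
    grid = cfg["design"]["time_grid"]
    if sorted(grid) != list(grid):
        raise ValueError("design.time_grid must be sorted ascending")
    if not any(t <= 0 for t in grid):
        raise ValueError("design.time_grid needs at least one pre-stimulus point (t <= 0)")
    from .params import PARAM_NAMES  # deferred: params loads config for defaults

    theta = cfg["parameters"]["epithelial"]
    missing_p = set(PARAM_NAMES) - set(theta)
    extra_p = set(theta) - set(PARAM_NAMES)
    if missing_p or extra_p:
        raise ValueError(
            f"parameters.epithelial mismatch: missing={sorted(missing_p)}, "
            f"unexpected={sorted(extra_p)}"
        )
    gen = cfg["generator"]["shared"]
    for frac in ("total_cv", "baseline_cv", "noise_cv"):
        if gen[frac] < 0:
            raise ValueError(f"generator.shared.{frac} must be >= 0")
    if not (0 <= gen["dead_fraction"] < 1):
        raise ValueError("generator.shared.dead_fraction must lie in [0, 1)")
    if not (0 <= gen["total_correlation"] < 1):
        raise ValueError("generator.shared.total_correlation must lie in [0, 1)")
    if gen["n_cells_per_snapshot"] < 10:
        raise ValueError("generator.shared.n_cells_per_snapshot must be >= 10")


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a config, for provenance manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.blake2b(blob, digest_size=8).hexdigest()


def stable_seed(master_seed: int, *tokens: object) -> int:
    """Derive an independent 31-bit seed from a master seed and labels."""
    blob = ":".join([str(int(master_seed)), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.blake2b(blob, digest_size=4).digest(), "big") % (2**31)
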
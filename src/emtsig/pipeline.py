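"""End-to-end orchestration of the synthetic two-phenotype analysis.

``run_all`` chains every stage — synthetic data generation (or ingestion of an
existing snapshot directory), preprocessing, partial-correlation network
inference, distribution-matching fits for both phenotypes, the sensitivity
grid, and parameter reconciliation — writing each stage's artifacts with a
provenance manifest (config hash, master seed, stage seed).  Per-stage seeds
are derived by stable hashing of (master seed, stage name) so stages are
independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .analysis import diff_report, reconcile, sensitivity_grid
from .config import config_hash, load_default_config, merge_config, stable_seed, validate_config
from .data import SnapshotDataset
from .mmd import CostSpec, FitSettings, MMDCost, baseline_cells, fit
from .network import edge_dynamics_by_timepoint, partial_correlation_matrix
from .params import ground_truth_presets
from .preprocessing import preprocess_dataset
from .synthetic import PhenotypeConfig, generate_timecourse

__all__ = ["run_all"]

logger = logging.getLogger("emtsig.pipeline")

PHENOTYPES = ("epithelial", "mesenchymal")


def _write_manifest(directory: Path, **entries: Any) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    lines = [f"{k} = {v}" for k, v in entries.items()]
    (directory / "manifest.txt").write_text("\n".join(lines) + "\n")


def run_all(
    out_dir: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
    budget: str = "desk",
    data_dirs: Mapping[str, str | Path] | None = None,
) -> dict[str, Any]:
    """Run the full analysis and write all artifact families under ``out_dir``.

    ``config`` may be a partial override of the packaged defaults.  If
    ``data_dirs`` maps phenotype labels to snapshot directories, those are
    ingested instead of generating synthetic data.  Returns a report bundle
    with the in-memory results of every stage.
    """
    cfg = load_default_config() if config is None else merge_config(load_default_config(), config)
    validate_config(cfg)
    chash = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config_hash": chash, "seed": seed}
    t_start = time.time()

    # -- stage 1: data -------------------------------------------------------
    truth = ground_truth_presets()
    datasets: dict[str, SnapshotDataset] = {}
    for pheno in PHENOTYPES:
        stage_seed = stable_seed(seed, "data", pheno)
        if data_dirs is not None and pheno in data_dirs:
            logger.info("ingesting %s snapshots from %s", pheno, data_dirs[pheno])
            datasets[pheno] = SnapshotDataset.load(data_dirs[pheno])
        else:
            logger.info("generating synthetic %s time course (seed %d)", pheno, stage_seed)
            theta = getattr(truth, f"theta_{pheno}")
            pcfg = PhenotypeConfig.from_config(cfg, pheno)
            datasets[pheno] = generate_timecourse(
                theta,
                pcfg,
                time_grid=cfg["design"]["time_grid"],
                seed=stage_seed,
                n_replicates=int(cfg["design"]["n_replicates"]),
                control_times=cfg["design"]["control_times"],
                panel=cfg["panel"],
            )
        d = out / "data" / pheno
        datasets[pheno].save(d)
        _write_manifest(d, stage="data", phenotype=pheno, config_hash=chash,
                        seed=stage_seed)
    report["datasets"] = datasets

    # -- stage 2: preprocessing ----------------------------------------------
    prepped: dict[str, SnapshotDataset] = {}
    for pheno in PHENOTYPES:
        stage_seed = stable_seed(seed, "preprocess", pheno)
        logger.info("preprocessing %s (seed %d)", pheno, stage_seed)
        prepped[pheno], scale_report = preprocess_dataset(
            datasets[pheno], pheno, cfg, seed=stage_seed
        )
        d = out / "preprocessed" / pheno
        prepped[pheno].save(d)
        scale_report.to_csv(d / "scale_report.csv", index=False)
        _write_manifest(d, stage="preprocess", phenotype=pheno, config_hash=chash,
                        seed=stage_seed)
    report["preprocessed"] = prepped

    # -- stage 3: network inference ------------------------------------------
    phospho = list(cfg["panel"]["phospho"])
    variables = phospho + (
        [cfg["panel"]["totals"][p] for p in phospho]
        if cfg["network"]["include_totals"]
        else []
    )
    networks = {}
    dynamics = {}
    for pheno in PHENOTYPES:
        logger.info("inferring %s network", pheno)
        pooled = prepped[pheno].select(condition="stimulated").pool(variables)
        logp = np.log1p(pooled.to_numpy(dtype=float))
        import pandas as pd

        net = partial_correlation_matrix(
            pd.DataFrame(logp, columns=variables),
            variables,
            threshold=float(cfg["network"]["threshold"]),
        )
        networks[pheno] = net
        d = out / "network" / pheno
        net.save(d, prefix=pheno)
        edges = [tuple(e) for e in cfg["network"]["canonical_edges"]]
        table, summary = edge_dynamics_by_timepoint(
            prepped[pheno].select(condition="stimulated"),
            edges,
            phospho,
            transform=np.log1p,
        )
        table.to_csv(d / "edge_dynamics.csv", index=False)
        summary.to_csv(d / "edge_dynamics_summary.csv", index=False)
        dynamics[pheno] = summary
        _write_manifest(d, stage="network", phenotype=pheno, config_hash=chash,
                        threshold=cfg["network"]["threshold"])
    report["networks"] = networks
    report["edge_dynamics"] = dynamics

    # -- stage 4: fits ---------------------------------------------------------
    settings = FitSettings.from_config(cfg, budget=budget)
    spec = CostSpec(
        channels=tuple(phospho),
        transform=cfg["cost"]["transform"],
        offset=float(cfg["cost"]["offset"]),
        estimator=cfg["cost"]["estimator"],
        bandwidth_cap=int(cfg["cost"]["bandwidth_cap"]),
    )
    fits = {}
    costfns = {}
    cells = {}
    for pheno in PHENOTYPES:
        stage_seed = stable_seed(seed, "fit", pheno)
        logger.info("fitting %s model (budget %s, seed %d)", pheno, budget, stage_seed)
        fits[pheno] = fit(
            prepped[pheno],
            None,
            spec=spec,
            settings=settings,
            seed=stage_seed,
            n_sim_cells=int(cfg["cost"]["n_sim_cells"]),
        )
        d = out / "fits" / pheno
        fits[pheno].save(d, prefix=pheno)
        _write_manifest(d, stage="fit", phenotype=pheno, config_hash=chash,
                        seed=stage_seed, budget=budget)
        # deterministic cost functionals reused by sensitivity + reconciliation
        cells[pheno] = baseline_cells(
            prepped[pheno],
            int(cfg["cost"]["n_sim_cells"]),
            seed=stable_seed(stage_seed, "cells"),
        )
        costfns[pheno] = MMDCost(
            prepped[pheno],
            cells[pheno],
            spec,
            seed=stable_seed(stage_seed, "bandwidth"),
            robust=True,  # wide grid offsets may need the stiff fallback
        )
    report["fits"] = fits

    # -- stage 5: sensitivity ---------------------------------------------------
    sens_cfg = cfg["sensitivity"]
    from .analysis import default_offsets

    offsets = default_offsets(
        float(sens_cfg["grid_lo"]), float(sens_cfg["grid_hi"]), float(sens_cfg["grid_step"])
    )
    logger.info("sensitivity grids (%d offsets per parameter)", len(offsets))
    grids = sensitivity_grid(
        fits["epithelial"].theta,
        costfns,
        {p: fits[p].theta for p in PHENOTYPES},
        offsets=offsets,
    )
    d = out / "sensitivity"
    d.mkdir(parents=True, exist_ok=True)
    for pheno, grid in grids.items():
        grid.save(d / f"{pheno}_grid.csv")
    _write_manifest(d, stage="sensitivity", config_hash=chash)
    report["sensitivity"] = grids

    # -- stage 6: reconciliation ------------------------------------------------
    rec_cfg = cfg["reconciliation"]
    logger.info("reconciling parameter sets")
    rec = reconcile(
        fits["epithelial"].theta,
        fits["mesenchymal"].theta,
        costfns,
        slack=float(rec_cfg["slack"]),
        n_candidates=int(rec_cfg["n_candidates"]),
        polish_iters=int(rec_cfg["polish_iters"]),
        sparsity_weight=float(rec_cfg.get("sparsity_weight", 1e-3)),
    )
    diffs = diff_report(rec, tol_log2=float(rec_cfg["tol_log2"]))
    d = out / "reconciliation"
    rec.save(d)
    diffs.to_csv(d / "differing_parameters.csv", index=False)
    _write_manifest(d, stage="reconciliation", config_hash=chash)
    report["reconciliation"] = rec
    report["differing_parameters"] = diffs

    # -- bundle ------------------------------------------------------------------
    summary = {
        "config_hash": chash,
        "seed": seed,
        "budget": budget,
        "runtime_s": round(time.time() - t_start, 2),
        "fit_costs": {p: fits[p].cost for p in PHENOTYPES},
        "reconciliation": {
            "cost_epithelial": rec.cost_e,
            "cost_mesenchymal": rec.cost_m,
            "bound_epithelial": rec.bound_e,
            "bound_mesenchymal": rec.bound_m,
            "n_differing": int(len(diffs)),
            "differing": diffs["parameter"].tolist(),
        },
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    report["summary"] = summary
    logger.info("pipeline complete in %.1f s", summary["runtime_s"])
    return report
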
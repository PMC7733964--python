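"""Shared fixtures: small synthetic populations and datasets."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import emtsig as es


@pytest.fixture(scope="session")
def presets() -> es.GroundTruth:
    return es.ground_truth_presets()


@pytest.fixture(scope="session")
def small_epithelial_population(presets):
    """150 epithelial cells with derived per-cell rates."""
    cfg = es.PhenotypeConfig.from_config(label="epithelial", n_cells_per_snapshot=150)
    pop, markers = es.generate_cell_population(cfg, seed=101)
    return es.derive_cell_rates(presets.theta_epithelial, pop), markers


@pytest.fixture(scope="session")
def tiny_study(presets):
    """Two-phenotype study at reduced scale (120 cells, 2 replicates)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return es.generate_two_phenotype_study(seed=7, n_cells=120, n_replicates=2)


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_study):
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pheno, data in tiny_study.items():
            out[pheno], _ = es.preprocess_dataset(data, pheno, seed=13)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
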
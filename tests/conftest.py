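import dataclasses

import numpy as np
import pytest

from mowsense import (ModelConfig, MowingDetector, SimConfig,
                      build_feature_matrix, fit_normalization_stats,
                      simulate_dataset)
from mowsense.pipeline import preprocess_series, split_indices


@pytest.fixture(scope="session")
def small_dataset():
    """80 synthetic field-seasons with defaults (fixed seed)."""
    cfg = SimConfig(n_fields=80, seed=11)
    series, labels, truths = simulate_dataset(cfg)
    return cfg, series, labels, truths


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    cfg, series, labels, _ = small_dataset
    grids, _ = preprocess_series(series, cfg.window)
    stats = fit_normalization_stats(grids)
    return build_feature_matrix(grids, labels, stats, cfg.window)


@pytest.fixture(scope="session")
def small_grids(small_dataset):
    cfg, series, labels, _ = small_dataset
    grids, _ = preprocess_series(series, cfg.window)
    return grids


@pytest.fixture(scope="session")
def trained_results(small_matrix):
    """A quickly trained detector shared across tests that need a fitted model."""
    n = small_matrix.n_fields
    tr, va, _ = split_indices(n, seed=5, fractions=(0.7, 0.3, 0.0))
    cfg = ModelConfig(max_epochs=120, learning_rate=1e-3, seed=3,
                      early_stopping_patience=30)
    det = MowingDetector(small_matrix.subset_fields(tr),
                         small_matrix.subset_fields(va), cfg)
    return det.fit(), small_matrix.subset_fields(va)
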
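"""Shared fixtures.

The default study fixture (300 cases x 71 items, seed 1) and its 2PL fit are
session-scoped: many tests interrogate different aspects of the same study
run, and the fit is the expensive step.
"""

import numpy as np
import pytest

from grmsim import (GeneratorConfig, ModelSpec, generate_dataset, fit_matrix,
                    q3_statistic)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    matrix, truth = generate_dataset(default_config)
    return matrix, truth


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    matrix, _ = default_dataset
    return fit_matrix(matrix, ModelSpec())


@pytest.fixture(scope="session")
def default_theta(default_dataset, default_fit):
    matrix, _ = default_dataset
    return default_fit.predict(matrix.values)


@pytest.fixture(scope="session")
def default_q3(default_dataset, default_fit, default_theta):
    matrix, _ = default_dataset
    return q3_statistic(matrix.values, default_fit, default_theta,
                        threshold=0.2, item_ids=matrix.item_ids)


@pytest.fixture(scope="session")
def small_fit_pair():
    """A small (250 x 12) dataset without injected dependence plus its 2PL
    and 1PL fits, for model-comparison and scoring tests."""
    cfg = GeneratorConfig(n_cases=250, n_items=12, dependence_pairs=(),
                          seed=7)
    matrix, truth = generate_dataset(cfg)
    fit2 = fit_matrix(matrix, ModelSpec(model="2pl"))
    fit1 = fit_matrix(matrix, ModelSpec(model="1pl"))
    return matrix, truth, fit2, fit1
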
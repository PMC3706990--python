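import logging

import numpy as np
import pytest

from isopure import (
    OptimizerConfig,
    discretize_tumors,
    generate_dataset,
    normalize_panel,
    step1_fit,
)

logging.getLogger("isopure").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_truth():
    """A small mixed cohort with known ground truth."""
    return generate_dataset(G=250, N=8, R=3, depth=50_000, seed=11)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced protocol for unit tests (full protocol is exercised in the
    acceptance suite)."""
    return OptimizerConfig(n_outer_iterations=25, n_restarts=3, seed=5)


@pytest.fixture(scope="session")
def small_fit(small_truth, fast_config):
    """Stage-1 fit of the small cohort, shared across tests."""
    counts = discretize_tumors(small_truth.tumors)
    panel = normalize_panel(small_truth.normals)
    model = step1_fit(counts, panel, fast_config)
    return counts, panel, model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
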
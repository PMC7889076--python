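import numpy as np
import pandas as pd
import pytest

from cordsig import (
    COVARIATES,
    ExpressionDataset,
    SimulationConfig,
    meta_analyze,
    simulate_microarray_collection,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, n_signal_genes=10, seed=1)


@pytest.fixture(scope="session")
def collection(small_config):
    return simulate_microarray_collection(small_config)


@pytest.fixture(scope="session")
def meta_tables(collection):
    datasets, _ = collection
    return {c: meta_analyze(datasets, c, seed=7) for c in COVARIATES}


def make_dataset(dataset_id, genes, matrix, **covariates):
    """Tiny hand-built dataset for unit tests."""
    matrix = np.asarray(matrix, float)
    n = matrix.shape[1]
    cov = pd.DataFrame(covariates, index=[f"s{i}" for i in range(n)])
    frame = pd.DataFrame(matrix, index=genes, columns=cov.index)
    return ExpressionDataset(dataset_id, frame, cov, frozenset(covariates))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
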
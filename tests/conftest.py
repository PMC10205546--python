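import numpy as np
import pandas as pd
import pytest

from hnsomics import AbundanceMatrix, SimulationParams, default_design, simulate_study


@pytest.fixture(scope="session")
def design_son():
    return default_design("SON", 6)


@pytest.fixture(scope="session")
def design_nil():
    return default_design("NIL", 6)


@pytest.fixture(scope="session")
def small_study():
    """One small coupled study reused by read-only tests."""
    return simulate_study(SimulationParams(n_proteins=300, seed=7))


def make_log2_matrix(values, feature_ids, sample_ids, scale="log2"):
    return AbundanceMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=feature_ids, columns=sample_ids),
        scale=scale,
    )


@pytest.fixture
def log2_matrix_factory():
    return make_log2_matrix
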
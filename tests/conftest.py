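import dataclasses

import numpy as np
import pandas as pd
import pytest

from immunesig import ExpressionMatrix, SyntheticConfig, simulate_cohort
from immunesig.reference import reference_model


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """One 300-sample synthetic cohort shared by read-only tests."""
    config = dataclasses.replace(default_config, n_samples=300, n_datasets=3, seed=11)
    matrix, clinical, truth = simulate_cohort(config)
    return config, matrix, clinical, truth


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    frame = pd.DataFrame(
        np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.0, 4.0, 2.0]]),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(frame, feature_kind="gene")
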
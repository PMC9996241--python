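import logging

import numpy as np
import pandas as pd
import pytest

from protact.core_io import FeatureMatrix
from protact.synthesize import SimConfig, simulate

logging.getLogger("protact").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_sim():
    """A small full-featured cohort shared by read-only tests."""
    return simulate(SimConfig(n_samples=80, n_kinases=12, n_tfs=8,
                              n_genes=300, n_background_sites=150, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, layer="phospho", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return FeatureMatrix(pd.DataFrame(values, index=features, columns=samples),
                         layer)
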
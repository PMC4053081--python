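import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from survnet.expression_io import SurvivalData
from survnet.ppi_graph import build_network


def random_survival_dataset(rng, n=12, p=1, binary=False, censor_frac=0.0):
    """Small random cohort with distinct times and at least one event."""
    while True:
        if binary:
            X = rng.integers(0, 2, size=(n, p)).astype(float)
        else:
            X = rng.standard_normal((n, p))
        time = rng.uniform(1.0, 100.0, size=n)
        event = (rng.uniform(size=n) >= censor_frac).astype(int)
        if event.sum() >= max(2, p + 1) and np.unique(X, axis=0).shape[0] > 1:
            surv = SurvivalData(tuple(f"S{i}" for i in range(n)), time, event)
            return X, surv


@pytest.fixture(scope="session")
def path_net():
    """Path graph A-B-C-D-E."""
    return build_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-module cohort shared by search tests."""
    from survnet.expression_io import align_samples, standardize
    from survnet.simulate import generate_dataset

    ds = generate_dataset(
        n_nodes=60, module_size=4, n_samples=120, effect_size=0.9, random_seed=7
    )
    m = standardize(ds.expression)
    m, surv = align_samples(m, ds.survival)
    return ds, m, surv


@pytest.fixture()
def tiny_expression():
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 1.5, 1.0, 2.0]],
        index=["A", "B", "C"],
        columns=["S1", "S2", "S3", "S4"],
    )
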